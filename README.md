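# fishlength

Non-contact body-length measurement of fish swimming in a tank, from one
top-view stereo RGB-D frame.

Manual fish measurement (net, ruler) is slow and stresses the animal. With
an overhead stereo RGB-D camera the length can be read off a single frame —
but three things get in the way: the fish must be cut cleanly out of the
background, a swimming fish is often bent, and light refracts at the
air-water interface, so both the image positions and the stereo depths of
submerged points are distorted. `fishlength` addresses all three:

1. **Contrast-adaptive GrabCut segmentation.** A user-drawn rectangle seeds
   an iterative Gaussian-mixture / min-cut minimization of the Gibbs energy
   `E(α,k,θ,z) = U + V`, where `U` sums per-pixel GMM penalties
   `-log P(z|α,k,θ) - log π(α,k)` and
   `V = γ Σ_(m,n)∈C [α_m≠α_n] exp(-β‖z_m-z_n‖²)` over 8-neighbour pairs,
   `β = (2⟨‖z_m-z_n‖²⟩)⁻¹`. A grayscale percentile stretch (replicated into
   all three channels) normalizes low-contrast underwater frames first.
2. **Bend classification and straightening.** The fish contour's
   minimum-area rectangle gives head/tail candidates `e`, `f` where its
   short sides meet the contour; the bend angle θ is the supplement of
   ∠eof at the rectangle centre. If θ > 5°, the fish is straightened: its
   midline is extracted by Zhang-Suen thinning plus corner removal and burr
   pruning (exactly two endpoints, no nodes), and the tail is moved to the
   point `m` on ray `e→f` with `|em|` equal to the midline arc length,
   carrying the depth of the original `f`.
3. **Flat-interface refraction correction.** With the camera a height `h`
   above the water, a submerged point's unrefracted and refracted image
   radii are related by `K = h/Z + (1-h/Z)·tanβ/tanα` (Snell:
   `n_a sinα = n_w sinβ`). The stereo-measured distance is corrected as
   `Z' = Z/K`, and 3D coordinates as `(K_w·(u-u₀)/f_x·Z', K_w·(v-v₀)/f_y·Z', Z')`.
   The length is the Euclidean distance `L = √(ΔX²+ΔY²+ΔZ²)` between the
   corrected head and tail; evaluation uses
   `RE = (L_est - L_true)/L_true × 100%` and its absolute mean (MRPE).

A fully ground-truthed synthetic scene generator (exact Snell ray tracing,
stereo apparent depth, parametric straight/bent fish) serves as the physics
oracle for the whole pipeline. See `docs/methods.md` for the model details
and accuracy envelope.

## Worked example

Render a synthetic scene (a straight 256.0 mm fish, 350 mm camera height,
500 mm water column) and measure it:

```sh
fishlength simulate --out-dir demo --seed 3 --camera-height 350
fishlength measure demo/rgb.png demo/depth.png \
    --config demo/config.yaml --roi 190,168,273,81
```

with `demo/config.yaml`:

```yaml
camera:
  fx: 600.0
  fy: 600.0
  cx: 320.0
  cy: 240.0
  baseline_mm: 50.0
  width: 640
  height: 480
refraction:
  camera_placement_mm: 850.0   # tripod height above the bucket floor
  water_depth_mm: 500.0        # camera sits 850 - 500 = 350 mm above the surface
```

prints

```json
{
  "arc_length_px": null,
  "head_depth_mm": 608.0,
  "head_px": [451.5, 190.0],
  "length_mm": 256.76,
  "length_mm_uncorrected": 256.76,
  "pose": "straight",
  "refraction_applied": true,
  "tail_depth_mm": 607.0,
  "tail_px": [200.5, 226.0],
  "theta_deg": 0.112,
  "warnings": []
}
```

The fish was classified straight (θ = 0.11°, below the 5° threshold), its
head and tail were found at the contour/rectangle intersections, and the
corrected length 256.76 mm is within 0.3% of the 256.0 mm ground truth.
The depths read from the depth map (~608 mm) are *apparent* depths — the
true fish plane is ~700 mm from the camera, shallowed by refraction; for this nearly horizontal fish
the corrected and uncorrected lengths agree to the printed precision, and
the correction matters most when head and tail sit at different depths
(pitched fish). Omit the `refraction` section (or pass
`--ignore-refraction`) to reproduce the uncorrected behaviour explicitly.

Other commands: `fishlength segment` (mask only), `fishlength evaluate`
(RE/MRPE over an estimate/truth CSV). `--debug-dir` dumps the
contrast-adapted input, the mask and the skeleton overlay.

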