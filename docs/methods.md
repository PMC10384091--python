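# Methods

`fishlength` measures the body length of fish swimming in a tank from a
single top-view stereo RGB-D frame. This note records the model behind each
stage, the numerical choices, what the synthetic scenes do and do not
emulate, and the known limits of the method.

## Imaging model and refraction correction

A pinhole stereo camera (intrinsics `fx, fy, u0, v0`, baseline `B`) looks
straight down at a flat water surface from height `h`. Pixels map to
normalized image-plane coordinates `x = (u-u0)/fx`, `y = (v-v0)/fy`, in
which the focal length is 1.

Light from a submerged point bends at the surface, so the point images at a
larger radius than it would in air and the stereo disparity is inflated:
the camera reads a distance `Z` *smaller* than the true one. The flat-
interface model relates the unrefracted and refracted image radii through

    K = h/Z + (1 - h/Z) * tan(beta)/tan(alpha),      0 < K <= 1,

with `sin(alpha) = r/sqrt(r^2+1)` from the image-plane radius `r` and
`sin(beta) = (n_air/n_water) sin(alpha)` from Snell's law
(`n_air = 1.0`, `n_water = 1.333` by default). On the optical axis the
ratio `tan(beta)/tan(alpha)` is replaced by its analytic limit
`n_air/n_water` (applied below `sin(alpha) = 1e-9`). Because disparity
scales by the same factor, the corrected distance is `Z' = Z/K`, and 3D
coordinates are `(Kw * x * Z', Kw * y * Z', Z')`. `K` is applied
isotropically to the radial offset: exact when the point and the refraction
plane share an azimuth, and a very good approximation otherwise.

**Where `Kw` is evaluated matters.** Writing the lateral coordinate out,
`X = Kw * x * Z'`: if `Kw` is the `K` already computed at the measured
depth (single pass), the factors cancel to `X = x * Z` — which is exactly
the paraxial-correct lateral position, because the stereo camera measures
the depth of the *virtual image*, whose lateral position coincides with the
real point's. Evaluating `Kw` at the single-pass corrected depth instead
breaks this cancellation and introduces a systematic lateral bias of
-1.4..-1.7% in the bucket geometry (verified against the exact ray tracer).
The package therefore defaults to `kw_mode="measured"` with a single pass.
A fixed-point mode (`iterate=True`, solving `Z' = Z/K(Z')`, tolerance
1e-6 mm, at most 20 iterations, paired with `kw_mode="corrected"`) inverts
the paraxial forward model exactly and is the right choice when the full 3D
point — not just a length — is wanted; it is what the ray-trace inversion
checks use.

**Accuracy envelope.** Against exact Snell ray tracing, the pointwise-`K`
correction is paraxially exact; its error grows like the fourth power of
the field angle because disparity samples the *derivative* of the
refraction map while `K` is a *position* ratio. Measured worst-case
per-coordinate recovery error: under 0.5% within 10 degrees of axis, ~1.2%
at 15 degrees, and 2.5-3% at the extreme corner of a 20-degree ray on a
point 500 mm below the surface. Consequences for lengths are smaller: a
consistent single-pass correction and naive back-projection share the same
lateral map, so for a horizontal fish the two nearly tie, and the
correction's real gain is in recovering the head-tail *depth* spread of
pitched fish (naive back-projection compresses depth differences by
`n_air/n_water`). This also means that, contrary to intuition about
"objects look bigger under water", naive stereo back-projection slightly
*under*-estimates 3D length; the magnification lives in the image, not in
the depth-compensated coordinates.

## Segmentation

GrabCut with two 5-component full-covariance Gaussian mixtures (foreground
and background) over 3-channel pixel values, minimizing the Gibbs energy
`E = U + V`: `U` sums per-pixel penalties
`-log pi(k) - log N(z; mu_k, Sigma_k)` under hard component assignment, and
`V = gamma * sum exp(-beta ||zm-zn||^2)` over 8-connected neighbour pairs
with unequal labels, `beta = 1/(2 <||zm-zn||^2>)` over all pairs,
`gamma = 50`. Minimization alternates component assignment, mixture refit,
and an exact s-t min-cut (scipy's max-flow on integer capacities, scale
1000); only pixels inside the operator's rectangle are free — everything
outside is clamped to background, which also keeps the graph small. Mixture
initialization is k-means with a config-fixed seed; backgrounds larger than
20k pixels are subsampled (seeded) for fitting. Covariances are regularized
by `+0.01 I` when their smallest eigenvalue drops below 1e-4. Energy is
re-evaluated over the whole frame after each outer iteration and is
monotone up to capacity quantization (asserted at relative 1e-6).

Preprocessing ("contrast adaptation") converts the frame to grayscale,
stretches the 1st-99th percentile range linearly to 0-255, adds an optional
brightness offset, and replicates the channel three ways. Because the GMM
energy is nearly invariant to affine intensity maps, the stretch itself
changes little on clean frames; the *grayscale collapse* is what helps,
by removing chromatic background clutter that the colour mixtures would
otherwise have to model. Adaptation is asserted never to cost more than
0.01 IoU on the rendered fixture suite.

## Midline skeleton and deburring

Zhang-Suen two-subiteration thinning runs to a fixed point (re-thinning is
the identity). Cleanup then enforces the contract "one 8-connected
component, two endpoints, no nodes" (endpoint: 1 foreground neighbour;
node: 3 or more):

1. *Corner removal* — single-pixel stair protrusions matching one of four
   patterns (e.g. north and west neighbours set, the SE quadrant empty) are
   deleted in sequential row-major sweeps with immediate effect; their two
   supports are diagonally adjacent, so connectivity is preserved.
2. *Burr pruning* — while more than two endpoints remain, the pair with the
   largest mutual distance defines the main skeleton; every other branch is
   eroded endpoint by endpoint until it reaches a node or a per-branch
   deletion budget (default 15% of the skeleton pixel count).
3. *Break repair* — if pruning splits the skeleton, the closest endpoint
   pair across components is joined with a straight discrete line.
4. The loop re-thins and de-corners after each pass: pruning can expose
   residual thick spots (three path neighbours without a true branch).

Shapes with no axis (a disk thins to one pixel) are rejected with a clear
error. Interior holes are filled before skeletonization in the pipeline;
a hole would otherwise yield a cyclic skeleton with no endpoints.

**Arc length** of the midline path is measured by chord summation through
every 5th pixel, not by counting axial/diagonal steps: the raw step count
overestimates a smooth digital curve by up to ~8% at intermediate
orientations (the classic staircase bias), while chord summation is exact
on straight and purely diagonal chains and loses only O((step/r)^2) on
curves of fish-like curvature. The composite length adds the straight gaps
between the skeleton endpoints and the head/tail points.

## Pose, measurement points, straightening

The cleaned mask's largest component is outlined (sub-pixel marching
squares) and enclosed in a minimum-area rotated rectangle. The contour
points nearest the supporting lines of the two *short* sides are the
head/tail candidates `e` and `f` (ties broken toward the side midpoint);
with the rectangle centre `o`, the bend angle `theta` is the supplement of
angle `eof`. `theta > 5` degrees (strict) classifies the fish as bent.

Straight fish: `e` and `f` are measured directly. Bent fish: the tail is
replaced by `m` on the ray `e -> f` at a distance equal to the composite
midline arc length; `m` keeps the depth sampled at the original `f`, and may
fall outside the frame (flagged, never clamped).

Depth at a measurement point is the median of valid (non-zero) readings in
a 5x5 window, restricted to fish pixels when a mask is available, with a
nearest-valid fallback within 15 px. The pipeline erodes the mask by two
3x3 steps before sampling: the head/tail points sit on the silhouette
boundary, where the neighbouring *background* (the tank bottom) also
returns valid depth, and an unrestricted median can land in the wrong
surface entirely.

Head and tail are back-projected (through the refraction model when
configured) and the body length is their 3D Euclidean distance. Both the
corrected and the ignore-refraction lengths are always reported. Evaluation
uses the signed relative error `RE = (estimate - truth)/truth * 100%` and
its absolute mean (MRPE).

## Synthetic scenes: what they emulate

The generator renders the study geometry: a 500 mm water column, a camera
250/350/450 mm above the surface (640x480, `fx = fy = 600` px, 50 mm
baseline — a RealSense-class device), and fish of 250-320 mm with fusiform
sqrt-of-sine width profiles (blunt snout and tail, so the rasterized
silhouette preserves the nominal tip-to-tip length at pixel scale).
Straight fish pitch by N(0, 8 deg) clipped to +-20 deg — calibrated from
the head-tail depth spread implied by the physical experiment's
corrected-vs-uncorrected error gaps — and bent fish bend along circular
arcs of 40-110 degrees in the horizontal plane. Scenes are rendered by
exact Snell ray tracing (vectorized bisection, 52 iterations, residual
monotone on the bracket): the RGB holds the refracted silhouette
(PSF sigma 0.8 px, additive Gaussian noise sigma 4), and the depth channel
holds the *apparent* depth an ideal stereo pair at +-B/2 would report, with
2 mm Gaussian noise, bottom included. All randomness flows from one seed.

Not emulated: caustics, turbidity, waves, motion blur, fish occlusion and
overlap (overlap is rendered but flagged), the infrared-projector artefacts
and distance-dependent depth degradation of a physical active-stereo
camera, and lens distortion. Passing tests therefore show the *geometry*
of the method is right under ideal optics with realistic shape, pose and
sensor-noise statistics; they do not certify behaviour under real water or
real RealSense depth error profiles. Notably, the physical experiment's
uncorrected error *grows* with camera height, which ideal-stereo physics
does not reproduce (the refraction error shrinks as field angles shrink);
that trend likely reflects hardware depth degradation with distance.

## Study problem sizes

The shipped study grid is 3 heights x 10 fish x 3 replicates (90 rendered
scenes, one fish per scene — a 250-320 mm fish nearly half-fills the frame
at these distances, so multiple fish cannot fit without overlap). The
ray-trace inversion check uses 500 points. These sizes give MRPE estimates
stable to a few hundredths of a percent between seeds.

## Known limitations

- The pointwise-`K` correction degrades past ~15 degrees off-axis (2.5-3%
  per-coordinate worst case at 20 degrees on deep points). Keeping the fish
  in the central two-thirds of the frame avoids the regime entirely.
- On extreme bends (near-semicircular bodies) the rectangle short sides
  touch the outer corners of the C-shaped silhouette rather than the snout
  and tail tips, displacing `e`/`f` by up to half the body width; the
  straightened length then overshoots by 5-12%. At realistic swimming bends
  (up to ~110 degrees of arc) the end-to-end error stays under ~2%.
- One fish per rectangle; overlapping fish are not separated.
- The 5-degree bend threshold, GrabCut's `gamma = 50` and 5 components, and
  the 15% burr budget are operating defaults, exposed in the config.
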