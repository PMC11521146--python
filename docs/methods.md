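# Methods

`tiltprobe` implements a three-step design workflow for tilted-fiber
diffuse-reflectance probes on semi-infinite turbid media: (1) the minimum
source–detector separation (SDS, ρ) is fixed by a scattering-order
criterion F that bounds the influence of phase-function Legendre moments
above order 2; (2) the maximum SDS is fixed by the noise robustness of a
look-up-table (LUT) inverse solver; (3) the probe's sampling depth is
summarized by the zv80 quantile of the collected photons' scattering-event
depths. This note records the model, its assumptions, the numerical
choices, and what the desk-scale tests do and do not establish.

## Phase functions and moments

Three single-scattering phase functions are provided, all expressed per
unit cosine μ = cos θ on [−1, 1] (the per-solid-angle forms in the
literature differ by a 1/2π azimuthal factor, divided out here because
single scattering in an isotropic medium is azimuthally uniform):

* Henyey–Greenstein (HG): `p(μ) = ½ (1−g²)(1+g²−2gμ)^{−3/2}`, moments
  g_n = g^n.
* Modified HG (MHG): `α·p_HG + (1−α)·(3/2)μ²`; g1 = αg,
  g2 = αg² + (2/5)(1−α), g_n = αg^n for n > 2.
* Modified power of cosines (MPC): `α·p_PC + (1−α)·(3/2)μ²` with
  `p_PC = (N+1)/2^{N+1}(1+μ)^N`; gPC1 = N/(N+2),
  gPCn = gPC(n−1)(N−n+1)/(N+n+1). Non-integer N is allowed — the
  recursion stays valid and moment matching generally requires it.

Solving family parameters from a target (g1, g2): α is eliminated in
closed form; for MHG the remaining shape equation is an exact quadratic
(`g1·g² + (0.4−g2)·g − 0.4·g1 = 0`, positive root taken in its
cancellation-stable conjugate form), for MPC the exponent is found by
`brentq` on its unique monotone branch. Targets outside the representable
region (α ∉ [0, 1]) are rejected, not clamped, except that targets within
1e−9 of the pure-HG boundary g2 = g1² snap onto it — the limiting case
γ = 1.9 at g1 = 0.9 lands exactly there up to floating-point rounding.
Samplers are exact inverse-CDF constructions per mixture component and
were verified against the analytic moments through order 6 at 4×10⁶
samples.

The subdiffusive parameter is γ = (1−g2)/(1−g1). Because (μs′, γ) do not
pin down a phase function, media built from intrinsic optical properties
fix the anisotropy at g1 = 0.9 (a standard soft-tissue value) and derive
g2 = 1 − γ(1−g1). For the MHG family this bounds γ ≤ 1 + g1 = 1.9;
LUT γ-nodes beyond that are marked invalid and excluded from the search
(lowering g1 only tightens the bound, so no fallback exists).

## Effective phase functions and Ws

Legendre moments multiply under composition of independent rotations:
after s scattering events the effective phase function has moments
g_{n,s} = g_n^s, equivalently ⟨cos θ⟩_s = g1^s and
⟨cos² θ⟩_s = 1/3 + (2/3)g2^s (the reading of the second-moment decay
that is consistent with the general power law and reaches the isotropic
limit 1/3). Both laws are verified against composed-rotation Monte Carlo
(azimuth uniform on [0, 2π)) within 3 standard errors at 10⁶
compositions.

The per-order weight

    W_s = ∫ |p_MHG(g1^s, g2^s, μ) − p_MPC(g1^s, g2^s, μ)| dμ

measures how much the moments above order 2 can still influence an
s-times-scattered photon. The implementation solves both families at the
decayed (g1^s, g2^s) and integrates the absolute density difference with
≥512-node Gauss–Legendre quadrature (the |·| kink demands dense nodes;
convergence was checked by node doubling). An alternative reading sums
the Legendre series of the *true* effective-moment differences
(g_{n,MHG}^s − g_{n,MPC}^s) with the per-cosine (2n+1)/2 factors and
adaptive truncation (geometric tail bound < 1e−8). The two readings are
the same integral at s = 1 (agreement < 1e−6 relative, asserted in the
tests) but diverge structurally for s > 1, because a family re-solved at
decayed first moments does not have higher moments g_n^s: measured
divergence grows from ~2% at s = 2 to order-of-magnitude at s ≥ 20 where
both tend to zero. The area form is used throughout, as it is
convention-free and always feasible for γ ∈ [1, 2] (the decayed pair
remains representable by both families); the series form is retained as a
fallback and cross-check. W tables run from s = 1 to the first order
with W_s < 1e−4 (cap 300); orders beyond contribute nothing at the 0.1
criterion threshold. For flat pairs the area form shows a small
non-monotonic blip at mid-orders (e.g. (0.6, 0.4): W3 = 0.0180,
W5 = 0.0192); the overall decay to zero is what matters for F and is
what the tests assert.

## Transport model

Photon packets with unit initial weight start uniformly on the source
footprint (0.1 mm core on z = 0) and within the in-tissue cone of
half-angle asin(NA/n_in) (NA 0.4, n_in 1.43 → 16.25°) about the tilted
axis. Steps are exponential with mean 1/μs; directions update by the
standard local-frame rotation; absorption is continuous Beer–Lambert
weight attenuation over path length (no absorption events), so the
scattering count s counts scattering only and a single μa = 0 run can be
reweighted exactly to any absorption — the identity behind the LUT's μa
axis, verified against direct runs within 3 SE. Unpolarized Fresnel
coefficients at every surface crossing decide internal reflection versus
escape. Photons terminate by escape, by Russian roulette below weight
1e−4 (survival 0.1, unbiased), or by generous geometric caps (z > 12 mm,
r > 30 mm, s ≥ 30000) that only matter in zero-absorption runs; at
μs′ = 2/mm the caps remove ~11% of the *weight* of a μa = 0 run but a
negligible amount of its short-separation reflectance (those photons
would return within ρ ≤ 2 mm with vanishing probability). Weight
accounting over the exit/absorption/cap/roulette channels closes to
1e−9 per run.

Fiber–tissue coupling is configurable and defaults to **index-matched**:
the fiber face is treated as optically continuous with the tissue
(fused-silica cores at n ≈ 1.45 against tissue at 1.43), so the tilt
angle acts un-refracted in the medium and detection is decided on the
*internal* direction at the footprint — inside the circular footprint and
within asin(NA/n_in) of the internal tilted axis — before any Fresnel
lottery. The alternative `"air"` mode refracts the axis at the surface
(capping the usable internal tilt at the critical angle asin(1/1.43) ≈
44°) and accepts on the refracted external direction. The matched mode
is the default because a 60° probe tilt is optically meaningless through
an air gap, and the strong shallow-sampling effect of steep tilts only
exists when the tilt survives into the tissue. Outside detection events
the boundary is uniform tissue–air Fresnel in both modes (flush probe
face, no glass plate modeled); a footprint-hitting photon outside the
acceptance cone re-enters the normal boundary lottery.

For fully perpendicular layouts the detector tally uses ring-averaged
(arc-fraction) scoring: the layout is azimuthally symmetric, so a
detector's expected signal equals the photon's exit-ring arc fraction
covered by the footprint times the rotation-invariant cone test. This is
an exact expectation identity and reduces variance by one to two orders
of magnitude; scored photons continue through the boundary lottery
(MCML-style expected-value scoring), whose revisit double-count is of
order the footprint-to-annulus area ratio (~1e−3 relative) — confirmed
by agreement with brute-force direct detection within combined errors,
for both reflectance and zv80. Tilted layouts use direct footprint
detection.

Tallies per detector: reflectance (collected weight fraction) with a
batch-means standard error (10 batches by default, SE ∝ 1/√n verified);
the weighted distribution p_s of scattering counts (an unweighted
variant is kept for sensitivity analysis); and a weighted histogram of
scattering-event depths in 0.01 mm bins (6 mm range, overflow in the
last bin), each event carrying the photon's final detected weight. zv80
is the 80% quantile of that histogram with linear interpolation inside
the containing bin.

The kernel is a single-threaded numba routine with an inline
xorshift128+ generator seeded via splitmix64 from the run seed; identical
seeds give byte-identical tallies. Throughput is roughly 3–4×10⁷
scattering events per second per core — with the roulette-limited path
lengths of absorbing media this is ~10–60 s per 10⁶ photons, the low end
for μs = 10/mm with μa = 0.4/mm and the high end for μs = 20/mm with
μa = 0.1/mm.

## The F criterion and ρmin

Per detector, F = Σ_s p_s W_s with the weighted p_s and the W table of
the medium's own (g1, g2). Small F means the detected photons scattered
enough times that moments above order 2 no longer shape the reflectance;
the validity threshold is F ≤ 0.1, calibrated by the requirement that
the MHG-vs-MPC reflectance discrepancy at matched (g1, g2) stay below
10%. ρmin is the smallest grid separation with F at or below threshold,
from a single multi-detector run on the 0.1 mm design grid.

Desk-scale measurements of the calibration across the
{μs′ ∈ {1, 2}} × {μa ∈ {0.1, 0.4}} × {tilt ∈ {0°, 40°}} grid (10⁶
photons per run, γ = 1.5) largely respect the 10% bound, with one
genuine exception: at high absorption (μa = 0.4/mm) and large separation
the matched-pair discrepancy reaches ~12–13% while F is far below 0.1.
With strong absorption the detected signal is exponentially sensitive to
the path-length distribution, which higher phase-function moments still
influence even after many scattering events; the scattering-count
heuristic undercounts this channel. The acceptance checks report what is
measured; this regime is flagged rather than hidden.

## LUT inversion and ρmax

The LUT tabulates per-detector reflectance over (μs′, γ, μa), full-scale
spans [0.25, 3] × [1, 2] × [0, 1] (40³ in the original protocol); the
desk profile uses 12 × 11 × 11 points (5–6 γ points in the quick test
fixtures) so that the benchmark media lie on grid nodes, with 1–1.5×10⁵
photons per (μs′, γ) node and the μa axis filled by reweighting; at that
budget the node standard errors (~2–3% over the fitted separations) stay
below the 10% measurement noise they are compared against. The cost is the *mean* per-detector relative
error (the mean, rather than the printed sum, keeps the 0.1 cost contour
comparable across fiber counts), minimized by exhaustive search over
valid nodes with lowest-index tie-breaking. Noiseless inversion of
independently seeded case-1 data recovers all three properties within
one grid step (the μs′–μa cost valley makes a one-step diagonal
trade-off the typical residual).

Robustness: the truth reflectance is corrupted with independent
multiplicative Gaussian noise (σ = 10% of R, non-positive draws
resampled), re-inverted, and the estimation error — the mean over the
three properties of |estimate − truth|/truth — is averaged over 10
replicates; detectors are added every 0.1 mm from ρmin outward and ρmax
is the smallest extent with mean error ≤ 10%. All replicate noise is
drawn once so successive extents see the same corrupted data, making the
error-vs-extent curve a paired comparison.

## Design workflow and benchmark media

Two reference media are built in: case 1 (μs′ = 2/mm, γ = 1.5,
μa = 0.2/mm), typical of visible-range tissue, and the limiting case 2
(μs′ = 1/mm, γ = 1.9, μa = 0.2/mm) whose low scattering and high γ
demand the largest ρmin — a probe designed against it remains valid for
more benign tissue. At desk scale (2–8×10⁶ photons) the workflow yields,
for case 2: ρmin = 0.3 mm perpendicular (one grid step short of the
published 0.4 mm) and 1.1 mm at 60° tilt (matching); zv80 ≈ 0.93 mm for
the perpendicular probe at ρ = 0.9 mm versus the published 0.8 mm, and
≈ 0.35 mm for the tilted probe at ρ = 1.7 mm versus 0.3 mm, a
depth-reduction ratio of ~2.7 (published ~2.6). The perpendicular-depth
excess is reproducible across scoring modes and photon budgets; it most
plausibly reflects boundary-model sensitivity (the uniform tissue–air
boundary recycles photons into deep excursions by total internal
reflection; a glass-faced probe tip would suppress them). The spread
between the two printed readings of the W-normalization would likewise
move ρmin by one grid step. Both sensitivities are documented rather
than tuned.

## What the desk scale does and does not show

All simulation-backed numbers here use 10⁵–8×10⁶ photons (the original
protocol used 10⁸) and reduced LUT grids; statistical tolerances in the
tests are stated as multiples of the measured standard errors, and
grid-quantized quantities (ρmin, ρmax) carry one-grid-step tolerances.
The synthetic benchmark is self-contained — media are mathematical
phase-function mixtures, not measured tissue; no instrument response,
probe-face reflections, spectral dependence, or layered structure is
modeled. Passing tests therefore establish the internal consistency of
the framework and its agreement with the published design points at
reduced budget, not the accuracy of any specific tissue measurement.
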