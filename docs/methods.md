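# Methods

## Coordinate contract

All streamlines are stored and processed in world millimetres (RAS).
Voxel indices are 0-based and an integer index denotes the voxel centre;
every voxel lookup goes through the target volume's 4×4 affine, so
co-registration differences between maps reduce to affine bookkeeping.
TRK headers are honoured on read so TRK and TCK bundles load into the same
world frame. Consecutive duplicate vertices are collapsed on read.

## Along-tract profiling

Fibers are oriented so the first vertex is the endpoint nearer the anchor
(the seed / LGN end), then resampled to 50 nodes at equal fractions of the
piecewise-linear arc length; endpoints are preserved exactly and no spline
smoothing is applied (deterministic and directly testable). The scalar
value at a node is a weighted mean across fibers. The node's mean position
and 3×3 sample positional covariance (ridged by ε·I, ε = 10⁻⁶ mm², so
single-fiber and collinear clouds stay well-posed) define Mahalanobis
distances dᵢ, and weights wᵢ ∝ exp(−dᵢ²/2), normalised to sum to one.
This Gaussian-of-Mahalanobis kernel is the standard fiber-core weighting
of along-tract analysis; identical fibers reduce to the unweighted mean
and a single fiber to plain point sampling.

Scalar maps are sampled with trilinear interpolation; binary masks always
use nearest-voxel lookup, since interpolating a mask would invent partial
lesions. Nodes 46–50 are computed but masked out of every analysis
default: near the cortical end the bundle fans out along the calcarine
sulcus and the core loses meaning. Analyses therefore run on nodes 1–45.

## Compartments

A fiber is lesional iff any of its original (pre-resampling) vertices maps
to a lesion voxel. A hemisphere is *no-lesion* (no lesional fibers),
*complete* (no non-lesional fibers) or *partial* (both present) — the
fiber-level operationalisation of "lesion occupying the entire
cross-section", chosen because it matches the downstream fiber split.
Hemisphere selection prefers no-lesion over partial and partial over
complete, with seeded random tie-breaks; the never-observed
(no-lesion, complete) pairing selects the no-lesion side and logs a
warning, maximising usable non-lesional fibers. Lesion connected
components use 6-connectivity (face neighbours), a conservative
separation on coarse grids. Lesion volume is partitioned exactly into
inside-tract and outside-tract parts against the mask of voxels visited
by any fiber vertex.

## Topography and the Wallerian-degeneration model

A lesion's node extent is the [min, max] of valid nodes where at least one
lesional fiber's node point lies in that lesion component; extents are
computed on lesional fibers only. The frequency histogram counts lesions
(not patients) per node. The cumulative WD load of a lesion [a, b] ramps
linearly from 0 at a to 1 at b and stays 1 distal to b: a transected axon
degenerates from its transection point to the cortical end, and the
transection point within the lesion is unknown, hence taken uniform. A
step alternative (full load from the proximal border) is available via
`within_lesion="step"`. Asymmetry Δ = (L − N)/N is computed per node on
core-averaged profiles, not per fiber. Topographic correlations are
Pearson r over jointly valid nodes.

## Statistics

Node-wise comparisons use the classic pooled-variance two-sample t with
uncorrected two-sided p (per-node significance flags; Welch and
Benjamini–Hochberg variants available but off by default, matching the
common per-node highlighting practice). Paired t, one-way ANOVA F and
Pearson r follow their textbook definitions via scipy. The regression is
OLS with backward elimination: predictors (and outcome) are z-scored so
coefficients are standardized betas; the predictor with the largest
p > 0.05 is removed iteratively until all remaining p ≤ 0.05. An empty
final model is a legitimate outcome. Numerically perfect fits
(R² = 1 − 10⁻¹²) mark negligible coefficients (|b| < 10⁻⁸) removable,
since p-values against a ~0 residual variance are meaningless. Covariate
adjustment is handled by entering covariates into this regression rather
than a separate GLM framework.

## The synthetic phantom

The phantom generates exactly the inputs the pipeline consumes (TRK
bundle, AD/RD NIfTI maps, binary lesion mask, ground-truth JSON) from a
seeded configuration; everything is deterministic under the seed.

**Geometry.** The centreline is an arc-length-parameterised quadratic
Bézier (~57 mm) inside a 64 mm cube; each of the 300 fibers is the
centreline plus a constant transverse offset drawn from an isotropic 2D
Gaussian (σ = 3 mm) in the transported normal frame. The grid default is
128³ voxels of 0.5 mm.

**Physiology.** Baselines are smooth low-order polynomials in arc
fraction t around the healthy optic-radiation means AD 1.32 and RD 0.57
(10⁻³ mm²/s), giving a few-percent along-tract variation. A lesion is a
sphere of radius 6 mm placed off-axis so that it transects a configured
fraction (default 0.5) of the fiber cross-section; the offset distance is
solved exactly from the noncentral-χ² coverage equation. Inside the
sphere, RD is scaled by 1 + δRD (default 0.30) and AD by 1 + δAD (default
0.10). The Wallerian territory — the tube swept by transected fibers
distal to the lesion — elevates AD by 1 + δAD_wd (default 0.10) and
leaves RD untouched: demyelination is lesion-confined, degeneration is
distal. Additive Gaussian noise with sd = 5% of the local baseline
(default; settable to 0) is applied last. An eigenvalue emitter
(λ1 = AD, λ2 = λ3 = RD) feeds the eigenvalue→metric path and defines the
phantom's MD and FA maps.

**Numerical-fidelity choices.** The WD territory is evaluated
analytically in the local frame (voxel's transverse offset inside the
lesion's coverage disk and t beyond the distal border) rather than by
rasterising fiber paths and dilating: the rasterised variant bleeds one
voxel onto intact neighbouring fibers and under-fills the transected
ones, biasing the recovered ΔAD downward by about half. Likewise the
0.5 mm grid and 3 mm fiber spread keep the trilinear blending shell at
the lesion surface thin relative to the bundle: at 1 mm voxels the shell
clips the recovered within-lesion ΔRD peak to ≈0.26 of the injected
0.30, at 0.5 mm it recovers ≈0.285. The residual gap is the expected
partial-volume clipping of a binary sphere sampled with trilinear
interpolation; partial-volume structure at lesion borders is deliberately
not modelled.

**Cohorts.** Subject seeds are spawned from a master seed. Lesion centres
are drawn from a truncated normal on (0.1, 0.9) with mean 0.62 and
sd 0.07 — lesions concentrated in the third quarter of the tract and none
near the seed end. A configurable fraction of subjects carries no lesion,
emulating a lesion-free group.

**What the phantom does not emulate.** Realistic anatomy (Meyer's loop,
fanning geometry), crossing fibers, DWI signal formation and tensor
fitting, registration error, and partial-volume effects at lesion
borders. Passing tests therefore demonstrate that the pipeline recovers
the compartment model's effects under clean geometry — not that it would
survive tractography or registration failure modes on patient data.

## Problem sizes

Defaults were chosen so a full cohort analysis runs in minutes on one
CPU: 300 fibers × 50 nodes per subject, 128³ half-millimetre voxels,
20-subject cohorts, 1000-replicate null simulations for the type-I-rate
check.

## Known limitations

The fiber-core weight kernel is a standard choice, not uniquely
determined by the compartment model itself; the interpolation scheme for
scalar sampling (trilinear) is likewise a convention. The backward
elimination stopping rule (p > 0.05, none forced in) is one reasonable
operationalisation. Lesion-frequency counting is lesion-level, so one
subject with several lesions contributes several counts.
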