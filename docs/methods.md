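# Methods

This note documents the models, numerical choices and known limitations of
`occlucontact`. Units are millimetres throughout the core; interocclusal
offsets are accepted in μm at the interface and converted once.

## Occlusal contact area

### Distance formulation

The contact area at interocclusal distance *t* is defined as the sublevel
set of the unsigned distance field of the maxilla, restricted to the
mandible surface. This is the package's reinterpretation of the CAD
construction in which the maxilla is *enlarged* by a surface offset and
intersected with the mandible: for offsets small relative to the local
feature size the enlarged-surface interior is exactly `{dist <= t}`, while
at large offsets (2000 μm) an explicit offset surface self-intersects inside
fissures and mesh booleans become fragile. The distance formulation remains
well-defined at every offset, and is unsigned on purpose: casts fixed in
contact can interpenetrate slightly after digitisation, and a signed
convention would drop exactly the regions that are most firmly in contact.

Distances are exact. A kd-tree over maxilla face centroids provides an
upper bound (the exact distance to the face with the nearest centroid); any
face that could contain the true closest point must have its centroid
within `bound + r_max` of the query (`r_max` = largest centroid-to-vertex
distance), and the minimum over that candidate set equals the exhaustive
all-triangle minimum — this is asserted against a brute-force oracle in the
tests. Queries that only feed membership decisions (`d <= t`) may stop at
the upper bound when it certifies the answer; this never changes a
decision.

### Patch extraction

Mandible vertices get distance values; faces are classified with the
1-Lipschitz bound (a face whose minimum vertex distance exceeds
`t + longest_edge` cannot touch the region; one below `t − longest_edge` is
entirely inside). Faces the iso-contour might cross are 4-way midpoint
subdivided until edges are below `refine_max_edge` (default 0.1 mm), and
the piecewise-linear interpolant of the vertex distances is clipped at
`d = t` (marching triangles): triangles with one vertex inside yield a
clipped triangle, with two a quad. `area_3d` is the sum of fragment areas.
One refined field serves all nine offsets, so patches are exactly nested
across offsets and both area sequences are monotone by construction.

Approximation errors: the linear interpolant of the distance field (second
order in the refined edge length — halving `refine_max_edge` moves fixture
areas by well under 1 %), and hairline cracks where refined triangles meet
coarse ones (sub-linear in edge length; negligible against the raster
tolerance). Both shrink with `refine_max_edge`.

### 2D projection

The 2D area is the area of the **union** of fragment projections onto the
occlusal plane, not their sum — overhanging facets must not double-count
(an explicit overhang fixture checks this). The default method rasterizes
the projected fragments at 100 px/mm (10 μm pixels) on a grid snapped to
the global origin, so nested patches see identical pixel centers and the 2D
areas inherit monotonicity; an exact polygon union (shapely) is available
as the verification reference and agrees with the raster to ~10⁻⁵
relative on phantom patches. A fragment-sum variant exists for sensitivity
analysis only. No anatomical masking is applied: the whole mandible surface
is eligible, so at 2000 μm non-occlusal near-contacts may contribute,
mirroring an unrestricted CAD intersection.

### Orientation and registration

`orient_pair` maps the landmark plane (incisal contact point 31/41,
distobuccal cusps 36/46) to z = 0 with the landmark centroid at the origin
and +z toward the maxilla centroid — the sign convention that makes the 2D
projection well-defined. Both jaws receive the same rigid transform, so the
relative pose (and hence every contact area) is untouched; rigid
invariance is tested to 10⁻⁶ relative. The clinical three-stage best-fit
through a buccal scan is deliberately not modelled: the downstream
computation depends only on the final relative pose, and inputs to the OCA
engine are an already-posed `AlignedJawPair`. For refining an approximate
pose, `rigid_register` implements ICP with nearest-vertex correspondences
and a linearized point-to-plane update (point-to-point Kabsch available),
max 100 iterations, stopping when the RMS residual improves by less than
1e-4 mm; a step that would worsen the residual is rejected, making the
reported residual sequence non-increasing. No pass/fail gate is imposed on
residuals; they are reported.

## Digital sieving (X50)

Segmentation is a global Otsu threshold (dark particles on a light
background by default, invertible) with 8-connected labelling and a minimum
particle area of 0.05 mm²; touching particles merge, because the protocol
assumes physically separated particles — no watershed is attempted. The
cumulative curve weights each particle by its equivalent-sphere volume d³
(sieving is mass-based and the silicone test food has uniform density);
area weighting is available as an alternative. The Rosin–Rammler form is
written with x50 as a direct parameter so `Q(x50) = 0.5` holds by
construction; fitting is nonlinear least squares on the cumulative points
with the empirical 50 %-crossing as the start value. Degenerate inputs
(fewer than 3 distinct sizes, non-convergence) fall back to the empirical
50 %-passing size with a flag. The recovered/initial weight ratio is QC
only (flagged below 0.9): lost material is never imputed into the
distribution, because no principled imputation exists without knowing which
sizes were lost. When two chewing trials are supplied, the second enters
analysis (the first is familiarisation); both are kept for retest
reliability.

## Cohort statistics

Outlier exclusion is a single group-wise pass on X50: records deviating
more than `k_sd` (default 2) sample SDs from the group mean are removed
from the **correlation analysis only** — group descriptives and the group
comparison use the full sample. Recursive trimming is deliberately not
applied (it is unstable). Pearson correlations are two-sided; no multiple
testing correction is applied across the 18 strategies in the headline
numbers, but a Bonferroni column is emitted alongside. Labels "strong"
(|r| > 0.7) and "significant" (p < 0.05) are annotations, not gates.
`best_strategy` takes the extreme r in the expected direction (negative by
default, since lower X50 = better performance); exact ties break toward the
smaller offset, then 3D before 2D. The Mann–Whitney U test uses midranks;
p-values are exact by full enumeration of all group assignments for
n₁+n₂ ≤ 12 (correct under ties) and otherwise use the tie-corrected normal
approximation with continuity correction. Quartiles use linear
interpolation between order statistics (numpy's default convention), fixed
here for reproducibility.

## Synthetic data

The generators define the conditions under which everything is tested; all
randomness flows through one seeded `numpy.random.Generator` and identical
parameters + seed give identical output.

**Analytic fixtures** (plates, sphere-on-plane, tilted patch, overhang)
carry closed-form area functions used as oracles; e.g. the sphere apex a
gap *g* above a plate gives a contact disk of area π((R+t)² − (R+g)²).

**Jaw phantoms** are height fields of Gaussian cusps along a U-shaped arch,
flat-capped at 80 % of cusp height; the maxilla is the mandible raised by
the gap plus an opening term that vanishes on the plateaus, so the minimum
interocclusal distance equals the gap (to ~0.01 mm near plateau rims where
surface slope makes the normal distance marginally smaller than the
vertical one). Defaults: 14 × 14 mm arch, 6 cusps of height 1.5 mm and
width σ = 2 mm, 0.1 mm gap, 0.25 mm grid. These are desk-scale phantoms,
not anatomy: no fissure systems, no enamel wear, no per-tooth morphology —
passing tests show the geometry engine is correct, not that clinical scans
look like this.

**Particle images** render non-overlapping anti-aliased disks. Because the
Rosin–Rammler Q is a mass-fraction curve, diameters are drawn from the
number density ∝ q(x)/x³ (truncated at 0.5 mm where Q ≈ 10⁻³), so that the
d³-weighted pipeline should recover the nominal x50; stratified
inverse-transform sampling keeps the finite population close to the law.
Real scans differ in texture, lighting gradients and irregular particle
shapes; the phantom tests segmentation geometry and the statistical
pipeline, not illumination robustness.

**Cohorts** use a latent per-subject contact quality *u*: the planted
strategy is exactly log-linear in *u*, X50 follows a Gaussian copula on the
log scale whose latent correlation is analytically compensated for
log-normal attenuation so the **raw-scale** Pearson r hits the target
(−0.75 in the normal-occlusion group, 0 in the malocclusion group, matching
the study frame of 23 + 18 subjects with group X50 means 4.58/5.35 and SDs
0.37/0.43). Every non-planted strategy carries independent log-noise of SD
0.5 (the 2D/3D ratio through a logistic transform so 2D < 3D holds without
clipping); monotonicity in offset is enforced outward from the planted
offset so the planted value is never modified, and the 2D profile by a
backward minimum pass. These noise levels were chosen so that the planted
strategy is reliably the strongest correlate at n = 23 — the detectability
contract the generator must honour for the strategy-selection analysis to
be testable at all; smooth-in-offset covariance (arguably more realistic)
would make neighbouring strategies statistically indistinguishable at this
sample size. The true in-vivo joint distribution of the 18 strategies is
unknown.

## Problem sizes and defaults

| parameter | default | notes |
|---|---|---|
| offsets | 100…2000 μm (9 values) | the standard evaluation grid |
| `refine_max_edge` | 0.1 mm | contact-band subdivision |
| raster resolution | 100 px/mm | 2D union area |
| min particle area | 0.05 mm² | speck filter |
| sieving weighting | volume (d³) | `area` available |
| outlier rule | 2 SD, one pass, X50 | correlation only |
| phantom suite | 20 seeds × 10⁵ MC points | Monte-Carlo cross-check |
| sieving suite | 20 seeds × 500 particles | X50 recovery |
| cohort suite | 100 replicates × n = 23 | planted-correlation recovery |

The suite sizes keep the full test run in a few minutes on one CPU while
leaving the statistical checks comfortably powered.

## Known limitations

Static occlusion only (no articulation, force or pressure); no per-tooth
attribution of contact; no automatic landmark detection; no watershed
splitting of touching particles; recovery-weight accounting is QC only; the
cohort generator's covariance across strategies is a modelling choice, not
an estimate from data.
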