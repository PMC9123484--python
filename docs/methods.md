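# Methods

This note records the models, conventions and numerical choices behind
`perifield`, in the order the pipeline applies them.

## Testing-grid geometry

The wide-field grid is a 185-point radial layout in chart coordinates
(visual-field degrees, x positive toward chart-right, y positive superior).
No published coordinate table exists for this grid family, so the package
uses a documented constructive recipe whose free parameters were solved to
satisfy the known structural constraints:

- **Central 30° disc (108 points):** five rings at 6/12/18/24/30° carrying
  12/16/20/24/32 evenly spaced meridians that each include the vertical
  meridian (90° and 270°), giving 10 central vertical-meridian points; plus
  two dedicated blind-spot stimulus locations at (15°, −1.5°) and
  (15°, −4.5°) on the anatomic-temporal side, and their nasal mirror images
  as ordinary points.
- **Periphery (77 points):** per-quadrant ring-fans bounded by the
  quadrant-specific maximal eccentricities (55.5° nasal and superior, 67°
  inferior, 80° temporal), plus four axis points — (80°, 0°), (0°, 55.5°),
  (−55.5°, 0°), (0°, −67°) — that realise the extents exactly. The fans give
  21 superotemporal, 16 superonasal, 16 inferonasal and 20 inferotemporal
  points strictly inside their quadrants.

Subfield classification is by eccentricity (central iff ≤ 30°) and the sign
of (anatomic-temporal x, y) otherwise. Boundary tie-breaks are
deterministic: peripheral points exactly on a **horizontal** meridian belong
to the inferior quadrant of their side; peripheral points exactly on the
**vertical** meridian belong to the temporal quadrant of their vertical
side. With these rules the subfield cardinalities are 108/22/17/22/16.

Central hemifield masks drop the 10 vertical-meridian points, the 2
blind-spot points, and the blind spots' 2 nasal mirror images (so the two
hemifields stay point-for-point comparable), leaving 47 points per
hemifield; the construction enforces the identity
`n_vertical + 2 · n_blind = 14`.

The left-eye grid is the mirror image of the right-eye grid about the
vertical meridian; anatomic labels (nasal/temporal) are defined through the
laterality, so subfield membership is identical per point id in both eyes.
The canonical OD coordinate table ships as package data
(`perifield/data/grid_od.csv`) and is regenerated bit-identically by
`build_grid`.

## Reliability

The reliability factor of a test is RF = (false positives + false
negatives) / catch trials; RF is undefined (an error) when no catch trials
were presented. Filtering excludes exams with RF **strictly greater** than
the threshold (default 25 %); boundary values are kept. Exclusion is
monotone in the threshold, and the model's fit logs every excluded exam with
its RF.

## Sensitivity averaging

All averaging is on the decibel scale (consistent with perimeter output;
linear-scale cd/m² averaging is out of scope).

- **Overall mean sensitivity (OMS):** arithmetic mean over all non-blind-spot
  points (183 of 185). Blind-spot locations measure no retinal function and
  are excluded from every sensitivity average.
- **Subfield / hemifield means:** geometric mean by default, with an explicit
  `method` flag for arithmetic averaging. The coexistence of arithmetic OMS
  and geometric regional means mirrors standard practice in this analysis
  family; both are first-class.
- **Zeros in geometric means:** the low-level default is zero-inclusive (one
  floored point makes the geometric mean 0 — the literal reading). An
  explicit `zeros="exclude"` policy drops floor points first. The model
  layer uses exclude-zeros for its subfield and per-subject hemifield
  tables, because zero-inclusive geometric means collapse whole regions to
  0 in floor-dominated fields and published regional means in such cohorts
  are plainly nonzero. The choice is always visible in the call signature.
- **Hemifield comparison:** per-subject temporal and nasal hemifield means
  over the 47-point masks; the difference is reported temporal − nasal and
  tested with a two-sided paired t-test. The composite-map variant
  (geometric mean of cohort-averaged pointwise values) is also reported.
  Note that for an *additive* dB offset the geometric-mean difference is
  inflated by value spread (d GM(v+c)/dc = GM/HM ≥ 1), so recovery of the
  generator's configured additive offset is checked on the arithmetic scale,
  where it is exact in expectation.

## Hill-of-vision volumes

Chart position is interpreted as a polar azimuthal-equidistant projection of
the viewing sphere: θ = eccentricity (radians), φ = meridian. Scattered
pointwise sensitivities are interpolated piecewise-linearly on a Delaunay
triangulation (no extrapolation beyond the convex hull) and rasterised onto
a regular lattice (default 0.5°/cell). Each cell carries the solid angle
`sin θ / θ · (π/180)² · Δx · Δy` steradians (the projection Jacobian at the
cell centre), and a region's volume is Σ value × solid angle, in dB-sr.

Numerical choices:

- **Canonical triangulation frame.** The ring layout contains many
  co-circular point sets, so the Delaunay triangulation is not unique;
  triangulating in anatomic coordinates (temporal x positive) and mirroring
  the raster back for left eyes makes fellow-eye volumes exactly symmetric.
- **Region masks with sub-cell fractions.** Cells crossing a region boundary
  contribute fractionally, via 4×4 per-cell sub-sampling. Every sub-sample
  point is assigned to exactly one subfield, so the five subfield fractions
  partition each cell and regional volumes sum to the total volume to
  machine precision. Against closed forms, a 30° cap integrates to
  2π(1 − cos 30°) ≈ 0.8418 sr within ~2·10⁻⁵ relative, and a cone profile
  matches independent quadrature within ~0.1 %.
- **Resolution.** 0.5° keeps quadrature error well below 1 % at negligible
  cost; halving the resolution changes the hull solid angle by < 0.01 %.
- **Blind-spot nodes** enter the triangulation as geometry with their
  measured (typically 0 dB) values.

## Agreement statistics

Bland–Altman agreement uses differences **second − first** (later test minus
earlier), sample SD (n − 1), limits of agreement mean ± 1.96 SD and
CoR = 1.96 SD. The 1.96 multiplier is fixed — no small-sample t-quantile
correction — so the identity CoR = half the LoA width holds exactly.

Pointwise repeatability pools per-point differences (optionally across
subjects and eyes); with floor exclusion (default) a point contributes only
when **both** tests measured strictly above 0 dB, since censoring at the
floor otherwise deflates the difference SD. Repeatability pairs are the
consecutive test pairs (1,2) and (2,3) in which both members are reliable.

Interocular symmetry correlates per-subject right- and left-eye values
(subjects with either eye missing dropped pairwise, n ≥ 3), choosing
Pearson's r when Shapiro–Wilk accepts normality for both eyes at α = 0.05
and Spearman's ρ when either eye fails (the conservative either-fails rule).
Bonferroni-adjusted levels α/m accompany multi-measure tables. The
per-eye reference value is the latest reliable test (3, else 2, else 1).

The minimum detectable follow-up interval divides a CoR by an assumed annual
decline rate: the time until expected true change exceeds test-retest noise.

## Synthetic cohort generator

The generator emulates a young-adult X-linked rod-cone dystrophy cohort
undergoing bilateral triplicate testing over two days. Its defaults are the
study conditions the rest of the package is validated against.

Latent structure per subject (all dB):

1. **Age model.** Latent OMS target = `38.6 − 9.0 · ln(age)` + N(0, 2.3²).
   Over ages 20–49 this yields a cohort OMS near 7 dB with ~3.3 dB
   between-subject SD, about half of it age-explained (r² ≈ 0.5). Ages are
   jitter-stratified over the range (uniform marginal, stable spread), so
   cohort-level statistics do not swing wildly between seeds.
2. **Reference profile.** A fixed non-negative profile over the grid:
   central Gaussian island (peak 14 dB, σ = 18°), inferotemporal Gaussian
   island (centre 45° temporal / −35°, σ = 15°) restricted to eccentricity
   > 30° — the drop across the boundary mimics the ring scotoma separating
   central and peripheral islands — and a 2.5 dB base level in the two nasal
   quadrants (near-floor once scaled). Blind-spot points are 0. The whole
   profile is scaled per subject so the latent OMS equals the target
   exactly. The inferotemporal amplitude is solved in closed form so the
   across-subject slope of inferotemporal on central arithmetic subfield
   means equals the configured coupling (default 1) on the latent scale.
3. **Temporal advantage.** A constant +2 dB added to the 47 central
   temporal-hemifield points (not scaled with severity), the only latent
   nasal-temporal asymmetry.
4. **Eyes.** The left eye mirrors the right with an eye-level OMS
   perturbation N(0, 0.5²). With the single-test OMS noise this implies an
   interocular Pearson correlation of ≈ 0.97 by variance components, and a
   mean absolute interocular OMS difference near 0.6 dB.
5. **Tests.** Each test adds a global shift N(0, 0.3²) and i.i.d. per-point
   noise N(0, 1.5²); test 1 is additionally degraded by a −1 dB learning
   offset and 1 dB extra per-point noise (so limits of agreement narrow from
   pair (1,2) to pair (2,3)). Values are clipped to [0, 50] dB; the 50 dB
   ceiling stands in for a wide dynamic range that real fields do not
   approach.
6. **Reliability.** 20 catch trials per test. Reliable tests draw
   RF = 0.25 · Beta(2, 8); a configurable forced-unreliable pattern defaults
   to five tests (three right-eye tests plus one left-eye test in one
   subject, and one test in another), so the default 60-exam cohort filters
   to exactly 55 with four exclusions concentrated in a single subject, and
   one eye ends up with no reliable test at all (missing, not zero, in the
   cohort table).

Randomness: one master seed; subject-level draws (ages, severity residuals,
eye deltas, refraction, acuity noise) come from the master stream in that
fixed order, then one spawned child stream per subject supplies test noise
and RF draws.

**What the generator does not emulate:** device thresholding staircases and
their quantisation, fixation losses and fatigue drift within a test, eyelid
artefacts in the superior field, spatial correlation of test-retest noise,
and longitudinal progression. Passing recovery tests therefore demonstrate
that the *analysis* is consistent on data with the assumed structure, not
that real perimetry satisfies those assumptions.

## Parameter-recovery checks (fixed seed, n = 200)

- Pooled pointwise CoR between tests 2 and 3 recovers
  1.96·√2·√(σ_point² + σ_global²) within 5 % (floor censoring leaves the
  estimate a few percent conservative even with floor exclusion — the same
  bias direction the exclusion rule exists to limit).
- The arithmetic hemifield comparison recovers the +2 dB temporal offset
  within 3 SEM; the age regression recovers the −9 dB/ln-year slope within
  3 SE; the inferotemporal-vs-central subfield slope lands within 0.15 of
  the configured coupling 1; the interocular correlation matches its
  variance-components closed form within 0.02.

## Problem sizes and determinism

Default analyses run a 10-subject bilateral triplicate cohort (60 exams);
recovery checks use 200 subjects. Volume rasters are 0.5°; every simulation
is reproducible from its seed, and `fit()` on identical inputs is
byte-identical.

## Known limitations

- Grid coordinates are a faithful *family member*, not a replica of any
  proprietary device grid; only the structural constraints are guaranteed.
- Geometric means of floor-containing regions depend strongly on the zero
  policy; both policies are provided and the choice is explicit.
- Volume values depend (weakly) on raster resolution and (through the
  convex hull) on the grid extents; comparisons should hold these fixed.
- The 1.96 multiplier understates limits of agreement for very small n;
  it is retained for comparability with the standard reporting convention.
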