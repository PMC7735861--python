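# Methods

This note records the models, conventions and design choices behind
`cst_recovery`, in the order the pipeline runs.

## Tract-injury scoring

A lesion and a tract atlas are binary masks on a shared voxel grid with
axis 0 lateral (left–right), axis 2 longitudinal (inferior–superior,
increasing index = superior).  The tract's occupied longitudinal extent is
cut into n = 16 half-open slice ranges of equal-as-possible length.  The
slab rule is a convention, not a published formula: when the span is not
divisible by 16 the remainder slices are assigned to the most superior
slabs, one each (a 35-slice tract partitions as thirteen 2-slice slabs
followed by three 3-slice slabs).  Both n and the rule's inputs are
explicit in the API so other dialects can be evaluated.

A subsection is injured when ≥ 5% of its *tract voxels* (not of the slab's
full volume — the subsection is a tract segment) overlap the lesion.  The
comparison is inclusive at the threshold; overlap fractions are exact
rationals k/m, so the implementation adds a 1e-12 guard that cannot flip a
genuinely sub-threshold fraction but protects the k/m = threshold boundary
from float rounding.  The score is injured/16.  Monotonicity (growing a
lesion never lowers the score) and exact agreement with a brute-force
triple-loop counter are enforced by tests.

Laterality uses a half-open midline convention: voxel indices strictly
below the midline index are left, the midline plane itself belongs to the
right.  Any fixed convention works; this one is stated and tested.
Bilateral lesions are flagged and must be excluded by the caller.

## Cohort filters

* Follow-up selection: initial = earliest assessment; follow-up = the
  later assessment minimizing |days − 60| among those ≥ 60 days
  post-onset ("around two months", operationalized as nearest-to-60 over
  the qualifying set), ties toward the earlier date.  No qualifying
  follow-up ⇒ exclusion for incomplete FMA data.
* Ceiling: keep initial FMA-UE ≤ 59 and initial FMA-LE ≤ 27 (strict `>`
  excludes).  The UE cut is 66 − 6.6 (MCID) rounded down; the LE rule is
  applied verbatim as `> 27` even though 34 − 6 = 28 — the discrepancy is
  noted, not resolved.
* Complete injury: score = 1 (16/16) excluded; proportionality of
  recovery to injury cannot be assessed at the ceiling of the injury
  scale.
* Severity stratification: the high stratum is `initial ≥ cut`.

Filters that are logically independent commute, and each returns an audit
whose counts reconcile exactly.

## Regression battery

Standardized coefficients throughout (z-scored outcome and predictors),
so a single-predictor β equals Pearson's r and R² = β².  Binary
covariates are entered 0/1 (male = 0/female = 1, cortical = 0/
subcortical = 1; the coding only affects signs and is recorded).  Partial
correlation residualizes both outcome and predictor on the remaining
predictors; the part (semipartial) correlation residualizes the predictor
only, and part² is the predictor's unique contribution to R² (equal to
the drop in R² when it is removed — the identity the tests enforce
against an independent normal-equations oracle).  Adjusted R² =
1 − (1−R²)(n−1)/(n−p−1).  Two-sided p-values; α = 0.05; no
multiple-testing correction is applied, deliberately mirroring the
screening procedure this battery models.  The multicollinearity check is
the partial correlation of two retained predictors controlling for the
screened-out covariates; collinearity is declared absent iff that
correlation is not significant.

## Subgroup discovery

The initial/follow-up pair is strongly correlated, so the pair is rotated
to principal components before clustering (decorrelation, not dimension
reduction — both components are kept, with their unequal variances
1 ± r preserved; a first-component-only mode would discard the recovery
contrast that separates the severe subgroups).  Sign convention: each
component's largest-magnitude loading is positive.

Ward's method is implemented directly (Lance–Williams update on the
ESS-increase matrix, initialized with half the squared Euclidean
distances) rather than delegated, because the procedure needs fully
deterministic tie-breaking — cost ties resolve toward the lowest
cluster-index pair, so duplicate points merge first — and because tests
compare the merge sequence against an exhaustive-search oracle.  Heights
equal the increase in total within-cluster sum of squares; WSS(1) is the
total sum of squares and WSS(n) = 0.  Agreement with
`scipy.cluster.hierarchy.linkage(..., 'ward')` (heights² / 2) is a test
cross-check, not the implementation.

**Elbow rule.** The default is the knee-point construction: choose k
maximizing the gap between the WSS profile and the chord joining its
endpoints.  The often-quoted max-second-difference rule is available as
an option but is *not* the default, for a structural reason: on nested
cluster hierarchies the WSS drops decay convexly, so the second
difference at k = 2 (first drop minus second) dominates whenever the
coarsest split is the largest — which it always is here (mild vs severe
dwarfs recoverer vs non-recoverer), making that rule return k = 2 on
exactly the three-group structure this analysis must detect.  The chord
rule recovers k = 3 in 100% of simulated cohorts.  Flat or linear
profiles have no elbow: the smallest candidate is returned with a
warning.  The chord rule inherits a mild dependence on k_max (default 8)
through its right endpoint.

**ROC cut-point.** Exhaustive search over the observed initial-score
values; the rule `initial ≥ threshold` predicts membership of the
high-scoring cluster; the threshold maximizes Youden's J
(sensitivity + specificity − 1), ties toward the lower threshold.  The
criterion is a design choice — J is the standard single-number summary —
and the search is provably identical to brute force.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not brain
anatomy.  The template is a small grid (32×32×40 voxels at 2 mm); the
"atlas" is a pair of mirrored tubes, one per hemisphere.  Lesions are
unions of tract-voxel selections targeting an exact score on the 1/16
grid — selected subsections receive ≥ 5% coverage, unselected ones
strictly less — plus an off-tract blob for volume variability.  They are
provably scored, not morphologically realistic.

Patients belong to three latent groups (defaults: mild/ceiling 28/67,
severe-recoverer and severe-non-recoverer ≈ 19.5/67 each, the proportions
a 67-patient cohort with ~14 ceiling exclusions and ~14 high-cluster
members implies).  Scores are truncated, rounded Gaussians conditioned on
group:

* Mild/ceiling initial FMA-UE: a half/half mixture of uniform{60..66}
  (removed by the ceiling filter) and uniform{35..59}, so the filter
  removes ~half of the group (67 → ≈ 52) and the observed mild minimum
  sits at the severity boundary of 35 — which is what makes the ROC
  cut-point identifiable.  Follow-up = initial + 0.7 × headroom + noise
  (proportional recovery), floored at the initial score; no effect
  parameters live in this group, so the floor biases nothing.
* Severe initial FMA-UE: clipped round N(11, 5) on [0, 34].  Follow-up
  follows a linear model whose *population standardized slopes* on
  initial FMA and CST injury equal the CohortSpec parameters
  (`initial_effect` = 0.45, `injury_effect` = −0.35 by default): the
  recoverer/non-recoverer mean offset (±12 points around a center of 34)
  is folded into the scale term, so regressing follow-up on initial and
  injury in the *pooled* severe stratum recovers the effects exactly —
  the target of the parameter-recovery tests.
* CST injury: uniform on {0..15}/16 in every group (plus a 3% rate of
  complete 16/16 injuries that the filter must remove); identical across
  groups so that group membership never confounds the injury signal and
  a zero injury effect yields a null partial correlation.
* Lower extremity: parallel structure on the 0–34 scale with boundary 14
  and ceiling 27, and `injury_effect_le = 0` by default — the lower limb's
  recovery is generated as decoupled from CST injury, the null the
  analysis is expected to find there.
* Demographics (age N(67.8, 15.0), sex 37:30, location 36:31, side
  37:30) and lesion volume (log-normal) are independent of outcome: null
  covariates that probe the screen's specificity.

These defaults were calibrated once, by Monte-Carlo at n = 500, to
satisfy jointly: overall initial→follow-up correlation r = 0.80 ± 0.01
(on the full generated cohort; the post-ceiling analysis cohort shows
r ≈ 0.72), elbow k = 3 in 100% of seeds, ROC cut-point within ±3 of the
generating boundary 35 in ≈ 95% of seeds, follow-up ≥ initial with
probability 0.98, and unbiased recovery of the injury slope
(−0.347 ± 0.047 across seeds against a truth of −0.35).

What the generator does **not** emulate: realistic lesion morphology or
anatomy, measurement error in FMA scoring, correlated demographics,
injury–severity correlation (initial FMA and injury are independent by
construction, unlike real cohorts where they correlate), or missingness
mechanisms beyond a simple missing-follow-up rate.  Passing tests
therefore demonstrate that the *pipeline* recovers known structure, not
that real cohorts have that structure.

## Numerical conventions and degenerate inputs

0-based voxel coordinates and half-open slice ranges everywhere; the
threshold guard described above; constant covariates reported as
undefined-r with a warning rather than an error in the screen (but a hard
error as a regression predictor); rank-deficient designs raise with the
collinear pair named; duplicate points merge first in Ward; identical
class distributions in the ROC step warn (J ≈ 0); empty strata and
single-class inputs raise.  Problem sizes in the test-suite simulations
(cohorts of 500, 100 seeds for recovery rates, masks of ≤ 6×6×20 voxels
for brute-force oracles) were chosen to keep every Monte-Carlo check
well-resolved while the whole suite runs in well under a minute.

## Known limitations

* The slab rule and the "5% of the subsection's tract voxels" reading are
  conventions; other dialects (equal tract-voxel slabs, slab-volume
  denominators) are expressible but not implemented.
* The elbow's chord rule depends mildly on k_max; report the WSS profile,
  not just the chosen k.
* Probabilistic atlases, DTI tractography and native-space images are out
  of scope: masks must already live on a common grid.
* At small n (e.g. a 67-patient cohort) the ROC cut-point is noisy — the
  high cluster's observed minimum drives it; the ±3-point recovery holds
  at n = 500, not at n = 67.
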