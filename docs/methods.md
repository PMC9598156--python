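# Methods

## Study design being modelled

A unilateral cryogenic lesion of the rat thoracic spinal cord (Th13)
produces hind-limb monoplegia; recovery is tracked by the maximum speed an
animal sustains on a treadmill (ceiling 50 m/min, tests at days 7, 14, 21,
30 and 60). Injured animals split into a favorable and an adverse outcome
group by their recovery dynamics. Two quantitative readouts predict that
split: (i) longitudinal MRI lesion volumetry summarized by a 10-grade
severity score and (ii) the plasma cytokine/chemokine panel measured 12 h
after injury. The package re-implements both readouts and the prognostic
construction on top of them.

Because no per-animal raw data are deposited, all inputs are synthesized
from the published facts: per-group analyte summaries (median [min; max],
pg/mL), imaging geometry (0.5 mm axial slices), and the treadmill protocol.
Consequences of this design are flagged throughout this note.

## Synthetic cohorts (`cryosci.synth`)

For each analyte and group the generator pins order statistics: sample
minimum and maximum are set to the published extremes, and the sample median
is made exact — for odd n the middle order statistic equals the published
median; for even n *both* central order statistics are set to it (the
simplest construction guaranteeing an exact sample median). Remaining values
are drawn uniformly, in balanced counts, inside (min, median) and
(median, max). The published summaries are therefore recoverable bit-exactly
from every generated cohort, and any analyte whose printed favorable/adverse
ranges are disjoint separates completely in every cohort, regardless of
seed.

What this does *not* emulate: the true within-group distribution shape (the
study reports none; uniform sub-range fill is an explicit assumption),
between-analyte correlation within an animal (values are shuffled
independently per analyte), and assay noise structure. Tests passing on
these cohorts therefore validate the *logic* of the statistics and the
prognostic construction under the published group geometry, not robustness
to realistic per-animal covariance.

Degenerate summaries are handled explicitly: n = 1 requires
min = median = max; n = 2 requires the median to be the midrange; a
zero-width range produces a constant sample.

## MRI phantoms and quantification (`cryosci.synth`, `cryosci.mri`)

Phantoms are single-channel (T2-weighted-like) grids, default 64×64×48
voxels at 0.25×0.25×0.5 mm — 0.5 mm axial slices as acquired, finer
in-plane, a scaled-down 60 mm field of view. Lesions are analytic
ellipsoids/spheres voxelized by the voxel-centre rule; intensity is a common
background (100 a.u.) plus signed offsets (±40 a.u. for hypo-/hyperintense
lesions, +120 a.u. for cysts) plus seeded Gaussian noise (default σ = 4,
i.e. 10 % of the lesion offset). Ground-truth masks are returned, so any
segmentation can be scored by Dice and any volume against the analytic
4/3·π·abc. Pulse-sequence physics, relaxation times, partial-volume and
bias fields are not modelled; the hypointense focus, hyperintense region and
cyst are placed at craniocaudally separated positions and do not overlap.

Segmentation realizes the study's "semiautomatic threshold mode" as
background median ± k·MAD (k default 5, MAD unscaled) with an explicit
two-threshold override; connected components use face adjacency
(6-connectivity) and components under 5 voxels are discarded as noise. A
constant volume yields empty masks (MAD = 0 plus strict inequalities).
Volumes are voxel count × voxel volume. Ratio conventions for degenerate
volumetry: V_Hypo = 0 with V_Hyper > 0 → "infinite", scored in the top
ratio bracket; both zero → "undefined", scored 0. The study never
encounters these cases; the conventions are ours and are configurable.

The cyst detector is an operational stand-in for the study's visual
criterion ("distinct, round, highly hyperintense"): a hyperintense component
is a cyst when its volume lies in 0.5–20 mm³, its sphericity —
√(λ_min/λ_max) of the covariance of its voxel coordinates in mm, i.e. the
shortest-to-longest axis ratio — is ≥ 0.6, and its median intensity reaches
the 0.9 quantile of the *remaining* hyperintense voxels (a lone component
passes the intensity criterion trivially). All three parameters are
configurable; defaults were chosen so a 1 mm-radius sphere at +3× the lesion
offset is detected under default noise while elongated scar-like ellipsoids
(axis ratio ≥ 3) are rejected.

Severity rubric: the published bracket labels overlap at their printed
boundaries ("<5", "5–10", ">10"). We adopt closed inner brackets so every
value maps to exactly one bracket: hyperintense volume 0 → 0, (0,5) → 1,
[5,10] → 2, >10 → 3; hypointense volume 0 → 0, (0,2) → 1, [2,5] → 2,
>5 → 3; ratio [0,1] → 0, (1,2] → 1, (2,3] → 2, >3 → 3; cyst +1; total
0–10. Whether boundary values scored high or low in the original visual
reading is unknowable; the convention is documented and configurable via
`ScoringRubric`. Note the *total* is deliberately not monotone in V_Hypo
(growing the hypointense lesion can lower the ratio points); monotonicity
holds per criterion.

The pipeline's longitudinal lesion course (per outcome group and day) was
set once to mirror the described dynamics: acute lesions common to both
groups, shrinking with recovery, faster in the favorable group; the adverse
group keeps larger lesions and develops a cyst from day 21. The study's
actual day-60 mean severity scores (3.75 vs 1.16) depend on the real animal
images and are *not* reproduction targets; the pipeline asserts only the
ordering (adverse > favorable at day 60), which holds by construction.

## Treadmill series and outcome labelling (`cryosci.synth`, `cryosci.outcome`)

Synthetic recovery follows a saturating curve plateau·d/(d + t_half) with
t_half ~ U(5, 15) days and mild seeded jitter, made monotone non-decreasing
and clipped to [0, 50] m/min; intact animals run at the ceiling. Default
plateaus: 45 m/min (favorable), 12 m/min (adverse) — chosen so the two
groups bracket the published cohort impression (injured mean 19 m/min)
without targeting it.

The study does not quantify "dynamics of recovery"; the classification rule
here is explicit and configurable: favorable iff day-60 speed ≥ 30 m/min
(60 % of the ceiling) OR least-squares slope over the test days ≥ 0.3
m/min/day, boundaries counting as favorable. The OR-rule is not monotone
under arbitrary pointwise increases (raising only early-day speeds lowers
the fitted slope); it is monotone under constant shifts and whenever the
final-speed criterion decides, which is what the tests assert. The
generator/classifier round trip is exact over 100 seeds at defaults.

## Statistics (`cryosci.stats`)

*Mann–Whitney.* U counts pairs (x > y) plus half the ties. For
n₁ + n₂ ≤ 16 the two-sided p is exact: all C(n₁+n₂, n₁) group assignments
are enumerated on midranks and p is the mass of |U − n₁n₂/2| at least as
extreme as observed — well-defined with ties at these sizes and matching an
SPSS-style exact test in spirit. Larger samples fall back to the
tie-corrected normal approximation. Under the complete separation implied by
the published panel, the exact p is 2/12870 ≈ 1.6 × 10⁻⁴ (8 vs 8) and
2/1287 ≈ 1.6 × 10⁻³ (8 vs 5); the study's printed p values (0.021, 0.014)
evidently come from different software settings and are intentionally not
reproduction targets.

*Median CIs.* Distribution-free order-statistic intervals: the narrowest
symmetric pair (k-th, (n+1−k)-th) whose binomial coverage
1 − 2·BinomCDF(k−1; n, ½) reaches the requested level, else the widest
available with its achieved coverage reported (at n = 8 and level 0.95 the
interval is min–max with coverage 0.9922). Chosen over bootstrap for
determinism at n = 5–8.

*ROC.* Empirical curves over the rule "value ≥ threshold ⇒ positive
(adverse)", AUC by trapezoid; with midrank tie handling AUC·n₁n₂ equals the
Mann–Whitney U (asserted as a cross-check against both a brute-force oracle
and scikit-learn).

*Fold changes* are ratios of group medians, displayed at the study's printed
precision (one decimal below 20, integers above); raw values are retained.

## Prognostics (`cryosci.prognostic`)

*Cutoffs.* Every published decision threshold (221.5, 413, 118, 318, 137,
126.5, 177.5 pg/mL) equals the printed adverse-group minimum, so
"threshold = adverse minimum" is the default rule — an inference from the
printed numbers, documented as such — with the separation-gap midpoint as an
alternative. Cutoffs exist only under complete separation (AUC = 1);
overlapping samples return an explicit not-separable result. Tie convention:
value ≥ threshold ⇒ adverse (the derivation cohort's smallest adverse value
sits exactly at the threshold).

*Marker selection.* An analyte is prognostically significant when (a) its
favorable/adverse groups separate completely (AUC = 1.0, adverse higher) and
(b) its adverse group is shifted above intact (exact Mann–Whitney p < α,
default 0.05, and adverse median > intact median). Criterion (b) is the
minimal published fact distinguishing the study's seven markers from
GM-CSF, whose outcome groups are disjoint but whose adverse levels merely
return to the intact baseline. On pinned cohorts the rule deterministically
selects IL-1α, IL-1β, TNFα, GRO/KC, G-CSF, IFNγ, IL-13.

*IPI.* The study describes the index only as "a linear regression equation"
with decision value 632; its coefficients and regression target are not
published and are not recoverable, so the model here is a re-derivation with
a stated construction: ordinary least squares of the 0/1 adverse indicator
on the marker concentrations (pg/mL), intercept included, decision threshold
at the midpoint between the largest favorable and smallest adverse training
score, adverse called strictly above it. Rank-deficient designs (fewer
animals than markers + 1, or collinear markers) are rejected with guidance
to the ridge fallback (L2 penalty on marker coefficients only). The score is
affine, hence equivariant to per-marker unit changes. The published 632
threshold is on an unknown scale and is deliberately not a target.

## Pipeline determinism (`cryosci.pipeline`)

One master seed fans out through `numpy.random.SeedSequence.spawn` in a
fixed order (cohort, treadmill, phantoms; derived seeds reduced mod 2³¹), so
stages can re-run independently and a report is a pure function of its
`RunConfig` — byte-identical JSON across repeated runs; provenance records
the config hash, seed and package version, never timestamps.

## Problem sizes and numerical choices

Exact-test enumeration is capped at n₁ + n₂ ≤ 16 (C(16,8) = 12 870 subsets,
vectorized over cached index arrays); the default phantom grid is 64×64×48
(~200k voxels); the pipeline images two outcome groups at days 7/30/60.
These defaults keep a full study run under a second while staying at the
study's own group sizes. Floating-point ties in the exact test use a 10⁻⁹
tolerance on the deviation comparison; AUC = 1 is tested against 1 − 10⁻¹²;
uniform draws on a zero-width interval return the endpoint.

## Known limitations

- Uniform sub-range fill and independent per-analyte shuffling are
  assumptions; any statistic sensitive to within-group shape or
  between-analyte correlation (e.g. IPI coefficient values) should be read
  as construction-specific, not biological.
- The cyst detector's three thresholds are operational stand-ins for a
  visual criterion and were not validated against real images.
- Severity brackets at the printed boundaries follow our stated convention;
  alternative readings of the published scale shift scores by at most one
  point per criterion.
- Printed p values, the day-60 mean severity scores, the injured-cohort
  mean speed and the IPI value 632 depend on unavailable raw data or
  software settings and are intentionally out of scope.
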