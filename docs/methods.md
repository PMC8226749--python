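# Methods

`lactoref` implements the complete computational procedure for turning a
multi-farm bovine blood-chemistry panel into phase-specific reference
intervals (RIs): herd welfare scoring and gating, cohort enrollment,
retrospective subclinical-disorder (SCD) exclusion, normality-gated phase
statistics with pairwise testing and phase merging, and nonparametric
bootstrap reference limits. A synthetic herd generator parameterized from
the packaged summary tables makes every stage testable without raw data.

## Study design being modelled

Reference individuals are multiparous Holstein cows from high-welfare herds,
sampled cross-sectionally in one of four lactation phases defined by days
from calving (DFC, 0 = calving day, negative before calving):

| phase | DFC window | extra condition |
|---|---|---|
| dry | −30 … −10 | 30–50 days from dry-phase onset, when known |
| postpartum | +3 … +7 | — |
| early lactation | +28 … +45 | — |
| late lactation | +160 … +305 | confirmed pregnancy |

The panel covers 34 plasma analytes (energy, protein, mineral, liver,
inflammation and oxidant-status markers) with fixed units; the Zn unit
string is stored verbatim from its source table even though µmol/L is the
physiologically plausible reading, and no unit conversion is performed
beyond a display-only retinol factor (µmol/L × 28.645 = µg/100 mL).

## Herd welfare gate

Herd welfare is a weighted pooled mean over a hierarchy
clusters → components → aspects → indicators. Only the cluster level is
fixed by the model — environment 0.3, feeding 0.3, animal 0.4 — so
`ScoreNode` trees represent lower levels generically with user-supplied
weights (sibling weights must sum to 1 within 1e-9). A herd qualifies as
high-welfare iff total > 70% and every cluster > 65%, both strict; the gate
runs before any cow-level processing. Display scores round half-to-even to
integer percent. Because the packaged per-farm cluster scores are
themselves printed as integers, recomputed totals can disagree with a
printed total when they fall within rounding distance of a half point;
fixture tests therefore only assert totals at least 0.4 from a rounding
boundary (herds 3, 8 and 11).

Energy-corrected milk standardizes yield to reference composition:
`ECM = milk × (0.383·fat% + 0.242·protein% + 0.7832)/3.1138`; the
denominator equals the numerator at 4.0% fat / 3.30% protein, making ECM a
fixed point there.

## Enrollment and retrospective exclusion

Enrollment collects *all* violated criteria per animal (no short-circuit):
phase window (with the pregnancy and dry-onset conditions above), parity
2–5, rectal temperature strictly above 39.5 °C, milk drop strictly above
15% of the prior-week mean (lactating phases only; a zero prior-week mean
is an error, not a pass), and non-optimal body condition class. Visual
inspection findings are consumed as a pre-coded class, never inferred.

Retrospective exclusion is evaluated in one pass per phase group:

1. Tukey fences per analyte *within each phase group* — pooling phases
   would mass-flag healthy postpartum animals because phase means differ
   several-fold (e.g. NEFA 0.67 vs 0.11 mmol/L). Fences are
   Q1 − 1.5·IQR / Q3 + 1.5·IQR with quartiles by linear interpolation
   between order statistics (h = (n−1)p + 1, the numpy/R type-7 default);
   the convention is configurable in the sense that the multiplier is a
   parameter and the oracle tests pin the interpolation rule.
2. An animal is excluded when BHB > 1.2 mmol/L (hyperketonemia), Ca <
   2.0 mmol/L (hypocalcemia) — both evaluated in every phase — or when
   strictly more than 3 analytes are flagged (a screen for unspecific
   SCDs). All applicable reasons are recorded.
3. For retained animals, individually flagged values are blanked (set
   missing) for downstream statistics; whole animals are never dropped for
   a within-limit flag count. This is why per-analyte n varies within a
   phase.

Threshold-based exclusion is idempotent on the retained set; outlier
re-flagging after removal is not guaranteed to be (quartiles move), which
the tests assert only for the threshold rules.

## Phase statistics

Normality is gated on moment-based sample skewness g1 = m3/m2^1.5 and
excess kurtosis g2 = m4/m2² − 3 (divisor-n central moments), with a strict
±1.5 limit; analytes breaching it are ln-transformed (the packaged registry
flags BHB, Zn and AOPP). Zero or negative values under the transform are a
validation error — all registered analytes are strictly positive.

Each analyte then gets a one-way fixed-effects ANOVA on phase
(R² = SS_between/SS_total, p from F with (k−1, N−k) df; no farm effect or
covariates by design) and two-sided pairwise t-tests over the six phase
pairs with Holm step-down adjustment (α = 0.05; "p ≤ 0.05 significant" and
"p > 0.05 merges" are complementary, so the boundary is unambiguous).

**SD pooling.** The pairwise t statistic defaults to the classic two-sample
pooled SD of the two compared groups (df = n1+n2−2); pooling the residual
SD across all four groups (df = N−k) is available via
`sd_pooling="all"`. The per-pair default is the package's own design
choice: with heteroscedastic phases (the postpartum SD of fat-mobilization
markers is several times the late-lactation SD) an all-groups pooled SD
inflates the standard error of the homoscedastic pairs enough to erase
comparisons that are unambiguous two-sample effects, while per-pair pooling
plus Holm simultaneously reproduces both the "all pairs differ" pattern of
NEFA and the "no pair differs after adjustment, though the raw dry-vs-late
contrast is nominally significant" pattern of K in the simulation tests.
Holm and raw ("none") adjustment are both exposed.

Phases with adjusted p > α are merged transitively: an edge per
non-significant pair, blocks = connected components. The report writer uses
the display codes *** (p < 0.01) and * (p < 0.1) but the 0.05 rule for
merging decisions.

## Bootstrap reference intervals

For each analyte and merged block, the block's values are pooled (always on
the original measurement scale — nonparametric resampling needs no
normality) and resampled with replacement B times (default 5000). Each
replicate records the (1−coverage)/2 and 1−(1−coverage)/2 sample quantiles
(same h = (n−1)p+1 convention); the reported limits are the means of the
replicate quantiles ("median" available), and each limit's 95% confidence
interval is the 2.5th–97.5th percentile range of its replicate
distribution. The reference fraction (default 95%) and the CI level are
independent settings. Samples under 20 values are refused unless
explicitly overridden. Every phase in a block reports the block's
identical interval.

RNG streams derive deterministically from `(seed, analyte index, block
phase indices)` via `numpy.random.SeedSequence`, so results are
bit-reproducible and independent of evaluation order for a fixed column
layout.

Calibration (measured by the acceptance tests): with a 100 000-value
standard-normal population, samples of n = 500 and B = 2000, the mean
population fraction inside the interval is ≈ 94.7% — the small inward bias
is the usual finite-n property of interpolated sample quantiles — and the
mean limits sit within 0.03 of ±1.96.

## Synthetic herd generator

The generator's defaults *are* the study conditions encoded in the packaged
tables: per-analyte per-phase means/SDs, per-phase reference sample sizes,
and the 11-farm enrollment layout (92/103/84/82 animals per phase, 361
total). Distribution families:

* ln-flagged analytes (BHB, Zn, AOPP): lognormal with exact moment matching
  σ² = ln(1 + sd²/mean²), µ = ln(mean) − σ²/2;
* all others: zero-truncated normal whose *parent* (µ, σ) is solved
  numerically so the truncated distribution reproduces the configured mean
  and SD exactly (plain normal when mean/SD > 6, where the truncated mass
  is < 1e-9). This keeps strictly-positive analytes positive without
  shifting their configured moments, which naive redraw-on-negative
  sampling would do by ≈ 7% for dry-phase NEFA.

Analytes are drawn independently (no published covariance); a correlation
hook is deliberately out of scope. Animal metadata (parity 2–5 uniform,
DFC uniform in window, temperature ~ N(38.6, 0.3) clipped below the fever
threshold, optimal BCS, pregnancy for late lactation) is synthesized to
pass enrollment.

Contamination injects ground-truth SCDs: hyperketonemia draws BHB uniformly
in (1.2, 3.0], hypocalcemia draws Ca uniformly in [1.2, 2.0), and the
multi-outlier pattern pushes 4 randomly chosen other analytes beyond their
phase group's upper fence. Magnitudes are invented plumbing, documented as
such and configurable. Selection is by per-animal rate or by exact
per-phase counts (the pipeline default uses the packaged per-phase
exclusion tallies 16/22/21/17). Because healthy draws can cross the BHB/Ca
thresholds by chance (≈ 2% of postpartum animals for BHB), the screening
stage recovers the injected set exactly up to a handful of such chance
crossers; tests bound both error types rather than asserting equality.

What the generator does **not** emulate: cross-analyte and within-farm
correlation, longitudinal within-cow trajectories, seasonal effects, and
assay measurement error structure. Passing tests therefore demonstrate the
correctness of the screening/statistics/bootstrap machinery under the
published marginal distributions, not field performance on real herds.

## Problem sizes and numerical choices

Default test-suite simulations use the study-condition sample sizes
(n = 63–81 per phase group) with 1000 replicates for the
significance-reproduction checks, 50 repeated samples for bootstrap
calibration, and B = 250–2000 bootstrap replicates in pipeline tests
(B = 5000 in production defaults). Degenerate inputs are defined errors:
zero-variance samples for moments/ANOVA, < 4 values for fences, < 4 animals
per phase group, < 20 values per bootstrap block (overridable), weights not
summing to 1, non-positive values under the ln transform. Ties and
constant vectors collapse fences and intervals to the constant rather than
erroring.

## Known limitations

* The published summary tables (means, SDs, RIs) are not reproducible
  without the study's raw data; they enter only as generator parameters and
  structural fixtures, and the tests assert reproduction of *patterns*
  (significance structure, merged-block equality, bookkeeping) rather than
  their values.
* One printed RI row (Na, dry/early) repeats Ca-magnitude values that are
  physiologically impossible for Na and is excluded from fixture tests as a
  typesetting artifact.
* The hierarchical welfare model below cluster level is represented
  generically; the field checklists behind the indicators are out of scope.
* Exclusion thresholds are marker-specific; unspecific SCDs are only
  screened via the multi-outlier rule, mirroring the study's own caveat.
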