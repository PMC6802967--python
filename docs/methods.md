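# Methods

## Kinetic model

The analysis assumes first-order decay of pre-existing protein in
non-dividing cells. During the chase, old protein is neither synthesized
nor diluted by division, so its fraction of a peptide's total signal is

    f(t) = exp(k t),  k < 0,

and with AR the new/old area ratio of the two isotope channels,

    %old(t) = 100 / (1 + AR(t)) = 100 f(t),
    ln %old(t) = k t + ln 100.

Each peptide's %old timecourse is therefore fit by unweighted ordinary
least squares in log space (`scipy.stats.linregress`), and the protein
half-life is T½ = −ln 2 / k̄ with k̄ the unweighted mean of its retained
peptide slopes. No weighting scheme is applied across peptides, and no
nonlinear (direct exponential) fitting is attempted; the log-linear fit
is the model, not an approximation to a richer one. Day-0 observations
enter as measured rather than being forced to %old = 100, so the
transformation is applied uniformly to every AR. If an input table's
ratio is oriented old/new instead of new/old, `--invert-ar` (or
`read_peptide_table(..., invert_area_ratio=True)`) flips it before the
transform.

## Quality control

Observations are gated per row (profile and regression scores are
row-level quantities in Census-style exports):

| gate | rule | default |
|---|---|---|
| profile | discard if profile score < threshold | 0.8 (strict) |
| extreme AR class | AR < `ar_low` or AR > `ar_high` | 0.111 / 9 (strict) |
| extreme gate | keep iff regression score > threshold | 0 (strict) |
| intermediate gate | keep iff regression score > threshold | 0.8 (strict) |

Boundary ratios exactly equal to 0.111 or 9 are classed intermediate:
"between" is read inclusively and "less than / greater than" strictly,
matching the asymmetry of the stated rules. All inequalities on scores
are strict. A row failing both the profile and a regression gate is
tallied under the profile reason (gates are evaluated in order), which
keeps the QC report's counts additive:
input = retained + profile drops + regression drops.

A peptide-level aggregation mode (scores attached once per peptide rather
than per row) is deliberately not implemented.

## Fit filtering and aggregation

A peptide enters fitting only with observations at ≥ `min_timepoints`
distinct timepoints (default 3), counted **after** QC — only retained
observations demonstrate that a timepoint was usable. Duplicate
(peptide, timepoint) rows — e.g. charge states — are collapsed by the
arithmetic mean of %old before fitting. A fit passes when r² > 0.8
(squared correlation of ln %old with t) and k < 0; flat or rising
timecourses carry no half-life information under the decay model.
Degenerate timecourses (single point, zero time variance) are marked
failed with undefined slope rather than raising.

Aggregation averages only passing fits ("all peptides detected" is read
as "all retained peptides": failed fits have no meaningful slope). With a
single peptide the SD and SEM are reported as 0 and `n_peptides_used`
records the support. Because only k < 0 passes, the mean slope is
negative and every emitted half-life positive; this is asserted, not
re-filtered. A protein with ≥ 3-timepoint coverage but no passing fit is
excluded and counted in the summary.

## Precision window

A chase sampled at days 0–3 cannot precisely resolve half-lives below
1 day (decay mostly complete before day 1, log-linearity deviations) or
above 8 days (slope indistinguishable from zero). Estimates outside
[1, 8] d are flagged `below_window` / `above_window` but retained; the
cohort median is computed over all emitted proteins, flagged included.
The window comparison uses a 1e-12 relative epsilon so a half-life
mathematically equal to a window edge is never reclassified by last-bit
rounding of the fitted slope. The simulator's recovery behaviour
reproduces the window: at the default design the median relative error
inside [1, 8] d is a few percent and the mean error beyond 8 d is
measurably larger (see `scripts/acceptance.py`).

## Group statistics

Mann-Whitney U uses midranks for ties, U_a = R_a − n_a(n_a+1)/2. When
C(n_a+n_b, n_a) ≤ 10,000 the two-sided p is exact: the U null
distribution is enumerated over every assignment of the observed
(possibly tied) values to groups, the one-sided tail doubled and capped
at 1 — the standard two-sided reading of a reported "ns". Larger designs
use the normal approximation with tie-corrected variance and a 0.5
continuity correction. Fully tied data yields p = 1. scipy's
implementation serves as an independent cross-check in the tests (its
exact method refuses ties), never as the computation.

For the domain-size correlation Spearman's rho is primary (half-lives
are heavy-tailed; ranks are robust to that), Pearson's r is reported
alongside. For n ≤ 10 the Spearman p is an exact permutation p computed
by enumerating all n! rank permutations (the rank multiset is
permutation-invariant, so rho reduces to a dot product of centred ranks
and the enumeration is evaluated as chunked matrix products); above that
the usual t-approximation is used. Constant input vectors make the
coefficients undefined; they are reported as None with an explanatory
note instead of propagating NaN. No multiple-testing correction is
applied across group pairs, matching how pairwise "ns" calls are
reported in this setting.

## Topology and extraluminal size

TMHMM long-format output is parsed into segments (inside → side_A,
outside → side_B, TMhelix → membrane; 1-based inclusive coordinates)
that must tile the protein without gaps or overlaps, with consecutive
non-membrane segments alternating sides. Which side faces the ER lumen
is supplied per protein via a YAML map rather than inferred: for
tail-anchored inner-nuclear-membrane proteins TMHMM's inside/outside
labels do not map reliably onto nucleoplasm versus lumen. The
extraluminal size is the summed length of non-membrane segments on the
non-luminal side; by construction extraluminal + luminal + membrane
residues equal the protein length, and flipping the orientation maps one
to the other — both are property-tested.

## Simulator

The generator inverts the analysis equations: per protein a half-life is
drawn (default log-uniform over [0.5, 16] d — wide enough to populate
both flanks of the precision window), k = −ln 2 / T½, and the noise-free
AR at chase time t is (1 − f)/f with f = exp(k t). Observed AR multiplies
that by exp(N(0, σ²)) (ratios are positive and heteroskedastic, so the
noise is multiplicative log-normal; σ = 0.1 default). At t = 0 the true
AR is exactly 0 and stays 0 under multiplicative noise — day-0 rows are
noise-free in AR by construction. Each peptide × timepoint row is dropped
with probability 0.2 (detection dropout), and a fraction 0.1 of rows is
made QC-bad, split evenly between profile-score failures and
regression-score failures; good rows draw both scores from [0.85, 1].
Default design: 200 proteins × 3 peptides × days 0–3. All draws come
from one `numpy` generator seeded from `SimConfig.seed` in a fixed order
(per protein: half-life, peptide count, sequences; per row: noise,
dropout, badness, scores), so tables are byte-identical across runs.

What the simulator does **not** emulate: correlated noise between
peptides of one protein, intensity-dependent score distributions, missed
cleavages, incomplete label incorporation, or non-exponential decay.
Passing recovery tests therefore demonstrates correctness of the
estimator under its own model assumptions, not robustness to every
artefact of real chromatography.

## Image quantification

Frames are 2-D; z-stacks are reduced by maximum-intensity projection
first. The DNA channel is thresholded (Otsu's between-class-variance
rule in `auto` mode — the histogram-based default of common imaging
software — or a fixed value) and connected components become cells. Per
cell, the signal channel is integrated over the mask; the background per
pixel is the mean signal in a user-supplied cell-free rectangle, and the
corrected intensity is integrated − background × area, floored at 0 (a
cell cannot carry negative signal). Normalization divides each cell's
corrected intensity by the mean corrected intensity of a reference
condition (the day-0/no-switch timepoint), so the reference averages 1.
Region ratios (e.g. Golgi vs nuclear envelope) compare
background-corrected integrated intensities of two externally supplied
disjoint masks; a non-positive denominator is an error, not an infinity.
Segmentation of the comparison regions themselves (marker-guided in the
original assays) is out of scope.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use the default design
(200 proteins; 50 for the noiseless closed loop), 100 random timecourses
for the least-squares oracle comparison at 1e-10, 1,000 null simulations
for rank-sum calibration, and 128×128 two-disc image fixtures — sizes at
which every check runs in seconds while keeping estimator behaviour
(attrition, window degradation, calibration) clearly visible. The
null-calibration group sizes (5 vs 7) were chosen because among all
enumerable designs the exact test's attainable level (0.048) sits closest
to the nominal 0.05; exact tests on smaller groups are conservative
enough that their rejection rate could not approach 0.05 for any data.
Ties in the exact enumerations are compared with a 1e-9 absolute slack so
midrank half-integers are never split by rounding.

## Known limitations

- The ≥ 3-timepoint rule counts distinct timepoints after QC; pipelines
  counting raw detections may admit slightly different peptide sets.
- Protein-level aggregation is a plain mean over peptide slopes; no
  mixed-effects model, no inverse-variance weighting.
- No cell-division dilution correction: the model is only valid for
  non-dividing cultures.
- The image module quantifies within supplied or DNA-derived masks only;
  it does not segment nuclear rim from nucleoplasm, fit FRAP recoveries,
  or compute colocalization.
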