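# Methods

## Problem and scope

Parkinson's disease (PD) and the atypical parkinsonian syndromes —
multiple system atrophy (MSA), progressive supranuclear palsy (PSP) and
corticobasal syndrome (CBS) — are clinically hard to separate early.
Spectral-domain OCT with manual layer segmentation shows distinct
retinal signatures across these diseases: PSP thins the outer nuclear
layer (ONL) and the RGC+IPL complex and shows a relatively thick nasal
outer plexiform layer (OPL), while PD thickens the inner nuclear layer
(INL). `parkoct` implements the analysis built on those observations:
cohort handling with the study's measurement conventions, the group
comparison battery, a two-threshold PSP screening rule with two-by-two
screening metrics, and an exhaustive cutoff search — exercised on
synthetic cohorts because no subject-level data were ever deposited.

## Synthetic cohort model

Only per-group means, SEMs and group sizes are published (35 controls,
40 PD, 19 MSA, 10 CBS, 15 PSP; 34 OCT parameters per eye; clinical
covariates per patient group). The generator treats each group's panel
as multivariate normal:

- **Means**: the published group means, taken verbatim from the summary
  table. Where the running text and the table disagree (e.g. control
  ONL 105.9 vs 105.1 µm), the table is canonical and the discrepancy is
  left as is.
- **SDs**: `SEM × sqrt(n_subjects)` with subject-level n. The
  publication does not state whether its SEMs are per subject or per
  eye; subject-level is the conservative reading of its figures
  ("mean of the two eyes of one patient").
- **Between-layer correlation**: not published. Default is exchangeable
  with `rho_layers = 0.3`, a moderate value typical of retinal layer
  panels; a full correlation matrix can be supplied for sensitivity
  analyses (validated for positive semi-definiteness before sampling).
- **Between-eye correlation**: not published. Default `rho_eyes = 0.8`,
  reflecting the strong fellow-eye agreement of retinal morphometry.
  Each eye is `mean + SD·(√rho_eyes·Z_subject + √(1−rho_eyes)·Z_eye)`
  with both Z terms layer-correlated, so per-eye marginals match the
  target mean/SD exactly while the same-layer between-eye correlation
  is `rho_eyes`.
- **Truncation**: thicknesses are resampled (not clipped) below 1 µm
  (volumes below 0.001 mm³) to avoid a point mass at the bound; at the
  published means/SDs this never triggers in practice.
- **Scan quality**: 25 ± 3 dB, resampled above a 20 dB floor so default
  cohorts pass the study's quality filter unchanged; lower the floor to
  exercise QC exclusions.
- **Clinical covariates**: drawn normal from the published clinical
  table, clamped to valid ranges (H&Y to [1,5], UPDRS-III to [0,108],
  durations positive), and independent of the layers — matching the
  reported absence of correlation between disease duration or UPDRS-III
  and any retinal layer. Controls have no published clinical row; their
  age (64 ± 1.5 SEM-scale) is a synthetic age-matched choice, and sex is
  50/50 in every group (matching is reported but ratios are not).
- **Seeding**: one integer seed; per-group substreams via
  `numpy.random.SeedSequence.spawn`, so identical seeds give
  byte-identical cohorts and group draws do not perturb each other.

What the generator does **not** emulate: measurement error structure of
manual segmentation, non-normal tails, the bimodal CBS pattern visible
in the original INL/OPL scatter, any layer–clinical coupling, or
longitudinal change. Consequently, cohort-dependent quantities — above
all the in-sample sensitivity/specificity of the screening rule
(96 %/70 % on the original 119 patients) — are *bracketed* by
simulation, not reproduced: they depend on the unpublished correlation
structure and on the specific cohort draw. Group means, which do not
depend on the correlation choices, are recovered exactly (law of large
numbers; verified at 10⁵–10⁶ subjects within 4 Monte-Carlo SEs).

## Measurement conventions and features

Manually segmented layers (RGC+IPL, INL, OPL) are measured at the
nasal and temporal thickest points and summarized by their arithmetic
mean; a one-sided measurement yields a missing summary. The ONL is
measured at its single central thickest point; when distinct nasal and
temporal maxima exist, the higher value is used. Ratios (ONL/OPL,
INL/OPL) use the mean OPL by default; whether the original ratio used
the mean or the nasal OPL (the component actually thickened in PSP) is
not stated, so an `opl_for_ratio="nasal"` switch provides the
alternative. Ratios with a missing or
non-positive denominator are missing, never infinite. Features are
derived per subject from eye-averaged panels (the figure convention); a
per-eye "duplicates" mode exists for the group statistics, which the
original analysis ran on both eyes as dependent duplicates.

Missing data are excluded per analysis (pairwise), never imputed, and
zeros are rejected as thicknesses at validation time.

## Group statistics

One-way fixed-effects ANOVA; Dunnett's many-to-one test against
controls (p-values from the multivariate-t distribution with the exact
correlation implied by the unbalanced group sizes, via scipy's
integrator with a fixed internal rng for run-to-run determinism; an
independent Monte-Carlo critical-value routine at 10⁶ draws cross-checks
the balanced-design critical point against the classical table value,
2.44 for four comparisons at large df); Tukey's HSD from the
studentized-range distribution; α = 0.05 throughout, configurable. No
correction is applied across the ~40 parameters, mirroring the original
analysis; summary-table flags are exactly "Dunnett-adjusted p < α".
Zero-variance (degenerate) data are reported unflagged with a note
rather than erroring, so SD = 0 sanity cohorts flow through.

Spearman correlation uses average ranks; the two-sided p-value is the
exact permutation probability for n ≤ 9 and the t approximation above.

## Screening rule and metrics

The PSP rule is the conjunction `ONL/OPL < 3.1 AND mean INL < 46 µm`,
both strict. The source never prints the inequality direction; it is
forced by the group pattern (PSP has the lowest ONL and highest OPL,
hence the lowest ratio). Boundary values are therefore negative.
Classification is per subject on eye-averaged features. Subjects
missing a rule feature are excluded from the 2×2 table and logged.

Sensitivity, specificity, LR+ = sens/(1−spec) and LR− = (1−sens)/spec
are kept raw and also rounded for reporting (whole percent; LRs to two
decimals, half away from zero). LR band edges are applied as: LR+ ≥ 50
excellent, [10, 50) good, [2, 10) fair; LR− < 0.05 excellent,
[0.05, 0.1) good, [0.1, 0.3] fair — the half-open convention is a
documented choice, since the verbal definitions ("from 10 to 50") do
not fix inclusivity. LR+ at specificity 1 is +∞; LR− at specificity 0
is undefined and flagged.

The published LR values (0.06 vs PD, 0.07 vs all syndromes) follow
exactly from the printed sensitivity/specificity; the published LR+
values (3.4, 2.4) do not follow from the *rounded* rates (3.2, 2.34),
implying unrounded counts that were not published — the package keeps
raw and rounded values distinct and does not force agreement.

## Cutoff search

Single rules enumerate every decision-distinct threshold (midpoints
between consecutive distinct observed values) in both directions over
the configured base features and pairwise-ratio features; conjunctions
pair two such tests on distinct features. Conjunction grids are
subsampled to ≤ 12 evenly spaced midpoints per feature by default (the
`SearchSpace` grid policy) to bound the quadratic stage at ~10⁵ rules,
computed via boolean matrix products; small instances can run the
complete grid, where the search is tested to agree exactly with a
brute-force enumeration. Ranking is by Youden's J (the optimality
criterion of the original choice is unstated; a sensitivity-first
lexicographic criterion is provided because the rule is used for
rule-out), with deterministic tie-breaks (fewer components, feature
name, smaller cutoff). All results are labelled in-sample
(resubstitution); no cross-validation or optimism correction is
applied, matching the original reporting. ROC bands and bootstrap
optimism correction are possible extensions, deliberately out of scope.

## Problem sizes and tolerances

Generator-recovery checks use 10⁵ subjects per group in the test suite
and 10⁶ in `scripts/acceptance.py`, both with 4-SE Monte-Carlo
tolerances. Family-wise error calibration uses 2000 replicate 5-group
null datasets (n = 20/group) against the binomial 95 % interval around
0.05. The study-sized demonstration cohort is 119 subjects, matching
the published group sizes. Dunnett's integrator is quasi-random; a
fixed internal rng makes p-values reproducible, and cross-ordering
agreement is asserted to 10⁻³.

## Known limitations

- Correlation defaults (`rho_layers`, `rho_eyes`) are assumptions;
  rule-performance numbers on synthetic cohorts shift with them.
- The search space is a documented superset guess of "combinations of
  tests or ratios"; the original space was not enumerated.
- The in-sample rank of the fixed published rule on a *synthetic* draw
  routinely falls below refit rules — its cutoffs were chosen on the
  original cohort and are deliberately not refit.
- No mixed-effects handling of inter-eye dependence (the original
  analysis used none); the duplicates mode inherits that limitation.
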