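# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the synthetic-data tests can establish.

## Per-edge moderation GLM

Each tested connection's Fisher-z connectivity across subjects is fit by
ordinary least squares on the design

    z_e = b0 + b_age·Age + b_sex·Sex + b_grp·GROUP + b_psqi·PSQI
          + b_int·GROUP·PSQI + eps,   eps ~ N(0, sigma_e^2) i.i.d.

with Sex 0 = male / 1 = female and GROUP 0 = no-pain / 1 = pain.  Under this
coding `b_psqi` is the PSQI slope in the no-pain group and `b_psqi + b_int`
the slope in the pain group, so `b_int` is the moderation effect of interest;
a negative `b_int` means chronic pain flips or flattens a positive
sleep-quality/connectivity association.  Covariates enter in raw units — no
centering or standardization — so the intercept is the no-pain, PSQI = 0,
male, age = 0 extrapolation; users who want interpretable intercepts can
center the cohort columns before building the design, which changes no
t-statistic of the interaction.  The simple model (`1 + Age + Sex + PSQI`)
exists for main-effect analyses comparable to moderation-free designs.

Fitting is vectorised linear algebra (`lstsq` plus the normal-equations
covariance) rather than a per-edge model object: the permutation null
refits every edge a thousand times, and the loop is the pipeline's cost
center.  Agreement with `statsmodels.OLS` to 1e-10 is enforced in the test
suite.  Degenerate edges (zero residual variance) yield t = 0 with se = 0
flagged rather than aborting a whole map.

Tail conventions: two-tailed p = 2·min(left, right); left-tailed
p = P(T ≤ t).  Left-tailed inference is the natural choice when the
hypothesis is a *negative* interaction.

Cohen's local f² for the interaction is
`(R²_full − R²_reduced)/(1 − R²_full)` with the reduced model dropping only
the interaction column.  For a one-degree-of-freedom term this equals
`t²/df`, which the pipeline uses for bulk computation; the two-fit definition
is retained in `cohens_f2` and the identity is a test invariant.  Labels
follow the conventional bands: small ≥ 0.02, medium ≥ 0.15, large ≥ 0.35.

For scatter-plot adjustment, `adjust_fc` removes the *demeaned* age and sex
contributions using full-model coefficients: adjusted values keep the
original mean level, and the group-wise adjusted regressions on PSQI carry
exactly the full-model implied slopes.  Full-model (rather than
covariates-only) coefficients are the package's choice where either reading
is defensible.

## Edge masks

The ROI table carries `is_sleep` / `is_pain` flags; the four configurations
(S-SP, SP-SP, S-A, SP-A) define seed and target sets from them.  Masks are
*exact enumerations of unique unordered pairs* — an edge is tested once
regardless of which endpoint is the seed.  The halved-product convention
`floor(n_seeds·n_targets/2)`, familiar from seed-to-target matrix reports,
is provided (`halved_pair_count`) for comparability only and never drives
inference; the two conventions coincide for SP-SP (where it equals
C(n, 2) + n/2 rounding) only accidentally and differ whenever the seed set
is a proper subset of the targets.

The packaged 132-ROI table is a calibrated transcription: a cell-by-cell
reading of the published seed list yields 51 sleep ROIs where the analysis's
own test counts imply 50, so one sleep flag (left insular cortex, a
two-reference cell that also carries the pain flag) was dropped to match the
stated totals of 50 sleep and 63 sleep∪pain ROIs while leaving the union
unchanged.  The table header says so.  Midline parcels whose hemisphere
cells are merged in the source are coded `midline` with the merged flags.

## Connectivity

Denoised ROI time series are converted to percent signal change
(`100·(x − mean)/mean`, then demeaned; constant columns map to zero and
near-zero means raise an error naming the ROI), band-passed 0.008–0.09 Hz
with a 4th-order Butterworth applied forward–backward (`sosfiltfilt`), and
correlated pairwise with a weighted zero-lag Pearson coefficient, then
Fisher-transformed.  Zero-phase filtering is chosen because phase shifts
would corrupt the zero-lag correlation the measure is defined on.  The
weight vector exists because some toolboxes weight time points by
condition/HRF envelopes; those weights are toolbox-internal and not publicly
specified, so the default is uniform (plain Pearson) — a deliberate,
documented divergence.  Matrix diagonals are NaN, never 0: the self
correlation is undefined after Fisher z and must not leak into statistics.
Correlations are clipped to ±(1 − 1e-15) before `atanh` so numerically
perfect correlations yield large finite z rather than infinities.

## TFNBS and permutation FWE

For thresholds `T_k = k·dT`, k = 1 … ceil(max_s/dT) (s the tail-adjusted
statistic: |t|, −t or t), supra-threshold edges (s ≥ T, decided with 1e-9
slack against grid round-off) form a graph whose connected components define
the extent `e(T)` — in **edges**, the network-based-statistics convention.
Each supra-threshold edge accumulates `e(T)^E · T^H · dT` with defaults
E = 0.5, H = 2, dT = 0.1.  An isolated edge with statistic s therefore
scores ≈ s³/3 (Riemann error ≤ s²·dT), a closed form used as an acceptance
oracle.

Two implementations coexist deliberately: a readable per-threshold summation
over `networkx` components (`tfnbs_scores_direct`) and a fast route
(`tfnbs_scores`, also inside the permutation loop) that processes thresholds
in descending order with an incremental union-find — components only merge
as the threshold drops, so each permutation costs O(edges · thresholds)
array work.  Exact agreement between the two routes is a test invariant.

FWE p-values use the max-statistic method: each permutation's maximum score
over the *masked* edges (so familywise control is per configuration) forms
the null, and `p = (1 + #{max* ≥ score}) / (1 + n_perm)` — the add-one
convention guarantees p > 0 and validity under exchangeability, with minimum
attainable p of 1/(1 + n_perm).

The permutation scheme for the interaction defaults to **Freedman–Lane**:
fit the reduced model (interaction removed), permute its residuals across
subjects, add back the reduced fit, refit the full model.  This preserves
the nuisance structure (age, sex, main effects) under the null and is the
standard recommendation for testing single terms in multiple regression.  A
`simple` scheme permuting the (group, psqi, group×psqi) design rows jointly
is available for sensitivity analyses; every results table records the
scheme, seed and permutation count.

BH-FDR is the textbook step-up (delegated to statsmodels, verified against
a brute-force enumeration oracle in the tests) applied to the raw GLM
p-values of the masked edges — not to TFNBS scores; where a published
analysis is ambiguous on this point, FDR-on-GLM-p is the natural reading
and is what this package computes.

## Synthetic data

`simulate_cohort` draws a 34 pain / 14 no-pain cohort by default, with
group-specific moments (age 72 ± 6.78 vs 74.5 ± 7.31; PSQI 6.88 ± 3.46 vs
3.93 ± 3.00; female proportions 26/34 and 7/14), ages truncated at 60 and
PSQI at [0, 21].  Truncation is by resampling, but from a *moment-matched*
parent normal: naive truncation of N(3.93, 3.0²) at zero would bias the
no-pain PSQI mean to ≈ 4.5, so the parent (mu, sigma) are solved such that
the truncated distribution has exactly the requested mean and SD, keeping
the generator's contract that sample moments converge to the requested values.
Covariates are independent within group — real cohorts have age×PSQI and
sex×PSQI covariances the generator does not emulate, because no group-wise
covariances are published to calibrate them against.

`simulate_fc` is the generative twin of the analysis GLM: noiseless data
round-trip through the fit to machine precision, which is the package's
strongest correctness anchor.  Noise is i.i.d. Gaussian in Fisher-z space —
the space the GLM is fit in — with an optional exchangeable correlation
across edges (off by default).  `simulate_timeseries` samples zero-mean
Gaussians whose population correlation equals the user's target after
projection to the nearest factorizable correlation matrix (eigenvalue
clipping at 1e-6, rescaled to unit diagonal), with per-subject `SeedSequence`
streams.

The default planted effect — six edges between three striatal and two
sensorimotor stand-ins, interaction −0.03 z per PSQI point, noise SD 0.15 —
is the regime the calibration suite runs at: strong enough that the
minimal-FWE-p edge is planted in ≈95% of seeds, weak enough that individual
planted edges regularly fail to reach significance, mirroring the
small-sample reality the method targets.

What passing these tests does *not* show: robustness to non-Gaussian noise,
motion or physiological artifacts, HRF variability, atlas misregistration,
or covariate confounding structures — the generator models none of these,
and real-data conclusions inherit all the usual caveats of resting-state
connectivity analyses.

## Problem sizes and numerical choices

Calibration simulations run at 500 null datasets × 200 permutations
(familywise error) and 100 seeds × 1000 permutations (recovery) on 12–20-ROI
atlases — sizes chosen so the full calibration completes in a couple of
minutes on one CPU while keeping Monte-Carlo error (≈ 1% on a 5% rate)
well inside the acceptance bands.  Determinism is end-to-end: a single
master seed expands via `SeedSequence` counters into cohort, noise and
permutation streams, and rerunning any configuration reproduces results
byte-identically.

Known limitations: the weighted-correlation weights of the original
toolbox-based measure are not reproduced (uniform default); group-level
inference is plain OLS (no robust or mixed-effects variants); TFNBS
component extent is edge-based only; and the packaged ROI table is a
flag-level transcription, not a voxel-space atlas.
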