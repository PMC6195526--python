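# Methods

This note records the statistical conventions, simulator models, defaults and
design choices behind `sigscreen`, at the level of detail a user would need
to interpret — or disagree with — its outputs.

## Screen analysis

**Normalisation.** Each sample well's growth inhibition is
`%GI = 100 · (median(NTC) − count) / median(NTC)`, where the NTC median is
taken from the non-targeting-control wells of the *same plate and the same
arm* (vehicle-arm samples against NTC-in-vehicle, drug-arm samples against
NTC-in-drug). %GI can exceed neither 100 nor be bounded below: negative
values mean growth promotion and are reported as such. Replicate experiments
are aggregated by the arithmetic mean per (cell line, gene, siRNA, arm).

**Plate QC.** Z′ = 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg| on raw counts, with
a pass threshold of 0.5 (the conventional "excellent assay" bound). The
positive control enters QC only; it takes no part in normalisation or hit
calling.

**Hit calling (deconvolution rule).** Per cell line a cutoff is set at
mean + k·SD over *all* gene × siRNA aggregated values in that line; a
sequence is significant at or above the cutoff, a gene is significant in a
line when ≥ 2 of its 4 sequences are, and a gene is called when significant
in ≥ 2 cell lines. The multiplier is k = 2 for the vehicle-arm growth screen
and k = 1 for the window screen; both are exposed (`hit_k_sd`,
`window_k_sd`) because either convention is defensible and the two arms of
the analysis historically used different ones. Requiring multiple
independent sequences is the off-target guard that motivates deconvoluted
libraries in the first place.

**Window of efficacy.** `window = GI_drug − GI_vehicle` per (line, gene,
siRNA), in percentage points. Because both arms are normalised to their own
arm's NTC, the drug's own effect cancels and the window of a
Bliss-independent gene is 0 in expectation; a positive window measures
benefit beyond independence on the GI scale.

**Bliss combination index.** For each (line, gene, siRNA, experiment):
f_A = knockdown-alone inhibition, f_B = drug-alone inhibition, f_AB =
combined inhibition, and `CI = (f_A + f_B − f_A·f_B) / f_AB`. CI = 1 at
Bliss independence; CI < 1 is synergy. All three fractions are referenced to
the NTC median of the *vehicle* arm — the untreated baseline the Bliss model
requires — even though display %GI uses arm-matched NTC; both conventions
coexist deliberately. Negative fractions are clipped to 0 (for Bliss only,
never for GI/window reporting) and f_AB ≤ 0 yields CI = +∞, excluded from
aggregation. Per-stratum CI is the mean over replicate experiments with its
standard error.

**CI significance.** Within each cell line the pool is the set of finite
per-stratum (gene × siRNA) mean CIs; the threshold is the empirical
0.05-quantile of that pool (linear interpolation between order statistics)
and a stratum is flagged when its mean CI ≤ threshold. The pool consists of
the same statistics that are flagged, so under a null screen the flag rate
equals the quantile by construction — this is the property that makes the
rule calibrated. (Pooling per-experiment CIs while flagging per-stratum
means would compare a 3-replicate mean against a quantile of noisier single
records and flag far fewer than 5 % of null strata.) A gene-level synergy
call in a line requires ≥ 2 flagged sequences, mirroring the deconvolution
rule; the screen-level synergy selection combines the window rule and the
CI rule, as a window alone (a relative cutoff) always flags a fixed fraction
of a pure-noise line.

## Signature pipeline

**Differential selection.** Per cohort, a two-sided Wilcoxon rank-sum test
per gene between the two subtype groups (robust across platforms), a log
fold change as the difference of group medians (log-scale data), and BH FDR
within cohort. A gene is selected when FDR < 0.05 and |logFC| > 1 in at
least `min_sets = 2` cohorts; genes absent from a cohort's platform count as
non-significant there. The curation step is a case-insensitive whole-word
keyword match over user-supplied annotation text ("cell" does not match
"cellular"); no external annotation retrieval is performed.

**ssGSEA.** Genes of a sample are ranked by expression (average rank for
ties). Walking the list from the most expressed gene, the score accumulates
the difference between the in-set ECDF weighted by rank^α (normalised to 1
over set members) and the uniform ECDF over non-members; α = 0.25. Scores
are compared within a cohort only, so no max–min rescaling is applied. A
constant sample is scored 0 with a warning; set genes missing from the
matrix are dropped and counted. The implementation is checked against a
direct double-loop summation to 1e-9 and is invariant under strictly
monotone transforms of a sample's values (it is a rank statistic).

**Grouping and survival.** 1-D k-means (k = 3, 50 restarts, tolerance
1e-10, fixed seed) on the scores; clusters are relabelled
high / intermediate / low by descending cluster mean, so the label order is
deterministic. Survival comparisons are standard two-group logrank tests
(chi-square, 1 df, hypergeometric tie variance) via lifelines, with
Kaplan–Meier step tables exported. Tertile analyses split samples by ranks
(equivalent to the 1/3 and 2/3 empirical quantiles for distinct values);
ties spanning a boundary are broken by stable sample order with a warning.
Correlation tables report each set gene's Pearson r against the per-sample
set-mean expression (the gene itself included in the mean, as is
conventional for such tables); ANOVA is one-way on set-mean expression by
sample type, types with fewer than 2 samples excluded.

## Growth assay

Confluence curves are normalised by the value at the scan nearest the
drug-addition time (within half a scan interval), which cancels
seeding-density differences exactly — the pipeline is invariant to scaling a
whole experiment's confluence. Relative growth is the pointwise ratio of
replicate-averaged normalised curves, drug over vehicle, per experiment
(vehicle linearly interpolated onto drug timestamps when grids differ);
curves are summarised as mean ± SEM across experiments. AUC uses the
trapezoidal rule over the common time window (window endpoints interpolated,
making AUC additive over adjacent windows and exact for piecewise-linear
curves), and groups are compared by a two-sided t-test on per-experiment
AUCs — Welch by default, Student's available. EC_x fits a four-parameter
logistic (bounded fit, hill slope on dose); when the fitted response never
reaches x % within the tested doses the result is a bound
(`ECx > max dose` / `< min dose`) rather than an extrapolated number, and a
monotone-interpolation fallback covers non-converging fits.

## Mitotic counts

Per well, ratio = post-metaphase / metaphase counts; wells with zero
metaphase cells are excluded (no continuity correction by default — the
ratio-of-counts reading; a log-ratio option exists for the fold-change
test). Averaging is strictly two-level: wells to an experiment mean,
experiments to a grand mean with SEM across experiments — on unbalanced
designs this deliberately differs from pooling wells. Drug-effect fold
changes are ratios of experiment-level means, tested by a paired t-test
across experiments (n = experiments, matching the SEM presentation).

## Synthetic-data generators

All generators are pure functions of `(params, seed)` drawing from a single
seeded NumPy generator.

**Cohort.** Baseline expression per gene ~ N(7, 1) (log2-microarray-like),
unit noise. Aggressive samples (30 % of n = 200 by default) add
`effect_delta` (default 1 log2 unit) plus a shared latent factor with
loading 0.6 to the 48 signature genes; the shared factor is what makes
signature genes mutually correlated, as the correlation analysis expects.
Survival is exponential with baseline hazard 0.02 per time unit and hazard
ratio 3 in aggressive samples; censoring is independent exponential with
its rate solved numerically (Brent) to hit the target 30 % censored
fraction. Sample types are drawn with probabilities conditioned on subtype
(aggressive: 35/40/25 % primary/metastasis/CRPC; normal-like: 85/12/3 %),
so the set-mean expression differs by sample type through its association
with the aggressive subtype — the mechanism in real cohorts — rather than
through an artificial independent shift (a direct per-type shift remains
available and defaults to 0).

**Screen.** 48 genes × 4 siRNAs × 3 replicates × 2 arms per cell line,
laid out row-major over 96-well plates (80 sample wells in columns 1–10,
8 NTC in column 11, 8 positive controls in column 12; every plate carries
controls). Knockdown fraction f = gene effect × siRNA efficacy + off-target
noise (SD 0.02), clipped to [0, 1]; gene effects default to U(0.05, 0.5)
per gene (matching screen-wide mean GI in the 20–25 % range) and siRNA
efficacies to U(0.4, 1). Vehicle-arm survival is 1 − f; drug-arm sample
survival is (1 − f)(1 − d) − β with d the per-line drug effect (0.30, the
EC30 design point) and β the planted Bliss excess, so the planted
combination index is analytic:
CI = (f + d − f·d)/(f + d − f·d + β). Counts are truncated-normal,
mean = μ_NTC × survival (μ_NTC = 2000), SD = cv·μ_NTC
(condition-independent variance; cv = 0.05 default — a continuous
nuclei-count readout with plate-level CV, not Poisson), rounded to
integers; clipping above 10 % of wells triggers a warning. The positive
control knocks down 0.85 of growth, a choice in the range of a strong
mitotic-kinase control. The synergy-recovery simulations are run at
cv = 0.02, the noise level of a validated follow-up assay; plate-level hit
calling and null calibration use the full cv = 0.05.

**Growth.** Logistic confluence C(t) = K/(1 + ((K−C0)/C0)e^(−rt)) with
K = 100 %, C0 = 10 %, r = 0.03 h⁻¹, continued from the drug-addition point
(24 h) with r scaled by (1 − inhibition); scans every 2 h to 120 h, two
images per well averaged, Gaussian measurement noise (SD 1 % confluence),
3 wells per condition, 3 experiments, and a lognormal per-experiment
seeding factor (CV 0.1) that the normalisation must cancel.

**Mitotic.** Per well, total mitotic cells ~ Poisson(λ = 150 by default;
10⁴ for analytic checks) and post-metaphase ~ Binomial(N, p). Default
post-metaphase probabilities plant the metaphase-arrest scenario: drug
lowers p (ratio fold change ≈ 0.6 for control), knockdown + drug lowers it
further (fold change ≈ 0.4), receptor knockdown leaves it nearly unchanged.
At large λ the expected ratio converges to the odds p/(1 − p).

**What the generators do not emulate.** Plate edge effects and spatial
drift, platform batch effects, non-proportional hazards, cell-cycle
phase structure beyond a single binomial split, and image-level artefacts.
Recovery results on these simulations validate the *statistical machinery*
(normalisation, calibration, thresholds, error rates) — they do not certify
performance on real screens, where effect-size distributions and noise are
messier.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for a
single-CPU run: cohorts of 200 samples × 2000 genes, full three-line screens
(4320 wells), 20-seed recovery batches, 6000 null survival simulations at
n = 100 and 100 power simulations at n = 200, 1000-fixture formula-oracle
sweeps. Empirical quantiles use linear interpolation between order
statistics; k-means uses 50 restarts with a fixed seed; BH adjustment is
applied within cohort; all output tables are written with a fixed float
format so identical config + seed gives byte-identical files.

## Known limitations

* The CI significance rule is relative to the screen's own CI distribution;
  a screen in which most genes are truly synergistic would hide its hits.
* The mean + k·SD sequence cutoff is likewise relative; it controls the
  flagged fraction, not a false-discovery rate.
* EC_x values are only as good as the monotone dose–response assumption;
  the 4PL fit reports bounds rather than extrapolating beyond the dose
  range.
* The differential-selection step assumes subtype labels are given; deriving
  the labels themselves (upstream molecular classification) is outside this
  package's scope, and the synthetic cohorts plant them directly.
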