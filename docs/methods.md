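# Methods

## Problem setting

A label-free proteomics discovery cohort (four clinical groups: control
hydrocephalus, low-grade glioma + glioneuronal tumors, embryonal
tumors, other tumors) is screened for candidate CSF biomarkers, and
short-listed analytes are re-measured by ELISA in a larger cohort that
adds a post-haemorrhagic non-tumor group. The package implements the
full statistical path for both arms; everything upstream of the
protein-by-sample intensity matrix (acquisition, identification,
quantification) is out of scope.

## Preprocessing

*Group-validity filter.* A protein is kept when quantified in at least
70 % of the samples of at least one clinical group. The comparison
`present/n ≥ min_frac` is evaluated in exact rational arithmetic (the
threshold is taken at its decimal value), so a protein present in
exactly 7/10 samples passes 0.70 regardless of binary float
representation. The filter is idempotent.

*Transform and normalization.* Intensities are log2-transformed
(strictly positive by construction; zeros were already mapped to
missing at read time, the MaxQuant convention for unquantified LFQ).
Between-sample normalization is per-sample median centering to the
grand median — the least aggressive standard choice, preserving
within-sample ordering — with quantile normalization available behind
`normalize.method`. The order filter → log2 → normalize → impute is
fixed; the source protocol does not state its internal order, and this
one never lets imputed values influence filtering or testing.

*Imputation.* Univariate tests run on observed values only (imputation
distorts per-protein variance); the multivariate stages need a complete
matrix, so missing cells are drawn per sample from
N(μ_s − 1.8 σ_s, (0.3 σ_s)²), where μ_s, σ_s are the sample's
present-value mean and sd — the community "downshifted normal"
convention for left-censored LFQ missingness. Width/shift are
configurable; the draw is seeded.

*Z-scoring* for heatmap export uses the population (divide-by-n) sd per
row; constant rows map to zero rather than NaN.

## Differential testing

Two-group contrasts use Welch's unequal-variance t-test (group sizes
and variances are unequal by design, e.g. 17 vs 29); the four-group
contrast uses one-way ANOVA. Zero-variance ties yield p = 1 rather
than NaN. Multiplicity is controlled by Benjamini–Hochberg step-up
(delegated to statsmodels; an independent brute-force step-up serves as
the test oracle).

The significance gate is the hyperbolic volcano boundary
y = c/(x − x₀) in (|log2 FC|, −log10 p_adj) space with x₀ = 1 (log2 of
the required 2-fold change): a protein is significant when strictly
above the curve *and* p_adj ≤ 0.05. At |log2 FC| = x₀ the threshold is
infinite, so boundary points are non-significant; as c → 0 the rule
reduces to the rectangular gate p_adj ≤ 0.05 ∧ |log2 FC| > 1, and for
any c > 0 the curved set is a subset of the rectangular set. c is a
free parameter (default 0.5); no value is published for it. The curve
is applied to BH-adjusted p by default ("adjusted" is what the cutoff
description names); a raw-p switch exists.

An optional post-hoc power gate (two-sample t power at the observed
Cohen's d, threshold 0.80) is implemented but off by default: the
stated "power of 80 %" plausibly describes design power, not a
per-protein filter, and post-hoc power computed from observed effects
is a deterministic function of the p-value. Enabling it drops
significant proteins with power < 0.80.

## Multivariate ranking and the consensus panel

*MDS.* Classical MDS (principal coordinates via double-centered
eigendecomposition) on the distance 1 − Spearman ρ between samples.
Rank-based, hence invariant under monotone intensity transforms;
negative eigenvalues of the non-Euclidean distance are discarded.

*PLS-DA and VIP.* PLS regression (NIPALS, via scikit-learn) on the
centered one-hot class indicator matrix. Per component a,
SSY_a = (q_aᵀq_a)(t_aᵀt_a) is the class sum of squares captured; the
variable importance in projection is
VIP_j = √( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),
which satisfies mean(VIP²) = 1 identically — asserted on every fit.
Two components by default (the visualization choice); configurable.

*SVM ranking.* The exhaustive "all subject combinations" scheme is
combinatorially infeasible; we use seeded Monte-Carlo over stratified
65/35 learning/test splits (default 200; at least 4, the stated
fold count). Per split an ANOVA F prefilter (p ≤ 0.05) is fitted on
the learning fold only; an RBF-kernel SVM on the surviving features
supplies test-fold accuracy. For the per-feature rank list the default
importance is the mean |weight| of a linear SVM trained on the same
selected features. Permutation importance of the RBF model (the
kernel-faithful choice) is available behind `svm.importance =
permutation`, but it is *not* the default because it is structurally
blind to redundant informative features: in a correlated marker panel
any single member can be permuted without hurting accuracy, so all
markers score ≈ 0. Planted-recovery experiments here showed exactly
that failure (4/50 markers in the top 50, vs 45–48/50 for the weight
ranking). Features never passing the prefilter keep importance 0 and
rank after all selected features, alphabetically.

*Consensus panel.* Candidates are the ANOVA-significant proteins; the
panel is the intersection of the top-k of the VIP ranking and of the
SVM ranking, ordered by the mean of the two rank positions (ties:
higher VIP, then accession). k defaults to the candidate-set size, so
by default the intersection rule alone fixes the panel size — the
published 104-protein panel arises from that study's data, not from a
stated k. A k-means (50 restarts, seeded) adjusted-Rand check against
the clinical labels quantifies cluster agreement on the PLS-DA scores.

## Diagnostics

Per-sample assay value = mean of the technical triplicate; values below
the assay's lower limit of quantification are substituted by LLOQ/2
(the substitution rule is unstated in the source; LLOQ/2 is the common
convention) and flagged. Group comparison: tie-corrected
Kruskal–Wallis; pairwise Dunn z-tests on mean ranks with tie-corrected
variance, Bonferroni-corrected over the pairs of one analyte (Dunn's
correction applied per analyte, not across analytes). All-identical
values are the defined degenerate case H = 0, p = 1. No maintained
installed package provides Dunn's test, so it is implemented here; for
two groups it is checked against the identity z² = H.

ROC: the empirical AUC is the Mann–Whitney rank estimator (ties count
½), auto-oriented to ≥ 0.5 with the direction recorded — analytes lower
in the positive class (TAF15 in tumors) get a "<" decision rule so the
reported cutoff stays in analyte units. p tests AUC = 0.5 by two-sided
Mann–Whitney. The default CI is a seeded stratified bootstrap
percentile interval (2000 resamples); DeLong's closed-form variance is
behind `roc.ci_method = delong`. The published CI method is unstated;
bootstrap was chosen as assumption-light at the table's small n. The
cutoff maximizes Youden's J over midpoints between adjacent distinct
observed values (plus one candidate beyond each end); ties in J break
toward higher specificity, then lower cutoff. Sensitivity and
specificity carry Clopper–Pearson (exact beta) CIs; LR+ =
sens/(1 − spec), +∞ at specificity 1. AUC bands: exactly 0.5 not
discriminant, then [0.5, 0.6) fail, [0.6, 0.7) poor, [0.7, 0.8) fair,
[0.8, 0.9) good, [0.9, 1] excellent.

## Synthetic data: what it emulates and what it does not

*Intensity matrices.* Per-cell log2 intensity = protein baseline
(N(25, 2²) across proteins, the magnitude range of MaxQuant LFQ) +
within-group noise N(0, 1) + a planted shift of `effect_log2` (default
2.0, matching the pipeline's fold-change gate) for marker proteins in
their assigned group; markers are dealt round-robin to the non-control
groups, so a two-group design plants a single tumor signature and the
four-group design gives each group its own third. Cells drop out with
probability expit(22 − x) in x = log2 intensity — missing-not-at-random
censoring of low-abundance proteins (~10–15 % missing overall), which
is what makes the 70 % validity filter consequential. Defaults mirror
the study scale (1789 proteins, 104 markers, 17/11/10/8 samples). No
published intensity distributions exist for this study; these defaults
are plausible, not calibrated to the deposit.

*Assay panels.* Per analyte and group, true concentrations are
log-normal with μ = ln(median) and σ = (ln q3 − ln q1)/(2 z₀.₇₅), the
exact quantile mapping for a log-normal; the packaged defaults are the
published six-analyte median/IQR table with the 68-sample cohort split
(22 + 15 + 11 + 11 + 9). This fit reproduces the configured median
exactly and the quartile *ratio* exactly; the individual quartiles are
recovered only when the printed IQR is log-symmetric, which printed
rounding often breaks. Quartile cells printed with zero width (e.g.
HSP90α, 0.08 in every group) degenerate to point masses — such
analytes cannot discriminate anything in simulation even though the
published assay did (its resolution lies below the printed rounding);
green tests on the simulator therefore establish pipeline correctness,
not assay performance. One printed upper quartile (TMSB4X, embryonal
group) is impossible as printed (below its lower quartile) and is
replaced by the control group's quartile width in the packaged file.
Replicates multiply the true value by log-normal noise with CV 0.05
(the order of the printed assay CV% row); CV 0 gives identical
replicates exactly.

## Reproducibility and numerics

All randomness flows from one integer root seed through named
substreams (crc32 of the stage name mixed into a `SeedSequence`), so
changing the number of draws in one stage never perturbs another.
p-values are clipped to [tiny, 1] before BH; NaN p from zero-variance
rows becomes 1. Percentages print at one decimal with half-up
rounding, matching published tables. Protein groups collapse to their
first accession (full group string kept as metadata); this is exposed
as a rule, with no claim it reproduces the deposited protein count.

## Known limitations

- The published headline counts (241 t-test proteins, 302 ANOVA
  proteins, the 104-protein panel, the six specific biomarkers) require
  the original deposit and upstream settings; the package reproduces
  the procedure and its behavior on planted data, not those numbers.
- The volcano constant c and the SVM importance definition are
  interpretations where the source is silent; both are configurable and
  documented above.
- GO/network enrichment, external database cross-referencing and any
  peptide-level processing are out of scope.
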