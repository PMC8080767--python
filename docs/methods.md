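# Methods

## Scope and data model

The package analyses CpG-level methylation fractions (beta values, β ∈
[0, 1]) for a two-group cohort (responders R vs non-responders NR to
anti-PD-1 therapy), gene-level RNA counts for the same patients, a
regulatory annotation (promoter and enhancer intervals, 0-based half-open;
an enhancer→gene interaction map; super-enhancer intervals; a coding-gene
set), and a per-patient clinical table (response, marker percent
methylation, PD-L1 percent, PFS/OS times and events, covariates).
Normalized beta values are an input contract: array normalization, probe
chemistry and IDAT parsing are out of scope.

## Site filtering and transform

`preprocess.filter_sites` removes a CpG if its detection p exceeds 0.01 in
*any* sample (the conservative per-site reading), if it lies on a
configured sex chromosome, carries a masked SNP with minor-allele
frequency above 0.01, is cross-reactive, or sits in an excluded probe
context. Rules commute, and the removal report counts each rule with
overlap accounting. Testing happens on M-values,
`M = log2((β + ε)/(1 − β + ε))` with ε = 0.01 by default to keep boundary
values finite; the transform is strictly monotone for any fixed ε ≥ 0.

## DMR calling

Per CpG, a Welch t statistic on M-values compares R vs NR
(Welch–Satterthwaite df; group variances floored at 1e-8 and flagged when
degenerate), with BH adjustment across all CpGs and the beta-scale effect
size `delta_beta` = mean β(R) − mean β(NR).

For region detection each statistic is first probit-standardized through
its own p-value, `z = Φ⁻¹(1 − p/2)`, which is exactly N(0, 1) under the
null whatever the per-CpG df — squared Welch t values with ~16 df are
visibly heavier-tailed than χ²₁ and using them directly miscalibrated the
null. The smoothed statistic at CpG *i* is the Gaussian-kernel weighted
mean of z² over neighbours within ±3λ (λ = 1000 bp by default; a CpG with
no neighbours keeps its own z²), referred to a Satterthwaite-matched
scaled chi-square with effective df `1/Σw²` for normalized weights, then
BH-adjusted.

Regions merge consecutive smoothed-significant CpGs (smoothed FDR below
the threshold, default 0.01) separated by at most `gap_bp` (default
1000 bp), require at least 2 CpGs, and must additionally contain at least
that many *anchor* CpGs with raw p below the threshold. The anchor rule
counters kernel leakage: up to three bandwidths from a strong region, CpGs
with no evidence of their own inherit enough borrowed signal to pass the
smoothed threshold and would otherwise surface as spurious satellite
regions; anchoring keeps calls consistent with runs of individually
supported CpGs. A region's `min_fdr` is its minimum smoothed FDR and its
`meanbetafc` the unweighted mean of member `delta_beta` (signed R − NR;
downstream filters use the magnitude). On the package's reference
recovery design (10 planted 20-CpG regions with Δβ = 0.3 among 20,000
null CpGs, 6 vs 12 samples) the caller attains mean recall 1.0 and
precision 0.98 over seeds 1–5, and averages 0.05 called regions per seed
across 20 null seeds — numbers recomputed by the acceptance tests.

## Regulatory annotation

Assignment is any-base overlap of half-open intervals. Elements are first
restricted to those containing ≥1 profiled CpG (`start ≤ pos < end`). A
DMR overlapping a promoter is a pDMR and gains that promoter's gene(s); a
DMR overlapping an enhancer is an eDMR; one DMR may be both, so class
counts can sum to more than the number of distinct DMRs. pDMR targets are
the promoter genes, eDMR targets the union of interaction-edge genes over
overlapped enhancers; both are intersected with the coding-gene set.
Edge-less enhancers contribute nothing and are reported. Super-enhancer
overlap is a per-eDMR flag; per-chromosome summaries report the fraction
of elements hit by DMRs.

## Expression integration

Counts are normalized by median-of-ratios size factors (total-count
fallback when no gene is expressed everywhere, flagged). Per gene, a
negative-binomial model with method-of-moments dispersion pooled within
groups (`α = max(0, (s² − μ)/μ²)`) yields a Wald statistic on the log
ratio of normalized group means, referred to N(0, 1) — the definition of
a Wald test; a heavier-tailed reference was tried and rejected because it
failed to flag genuinely 4-fold-coupled genes at q < 0.01 in the stated
world while the normal reference keeps the null call rate at q < 0.01
near 1e-4 (bound 0.02). `log2fc` uses a pseudocount of 1 on both group
means. All-zero genes are excluded and listed.

DMR-level methylation per sample is the mean beta over the region's CpGs
(the summarization is not otherwise pinned down); expression for
correlation is `log2(normalized count + 1)`, paired on the sample
intersection with n reported. The functional-DMR predicate selects a
promoter DMR iff |meanbetafc| > 0.15; expression moves inversely at least
two-fold with q < 0.01 (hypermethylated ⇒ log2FC < −1, hypomethylated ⇒
log2FC > +1, reading "fold-change < 1/2" on the linear scale); and the
Pearson correlation is negative with two-sided p < 0.05. Inverse coupling
makes the cross-sample correlation negative regardless of the direction
of the methylation shift, so the sign requirement is `r < 0` throughout.

## Enrichment

Over-representation only: `p = P[X ≥ k]` for X ~ Hypergeometric(N, K, n)
with the universe defaulting to the annotation's coding genes, BH across
all sets of the collection. Genes outside the universe are dropped and
counted. Category labels ride along from the GMT description field.
Printed pathway counts from any particular study depend on the tool and
universe used there and are not implementation targets.

## Biomarker evaluation

Prediction direction is fixed: hypomethylation predicts response, so a
marker value at or below the cutoff predicts responder (the boundary
counts as predicted responder). Missing marker values drop the patient
for that marker only. PPV = TP/(TP+FP), NPV = TN/(TN+FN), reported as
missing when the denominator is zero. The cutoff sweep evaluates every
multiple of 5% in [0, 100] and maximizes PPV + NPV with undefined terms
scored 0 and ties broken toward the larger cutoff; the full sweep table
is returned so alternative objectives remain auditable. The combined
classifier predicts response iff every marker is at or below its cutoff,
evaluated on patients with all markers present; the PD-L1 comparator
predicts response iff PD-L1 ≥ 1%. Wilcoxon rank-sum p-values are exact by
enumeration for combined n ≤ 12 without ties, otherwise normal with tie
and continuity corrections; a fully tied comparison returns p = 1. ROC
scores are negated marker values so AUC equals the Mann–Whitney pair
probability with ties half-weighted.

## Survival

Kaplan–Meier is the product-limit estimator over distinct event times;
censored-only times act through risk sets; the median is the first event
time with S(t) ≤ 0.5 and is reported missing when never reached. The
two-group log-rank statistic accumulates observed-minus-expected events
with the hypergeometric variance and is referred to χ²₁. The Cox model
maximizes the Breslow partial likelihood by Newton–Raphson (tolerance
1e-8 on the max coefficient change, 50 iterations, covariates centered);
Wald 95% CIs are `exp(b ± 1.96·se)`. Non-convergence and monotone
likelihoods (coefficients running past ±50, as under perfect separation)
are flagged and carry no silent estimates. Breslow ties are the simplest
consistent choice; with continuous simulated times Breslow and Efron
coincide, which the cross-check against an independent survival library
exploits. Covariate encodings default to age continuous and sex, smoking
and PD-L1 (at 1%) binary.

## Synthetic worlds

The generator's defaults are the stated discovery design: 6 responders vs
12 non-responders, 20,000 CpGs on 4 chromosomes, 200 genes, 100
enhancers. Promoters and enhancers are 1000 bp, laid out without overlap
in randomized slots; CpGs follow a piecewise-homogeneous Poisson process
(~500 bp background spacing, ×5 densified inside elements, echoing how
array probes cluster in regulatory elements), and every element holds ≥1
CpG. Enhancers link to their 2 nearest same-chromosome promoters by
default; 10% are flagged super-enhancers.

Background CpG means follow a bimodal mixture (Beta(2,10)/Beta(10,2)
/Beta(5,5)); planted regions draw baselines so the configured Δβ fits in
[0, 1], shifting the responder mean by Δβ (clipped with a warning if
infeasible). Per-sample noise is Beta-distributed with mean exactly the
group mean and SD 0.08 on the beta scale (a typical within-group
array-level spread; shrunk near the boundaries where that SD is
infeasible). A logit-normal noise model was tried first and discarded:
the inverse-logit is nonlinear, so group-mean differences attenuated and
the generator violated its own contract that planted Δβ is reproduced.
Array features *not* emulated: probe-type chemistry, batch effects,
spatial autocorrelation of the noise, and realistic chromosome-scale
structure — so a green planted-recovery test establishes calibration and
power under independent noise, not robustness to array artefacts.

Expression is gamma-Poisson (NB) with dispersion 0.1, gene baselines
log-normal around 200 counts, and library-size factors spanning exactly
2-fold. Genes whose promoters host planted DMRs are "functional": their
responder mean shifts by ±coupling_strength in log2, opposite in sign to
the methylation change. The clinical simulator centres marker percent 15
points below the cutoff for responders and 15 above for non-responders
(SD 10, clipped to [0, 100]), biases PD-L1 positivity toward responders,
and draws exponential survival with the marker-low hazard scaled by the
configured hazard ratio (default 0.45, the adjusted-HR scale reported for
such markers), baseline median 4 months, administrative censoring at 24
months.

The validation fixture is fully deterministic and synthetic: per-patient
methylation for such cohorts is not published, so the fixture stores
group-level values that reproduce the published predicted-group sizes and
responder counts exactly (56 patients, 25 R; 51 evaluable for CYTIP, 52
for TNFSF8, 49 for both; the full 8-cell joint distribution is documented
in the fixture docstring). Predicted positives sit exactly at the cutoffs
and selected negatives just above (45%/55%) so that the 5% sweep uniquely
selects 40% and 50%; its survival times are synthetic draws favouring the
hypomethylated stratum and support shape checks, not effect-size claims.

## Numerical choices and degenerate inputs

- Variance floor 1e-8 in Welch t; flagged per CpG.
- Probit z capped at 40 before squaring to guard p-underflow.
- BH everywhere via `statsmodels.stats.multitest.multipletests`.
- Kernel window truncated at ±3λ; effective df from normalized weights.
- Pearson correlation undefined (NaN) for constant vectors; those pairs
  are flagged rather than selected.
- Empty classifier denominators yield missing PPV/NPV, never 0/0.
- Determinism: every simulation stream is `default_rng(seed + offset)`
  with fixed per-operation offsets, so operations are reproducible
  independently of call order.

## Known limitations

- The DMR caller is not a re-implementation of published kernel methods'
  internals (no empirical-Bayes moderated t, no Satterthwaite on limma
  statistics); printed genome-wide counts from any specific cohort are
  not reproduction targets at desk scale.
- The DE test has no dispersion shrinkage; at very small n its power
  profile differs from empirical-Bayes tools.
- The enrichment universe and tool choices differ across studies; only
  the hypergeometric arithmetic is asserted.
- Survival omits proportional-hazards diagnostics and multi-state
  structure; the Cox fit assumes non-informative censoring.
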