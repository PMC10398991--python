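# Methods

`neuromethyl` implements a promoter-hypermethylation analysis for
array-style DNA methylation data, centred on one question: are
neural-related genes overrepresented among the genes that gain promoter
methylation in tumors relative to the gene background of the array? The
package provides the differential-methylation caller, the GO string-match
classifier, the enrichment statistics, three confounder analyses, a
differentiation-expression stage, and a synthetic-data generator with
planted truth that makes every stage testable end to end.

## Differential methylation

Testing is done on M-values, `M = log2((β + ε)/(1 − β + ε))` with offset
`ε = 1e−6` (configurable) guarding the endpoints. The M scale is
approximately Gaussian and homoscedastic where the bounded β scale is not;
effect-size filters are nevertheless applied on β, where "10% methylation
difference" has its biological meaning.

Each probe is fit as a two-group comparison (tumor − normal): the
coefficient is the difference of group mean M-values, the residual
variance is the pooled two-sample variance `s²` on `d = n₁ + n₂ − 2`
degrees of freedom. Missing β entries are handled complete-case per probe;
probes left with fewer than two observations in either group are excluded
with a logged count.

Per-probe variances are moderated by empirical Bayes. The prior
`s² ~ s0²·d0/χ²(d0)` is estimated by moment matching on `log s²`: the mean
and variance of `e = log s² − ψ(d/2) + log(d/2)` identify `log s0²` and
`d0` through the digamma/trigamma functions; the trigamma equation is
inverted by Newton iteration. Posterior variances are
`(d0·s0² + d·s²)/(d0 + d)` and the moderated t has `d0 + d` degrees of
freedom. Two degenerate cases are defined explicitly: when the observed
spread of `log s²` does not exceed its sampling expectation, `d0 = ∞` and
every posterior variance equals `s0²` (when all sample variances are
exactly equal, `s0²` is the common value itself — there is no sampling
spread to de-bias); with fewer than 10 usable probes no prior is estimated
and the fit falls back to the ordinary t (`d0 = 0`) with a warning.

Calls use three strict thresholds, all configurable: BH-adjusted p < 0.05,
logFC(M) > 1, and mean Δβ > 0.1 for hypermethylation; mirrored with
negated cutoffs for hypomethylation. The contrast is oriented tumor −
normal throughout, so hypermethylation is a *positive* logFC. A gene is
hypermethylated when at least one of its promoter probes (labels TSS200,
TSS1500 or 1stExon, taken per (probe, gene) pair; optionally restricted to
CpG-island probes) is called; genes with both hyper- and hypomethylated
promoter probes belong to both sets. The background for all enrichment
percentages is the set of genes with at least one *tested* promoter probe.

## Neural classification

A GO term is neural-related when its lower-cased name contains any of 13
pattern strings ("neuro", "neuron", "neuronal", "neural", "nervous",
"axon", "dendritic", "synaptic", "synapse", "learning", "memory", "brain",
"hippocampus") as a substring; a gene is neural-related when annotated to
at least one such term. Substring semantics are deliberate — "neuro" must
match "neurotransmitter" — and bring known false matches ("dendritic
cell", an immune term, matches "dendritic"). Under substring matching
"neuron" and "neuronal" are redundant with "neuro"; a regression test
pins that invariance. Matching uses term names only (no definitions,
synonyms, or ancestor propagation through the GO graph) and the pattern
list is configurable.

## Enrichment statistics

The primary test is the Pearson chi-squared (1 df, no continuity
correction) on the 2×2 table (in-set vs rest of tested background) ×
(neural vs not). Conditioning on the tested background, rather than a
fixed external expectation, keeps the test honest when the tested universe
shifts (e.g. island-only runs); a goodness-of-fit variant against a fixed
proportion would be the alternative reading and can be assembled from the
same counts. When any expected cell falls below 1 the output switches to
Fisher's exact test and flags the row. BH correction is applied across
cancer types within each direction. Hyper-vs-hypo percentage comparisons
across cancer types use a paired two-tailed t-test on the per-cancer
pairs. Generic overrepresentation of a query set in named gene sets (GMT)
is the upper-tail hypergeometric probability P(X ≥ k) with BH across sets.
Odds ratios use the Haldane +0.5 correction only when a cell is zero and
are undefined (error) when a full row or column is zero.

## Confounder analyses

**Tumor purity.** Per tumor sample, mean promoter β is computed for four
gene groups: neural/non-neural × hypermethylated/not-differentially-
methylated. Each group's means are regressed on the sample's tumor-cell
fraction with Huber M-estimation (IRLS, tuning constant 1.345, MAD scale,
coefficient tolerance 1e−8, 50 iterations max — the conventional
defaults), implemented via `statsmodels` RLM. On purity-mixed synthetic
data the HMG-group slopes are positive and the non-DM slopes flat: purity
dilutes a genuine tumor-cell signal rather than manufacturing one.

**Methylation degree.** Per-gene mean tumor β over promoter probes,
compared between neural and non-neural HMGs by two-sided Wilcoxon
rank-sum. The rank-sum choice is this package's (the comparison is
distributional and no specific test is canonical); single-gene sets are
flagged degenerate with p = 1.

**Bivalency.** Cross-tables of hypermethylation × bivalent-chromatin
status over the tested universe, plus hypermethylation × neural status
within the bivalent and non-bivalent strata, each with chi-squared p and
odds ratio. Marginals are asserted to sum to the stratum size.

**Hallmarks.** Within each hallmark gene set (restricted to tested genes),
the 2×2 (HMG vs non-HMG) × (neural vs not) chi-squared, BH-corrected
across the sets.

## Differentiation expression

Log-scale expression is modelled per gene as a linear function of a
two-level condition plus optional covariates (age linear and centred, sex
as a dummy-coded factor); the condition coefficient goes through the same
moderated-t machinery as methylation, which a consistency test pins
exactly. For log-count matrices, optional precision weights follow the
familiar mean–variance-trend construction: an unweighted first pass, a
lowess fit (span 0.5) of the fourth root of the residual variance against
mean log expression, trend evaluation at each observation's fitted value,
and weights `sd⁻⁴`. Genes with logFC > 1 and BH p < 0.05 are upregulated;
the upregulated set of the neurons-vs-progenitors contrast is the
"differentiation-associated" set. The overlap report then gives the
hypermethylated share inside the differentiation set (and inside its
neural subset) with odds ratios against the rest of the tested universe,
and the DR/UR/nonDE composition of hypermethylated neural genes by
differentiation membership.

## Synthetic data

The generator is first-class code: it defines the conditions under which
every recovery claim is evaluated.

* **Universe.** Each gene gets one guaranteed promoter probe plus further
  probes that are promoter or gene-body at random; island flags are
  independent Bernoulli(0.5). Neural genes receive ≥1 GO term whose name
  contains a pattern string, all other genes only pattern-free names, so
  the classifier's correct answer is decidable by construction. A
  configurable fraction of genes is labelled bivalent.
* **Methylation.** Per-probe baseline M ~ Normal(0, 2²); per-probe noise
  variance σ² ~ s0²·d0/χ²(d0) with s0² = 0.25, d0 = 4 (typical M-value sd
  ≈ 0.5, with enough heterogeneity that the empirical-Bayes estimator has
  something to shrink). Planted hyper genes have all their promoter probes
  shifted by +effect_m in the pure tumor signal; hypo genes mirrored.
  Planted probes draw their baseline from the unmethylated mode
  (M ~ Normal(−2, 1); mirrored for hypo): a methylation *gain* must be
  expressible on the bounded β scale, just as cancer hypermethylation
  biologically targets unmethylated CpG-island promoters. The planted gene
  set is chosen so its expected neural share equals the requested
  enrichment; selection odds can be biased per gene set (e.g. 3× for
  bivalent genes). When a purity interval is given, each tumor sample's
  observed β is `purity·β_tumor + (1 − purity)·β_contamination` — a
  cell-fraction mixture on the β scale, not the M scale.
* **Expression.** Gene baselines ~ Normal(6, 1.5²) log2 units with the
  same inverse-chi-squared variance law; differentiation genes shifted by
  +2 (default) in the second condition; 10% of genes carry an age slope
  and 10% a sex offset so covariate adjustment is genuinely exercised, and
  the age distribution can be confounded with condition on request.

What the generator does **not** emulate: Infinium type-I/II probe
chemistry, normalization artifacts, batch effects, copy-number
interference, correlated probes within a region, and the bimodal
cross-probe β landscape of real arrays beyond the planted/unplanted
distinction. Passing recovery tests therefore demonstrates that the
statistics recover the planted structure under the stated noise model —
not that any real cancer type has a particular neural share.

## Problem sizes and numerical choices

The bundled demo simulates 2,000 genes × 2 probes, two cancer types of
12 + 12 samples, and completes in a few seconds; the recovery analyses run
at 20,000 genes × 2 probes with 30 + 30 samples — array scale for genes,
reduced sample counts chosen so that planted power is effectively 1 and
recovered shares are dominated by composition, not sampling noise. BH is
the step-up procedure with monotone enforcement; all three call thresholds
are strict inequalities; the trigamma inversion uses asymptotic endpoints
outside [1e−6, 1e7]; lowess trend values are floored at 1e−6 before
weighting. All randomness flows through a single `numpy` PCG64 generator
per operation, seeded explicitly; reruns are byte-identical.

## Known limitations

Coordinates are never modelled: probe→gene assignment comes solely from
the annotation table. No paired designs, no normalization, no cell-type
deconvolution, no GO ancestor closure. The string classifier inherits the
false matches of substring semantics. The purity analysis takes purity
estimates as given inputs; it cannot distinguish dilution from genuinely
purity-correlated biology.
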