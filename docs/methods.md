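# Methods

## Scope and data model

`straindiff` analyses bulk RNA-seq count matrices from multi-strain,
multi-region designs. The canonical design it targets is a panel of the
eight Collaborative Cross founder strains profiled in three brain
regions (CeA, NAcc, PrL), both sexes, three biological replicates per
strain × region × sex cell (144 samples), multiplexed in three
sequencing batches each balanced for strain, sex and region. All
statistics operate on a genes × samples DataFrame plus aligned sample
and gene metadata tables; nothing upstream of the count matrix
(alignment, counting, sequence QC) is in scope.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions
under which every downstream guarantee is demonstrated.

**Count model.** Counts are negative binomial in the mean–dispersion
parameterisation, Var = μ + φμ². Per-gene dispersions are drawn
log-normally around a central φ (default 0.1, a typical bulk-brain
value; the log-sd defaults to 0.3 and the draw is mean-corrected so the
expected φ equals the configured value). Per-gene baseline log2
relative expression is Gaussian (default mean 3, sd 2), producing the
familiar several-orders-of-magnitude CPM range. Expected log2 means are
baseline + planted strain effect + gene-specific region, sex and batch
offsets (Gaussian with configurable sds; defaults 0.5 / 0.05 / 0.1 on
the log2 scale, putting region ≫ strain-planting ≫ batch ≫ sex, the
ordering real panels show). Relative expression is renormalised within
each sample and scaled to a log-uniform library size, so the expected
total count per sample is exactly the drawn library size.

**Planted structure.** Three planted layers, all recorded in a
`SimTruth` object: (i) *strain-unique* effects — disjoint gene blocks
per strain receiving a ±`effect_size_log2` shift (sign fair-coin) in
that strain, across all regions by default (region-restricted planting
is a config option, since the consensus analysis is per-region either
way); (ii) *shared signature* effects — one block shifted identically
in both designated high-preference strains (B6 and PWK); (iii)
optional *background divergence* — Gaussian per-strain offsets on a
gene fraction, with the wild-derived strains' sd inflated (default 2×)
to mimic their dominant share of fold-change distance. Background
genes belong to no membership set and are excluded from `null_genes`.
Non-chromosomal genes (sentinel chromosome, default 1% of genes) never
carry planted effects, because the preprocessing filter removes them
and recovery metrics would otherwise be undefined.

**Profiles.** The desk profile (default) uses ~5,000 genes and
400–600k expected counts per sample, which keeps a full-design run
under ten seconds; the `full` CLI profile widens this to 15,000 genes
and 8–30M counts. Because per-gene coverage at desk scale is ~30× lower
than in a deeply sequenced study, power for the weakest-expressed genes
is reduced; the sensitivity property below therefore uses a
*depth-matched* profile (2–4M counts over 2,000 genes), whose per-gene
coverage approximates a 25M-read, 15,000-gene experiment.

**Determinism.** One master seed; per-stage child generators are
spawned from a `SeedSequence`, so identical configs give byte-identical
matrices and `simulate_null(cfg)` equals `simulate_counts` with the
planted fractions zeroed.

**What the generator does not emulate.** Gene–gene correlation,
GC/length bias, isoform structure, sample-quality gradients, and
dropout-like zero inflation. Passing tests demonstrate the pipeline's
statistical behaviour under a clean NB world; they do not certify
performance on degraded libraries.

## Preprocessing

**Gene filters.** A gene is retained when (1) its mean CPM across all
samples (raw library sizes — filtering precedes normalization) is at
least 1, (2) no single count exceeds 50,000 (strictly above; 50,000
exactly is kept), and (3) it has a chromosomal location. A gene failing
several rules is reported once, claimed by the first rule in the order
low-CPM → max-count → non-chromosomal. The filter is idempotent.

**log-CPM.** log2((count + c)/(lib + 2c) × 1e6) with prior count
c = 0.5, recorded in output metadata.

**Outlier flagging.** Within each group (per region by default,
configurable to global), each sample's mean Pearson correlation with
the other group members is computed on log2-CPM. A sample is flagged
when its mean correlation falls more than `k_sd` (default 3.0) standard
deviations below the leave-one-out mean of the others' values. The
leave-one-out form matters: with n samples the plug-in z-score is
bounded by (n−1)/√n, so a gross outlier in a small group could never
reach 3 SD if it were allowed to inflate its own reference spread.
Nothing is removed automatically; the report carries z-scores and the
caller decides.

**TMM normalization.** Factors are computed against a reference sample
(the one whose 75th-percentile count fraction is closest to the mean of
those fractions). For each sample, M-values (log2 CPM ratios) and
A-values (mean log2 CPM) over genes positive in both samples are doubly
trimmed (30% of M, 5% of A, rank-based) and the factor is 2 to the
inverse-variance-weighted mean of the surviving M-values, with
delta-method binomial weights. Factors are rescaled to unit geometric
mean (asserted to 1e-8); effective library size = library size ×
factor. On a frozen 20-gene toy the factors agree with an independent
reference implementation of the same definition to 8 decimals. On
balanced null data TMM is a near-no-op (factors within a few percent of
1); its value shows when a few transcripts consume a large share of a
library's depth, which the tests exercise directly. We do not assert
that normalization strictly shrinks median log2-CPM spread on null
data — factor estimation noise can slightly widen it — only that it
corrects genuine compositional bias.

## Differential expression

**Design.** Per region: one coefficient per strain (cell-means coding)
plus treatment-coded sex and batch. Cell-means coding makes every
comparison an explicit weight vector over strain means: pairwise
contrasts are (+1, −1), and the Low_Average contrast weights one
high-preference strain +1 against the six low-preference strains at
−1/6 each (both high-preference strains are excluded from the average).
Rank deficiency (e.g., batch confounded with strain) is detected and
reported with the offending columns. Sex-by-strain interactions are not
modelled: the design is additive, the appropriate default for n = 3
per cell.

**Precision weights.** An unweighted gene-wise fit yields residual
sds; their square roots are smoothed against average log2 count
(lowess, span 0.5) and the trend, evaluated at each observation's
fitted log2 count, is inverted to weights 1/(predicted sqrt-sd)⁴,
floored at 1e-6. Flat planted trends give flat weights; planted
decreasing sd–mean trends give increasing weights.

**Empirical Bayes.** The prior (d₀, s₀²) is moment-matched on
log s²: with e = log s² − ψ(d/2) + log(d/2), solve
ψ′(d₀/2) = Var(e) − ψ′(d/2) (trigamma inverse by Newton iteration) and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). Var(e) ≤ ψ′(d/2) collapses to
the pooled limit d₀ = ∞, s̃² ≡ s₀²; d₀ = 0 is the no-shrinkage limit.
Posterior variances are the df-weighted average; moderated t uses
d₀ + d degrees of freedom (normal when d₀ = ∞). On a frozen seeded
simulation the estimated prior and per-gene statistics agree with a
reference moderated-statistics implementation within 2%.

**TREAT.** For threshold τ, with a = |log2FC| and the moderated SE:
p = P(T > (a−τ)/se) + P(T > (a+τ)/se). τ = 0 recovers the ordinary
two-sided p; p is monotone increasing in τ.

**Global FDR and calls.** BH is applied once to the pooled
(gene, contrast) p-values of a contrast family — all 28 pairwise
contrasts of a region form one family, the two Low_Average contrasts
their own two-contrast family per region — so DEG counts are comparable
across contrasts at the price of the most conservative per-contrast
power. A DEG has global FDR < 0.05. An hDEG additionally has
|log2FC| ≥ 1 and a TREAT global FDR < 0.05; a raw-cutoff variant
(`is_hdeg_simple`, no TREAT test) is emitted alongside because summary
figures in the field use both conventions. Reported log2FCs are always
model-based contrasts of fitted coefficients, not ratios of raw means.

## Consensus sets

All consensus operations are pure functions of DEG tables. Direction is
the sign of log2FC in the contrast oriented strain-minus-comparator;
a significant zero log2FC (possible only pathologically) is treated as
directionless and excluded.

* *Unique DEGs* (strain, region): DE with one consistent direction in
  all 7 contrasts against the other strains.
* *Signature genes* (high-preference strain): the same over 6
  contrasts, the partner high-preference strain ignored entirely — no
  requirement of any kind on the excluded contrast, per the definition.
  Hence unique ⊆ signature for the matching pair.
* *Low_Average DEGs* (relaxed): FDR < 0.05 in the single
  strain-vs-Low_Average contrast, with no fold-change floor.
* *Cross-region common sets*: genes in every region's set with the same
  direction everywhere (direction consistency can be disabled for
  sensitivity analysis). Venn cells are reported for all 2^k − 1
  region combinations, computed independently for up and down members:
  a gene up in two regions and down in the third contributes to the
  two-region cell of the up-venn and the singleton cell of the
  down-venn. Within each direction, cells are exclusive and sum to the
  size of that direction's union.
* *High-preference overlap*: genes in both strains' sets with identical
  direction, per region and intersected across regions.

The *strict* criterion is the signature-gene overlap of both
high-preference strains across all regions; the *relaxed* criterion is
the analogous Low_Average overlap. On strong planted shared effects the
strict set is empirically always contained in the relaxed set — the two
analyses differ only in stringency — and the acceptance harness reports
this containment as a percentage.

## Structure QC

**PCA** is covariance-matrix PCA of samples over gene-centered log2-CPM
(SVD; explained-variance ratios on the 1/(n−1) convention). Factor
association is one-way ANOVA of each leading component's scores on each
categorical factor with an eta-squared effect size, Bonferroni-corrected
across (component × factor) cells — chosen for transparency and
testability over fancier mixed-model attributions. The variance share
of a factor is Σ over components of (explained-variance ratio ×
eta-squared); on generator defaults region's share exceeds strain's,
and strain's exceeds sex's.

**Strain distances.** d(i, j) = Σ_genes |log2FC(i vs j)| — the
Manhattan distance of absolute log2 fold change, which weights every
gene equally rather than further up-weighting large changes as a
Euclidean distance would. Because log2FCs are contrasts of cell-means
coefficients, d is exactly the ℓ₁ metric between strain coefficient
vectors, so symmetry, zero diagonal and the triangle inequality hold by
construction and are asserted over all triples. The gene universe
defaults to all retained genes; a DEG-only option exists (that variant
is not guaranteed metric and is offered for exploration). Agglomerative
clustering uses average linkage by default (complete and single are
available; the choice is a convention, not an inference), and
dendrograms serialise to newick with branch lengths as height
differences.

## Reporting

Circle-grid cells per ordered strain pair: radius = total DEGs over the
grid maximum; color split = up:down ratio (up red, down blue,
configurable); opacity = quartile bin of the hDEG count over all grid
cells, upper quartile brightest, inclusive upper bin boundaries with
ties sharing the higher bin. The figure spec (JSON) is the contract;
SVG/PNG renderings are regenerated from it.

Enrichment is deliberately plain over-representation: one-sided
hypergeometric p per GMT category within a declared universe, BH across
categories. It stands in for ranked external enrichment services and
makes no attempt at GO-DAG semantics.

## Numerical and degenerate-input choices

* Weighted least squares is solved per gene from (XᵀWX)⁻¹ via batched
  inversion; contrast SEs use the unscaled covariance with the
  posterior variance.
* Zero-SE contrasts (constant genes) get p = 1 rather than NaN.
* TMM degenerate cases (no shared positive genes, all M below 1e-6)
  return factor 1; correlation-undefined outlier groups are signalled
  with NaN scores and no flags.
* BH ties follow the standard step-up cumulative minimum (delegated to
  statsmodels).
* All simulation seeds are spawned deterministically from one master
  seed and kept below 2³¹.

## Problem sizes

Default verification runs use 1,000–5,000 genes; the false-discovery
harness uses 20 seeds × 5,000 genes (two strains) and the
strict-vs-relaxed harness 5 seeds × 5,000 genes (full 144-sample
design), sizes at which every quantity of interest is stable to well
under its decision threshold. Effect-recovery and sensitivity
properties pool 10 seeds.

## Known limitations

* The NB world is idealised (no outlier samples unless planted, no
  correlation between genes); FDR control and sensitivity results
  transfer to real data only to the extent the model holds.
* The Low_Average contrast tests a mean of strain means, not a
  pooled-sample re-fit; with balanced cells these coincide in
  expectation.
* TREAT p-values are conservative near the threshold by construction.
* The per-region global-FDR family convention is a modelling choice;
  changing the family changes DEG counts, and the API leaves the family
  to the caller.
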