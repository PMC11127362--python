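# Methods

## Scope and model overview

`prebioresponse` is a desk-scale implementation of a biomarker-discovery
pipeline for prebiotic response: short-chain fatty acid (SCFA) phenotyping
of in vitro fecal fermentations, carbohydrate gene cluster (CGC)
discovery from annotated metagenome catalogs, negative-binomial
differential abundance, qPCR absolute quantification, and RBF-SVM
responder classification with permutation feature ranking. All stages run
on synthetic cohorts with planted ground truth; no external data are
required.

## Phenotyping

The response read-out is the baseline-subtracted acetate+butyrate sum in
mM. Duplicate fermentations are averaged per timepoint before testing
(configurable via `AnalysisConfig.average_replicates`), so each arm
contributes one observation per timepoint. Per subject, each prebiotic
arm is compared with the matched no-prebiotic (NP) arm by Dunnett's
many-to-one test; a subject is labelled responder (R) for a substrate iff
the family-wise adjusted p-value is below α = 0.05 **and** the mean
difference is positive. The Dunnett contrast is treated as two-sided with
an explicit positive-direction gate; both choices are configurable.
Baseline subtraction precedes any normalizing transformation; the
ordered-quantile (rank-based inverse normal) transform
`Φ⁻¹((rank − 0.5)/n)` with average-rank ties is available for modelling
diagnostics and is strictly rank-preserving.

**Dunnett p-values.** The contrast vector (x̄ᵢ − x̄₀)/SE with a pooled
within-group variance is multivariate *t* with one-factor correlation
ρᵢⱼ = λᵢλⱼ, λᵢ² = nᵢ/(nᵢ+n₀). Conditioning on the shared control factor
and the pooled scale factorizes the rectangle probability into a product
of univariate normal CDFs; the two outer integrals are evaluated with
48-node Gauss–Hermite and 96-node Gauss–Legendre quadrature (the latter
against the scaled-chi density of the pooled SD). This is deterministic,
accurate to ~1e-6 (cross-checked against `scipy.stats.dunnett`), valid
for unbalanced designs because the one-factor structure is exact there
too, and reduces *exactly* to the pooled two-sample t-test at k = 1.
Degenerate inputs (zero pooled variance, single-observation arms) raise
errors rather than returning NaN.

The two-way repeated-measures ANOVA (treatment × time, both
within-subject) is delegated to `statsmodels.AnovaRM` after balance
checks; its interaction p-value is what justifies averaging over
timepoints before phenotyping. The test suite verifies the F statistics
against a hand-written sums-of-squares partition.

## Cluster detection and the filter cascade

A CGC is a maximal run of signature genes (CAZyme, transporter TC,
transcription factor TF) on one contig in which consecutive signature
genes are separated by at most `max_gap` = 5 non-signature genes, kept
when it contains ≥ 1 CAZyme and ≥ 1 TC. Gaps are counted in genes (not
bp); TF genes keep a run alive but do not satisfy the transporter
requirement; strand is ignored (mixed-strand operonic clusters exist);
clusters may touch contig ends. Cluster members include the intervening
non-signature genes within the span. Detection is verified against an
exhaustive union-find enumeration on thousands of random contigs.

Substrate specificity is configuration, not code: per-substrate
CAZy-family whitelists (FOS: GH32, GH68; inulin: GH32, GH68, GH91; XOS:
GH8, GH10, GH43 with subfamilies, GH120, plus the broad GH1/GH2/GH3/GH30/
GH51/GH67/GH115 set) followed by an enzyme-name blacklist with EC
mappings (β-glucosidase 3.2.1.21, β-galactosidase 3.2.1.23, β-mannosidase
3.2.1.25, β-N-acetylhexosaminidase 3.2.1.52, arabinan
endo-1,5-α-L-arabinosidase 3.2.1.99) that removes the common false
positives inside the broad families. Genes surviving the cascade with
positive log2 fold change and q < 0.05 are retained, and every cluster
containing a retained gene is selected whole — carbohydrate uptake needs
the intact locus, not one enzyme.

## Differential abundance

Counts are modelled NB2 (Var = μ + αμ²). Samples are normalized with
median-of-ratios size factors; a two-group NB GLM with log link is fitted
per gene by Fisher scoring with the size factors as offsets, and the
group contrast is tested by Wald statistic. Dispersion is a pooled
per-gene method-of-moments estimate on normalized counts (shot-noise
component subtracted, floored at 1e-8) with **no** empirical-Bayes
shrinkage — a deliberate divergence from shrinkage-based tools, justified
because acceptance here is by simulation calibration rather than by
reproducing any particular study's gene lists. The Wald statistic is
referred to a *t* distribution with n−2 degrees of freedom: with
method-of-moments dispersion at n = 15 + 15 the normal reference is
slightly anticonservative, and the t reference puts the empirical type-I
error at 0.048 for nominal 0.05 (simulation, 2000 null genes). Genes with
mean normalized count below 1 are excluded by an independent filter and
flagged, as are all-zero genes; BH q-values are computed across the
tested genes only.

Two caveats verified in the tests: median-of-ratios is equivariant to
single-sample scaling only *relative to the other samples* (the shared
geometric-mean reference moves too), and fold-change estimates are exactly
invariant to such scaling only up to the re-estimated dispersion (a
second-order effect, < 0.01 log2 units in the median).

## qPCR quantification

Copy numbers of standards follow
`copies = conc·10⁻⁹·(1/660)·6.023×10²³·(1/size)·volume`; the Avogadro
constant is deliberately written 6.023×10²³ to match the convention of
the formula as used in the assay sheets this module mirrors. Standard
curves are OLS fits of CT on log10(copies) over ≥ 3 ten-fold dilutions,
with a warning when the slope leaves the amplification-efficiency band
[−3.6, −3.1] CT/decade. Unknowns invert the curve; values outside the
calibration range are flagged extrapolated. Non-detect wells are an
explicit sentinel (NaN in memory, "ND" on disk), never CT = 0, and
contribute 0 copies to downstream feature matrices — a non-responder
without the locus genuinely has zero assayable copies.

## Classification and feature ranking

Features are log10(copy number + 1), z-scored with training statistics
only. Hyperparameters: C ∈ {2⁻², …, 2⁶}; the RBF width σ is the median
pairwise distance of the standardized training matrix times
{¼, ½, 1, 2, 4}, with γ = 1/(2σ²). The grid is searched by mean AUC over
stratified 5-fold cross-validation repeated 10 times (the repeat count is
configurable; at ~20 training subjects more repeats only smooth fold
noise), and the winning pair is refit on the full training set. AUC uses
the rank-sum identity with ties counting ½, cross-checked against an
O(n²) pair-count oracle.

Permutation importance: for each of `n_models` models (each with its own
stratified 50:50 split and CV seed), the importance of a feature is the
held-out AUC minus the mean AUC over 25 shuffles of that feature's test
column; features are ranked by the mean across models. Test-set AUC (not
CV AUC) is permuted — the held-out half is the only unbiased surface.
Shuffling a constant column is the identity, so constant features get
exactly zero importance. With several redundant planted features, each
individual importance is small (the others compensate) but remains
strictly positive, while phenotype-independent decoys sit at exactly
zero; the planted-above-decoy ranking is the tested contract.

## Feeding-trial stage

Predicted phenotypes stratify subjects: single-substrate responders get
that substrate; multi-substrate responders are assigned balance-greedily
(seeded) among their predicted substrates so responder arms differ by at
most one subject when feasible; all-non-responders receive XOS as the
null-response control arm. Pre/post comparisons are paired t-tests (zero
difference variance is an error, not a p-value). Shannon diversity uses
natural log. Bray–Curtis dissimilarity feeds a PCoA implemented directly
(Gower double-centering + symmetric eigendecomposition) so that negative
eigenvalues of non-Euclidean inputs are reported uncorrected;
coordinates are checked against scikit-bio's implementation. Gene-profile
ordinations use the same log10(copies+1) encoding as the classifier.

## Synthetic cohorts: what they emulate, and what they do not

The generator mirrors the study design its parameters are named after:
40 donors, duplicate fermentations of FOS/inulin/XOS plus an NP control,
sampled at 12/24/36/48 h (the 12-h dilution-and-transfer cycle appears
only as this sampling grid; no kinetics are modelled).

- **SCFA**: additive Gaussian on baseline-subtracted concentrations —
  subject random intercept (SD 3 mM) + treatment effect + residual
  (SD 3 mM), clipped at 0. Responder arms add Δ = 20 mM to the
  acetate+butyrate sum (non-responders 0); the acetate share of the sum
  is ~0.65. pH decreases and % carbohydrate fermented increases affinely
  with the a+b sum plus noise — only the correlation signs are contract.
  Phenotypes across substrates share an equicorrelated Gaussian copula
  (ρ = 0.5) with responder prevalence 0.6 per substrate.
- **Catalog**: one planted cluster per substrate (four signature genes
  each — 12 planted target genes in total), each on its own contig with
  signature-free flanks so recovery must be membership-exact; background
  contigs draw signatures at configured rates, including decoy CAZymes
  with blacklisted enzyme names, and 6 decoy qPCR targets with no
  phenotype association.
- **Counts**: NB2 with per-sample depth factors ~ U(0.5, 1.5), gene base
  means lognormal(ln 50, 1), dispersion 0.2, and a planted log2FC of 2
  for cluster genes in responder samples of the matching substrate.
- **qPCR**: responder target genes at log10 copies ~ N(3, 0.5);
  non-responders non-detect with probability 0.9, otherwise N(1, 0.5);
  decoys N(2, 0.5) for everyone; CT = 40 − 3.32·log10(copies) + N(0, 0.15).

Variance components of SCFA across subjects are not reported in the
literature this emulates; the defaults were chosen once for clear
separability (Δ ≈ 6–7 residual SDs) rather than realism. Consequently a
passing pipeline demonstrates *correctness of the machinery* — recovery
of planted structure under the stated noise model — not expected field
performance: real cohorts have weaker effects, correlated genes within
real loci, strain-level annotation noise and compositional artifacts
that the generator does not emulate. Every stage is deterministic given
the seed (child seeds are spawned per stage), and `run-all` produces a
byte-identical artifact bundle under a fixed master seed.

## Problem sizes and numerical choices

Default resampling sizes are desk-scale choices of this package: the
pipeline driver uses 10 permutation-importance models with 3 CV repeats,
and the benchmark script uses 10 generator seeds with 10 CV repeats;
heavier settings are one config edit away. Quadrature tolerances
(~1e-6 on Dunnett probabilities), the dispersion floor (1e-8), the
independent filter threshold (mean normalized count ≥ 1) and tie-break
conventions (average ranks everywhere; mergesort for stable importance
ordering) are fixed constants documented at their definitions.

## Known limitations

- The NB Wald test does not shrink dispersions or fold changes; at very
  small n its power profile differs from empirical-Bayes tools.
- Substrate whitelists are a configurable approximation of curated
  family tables, not a complete curation.
- Signal-peptide/topology evidence and taxonomic profiling are consumed
  as annotations only; no annotation engines are run.
- The simulator plants phenotype-linked copy numbers gene-wise
  independently; real loci are inherited as haplotype blocks, which
  would strengthen within-cluster feature correlation.
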