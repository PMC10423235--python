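# Methods

## Model and score

Replication timing is consumed as a numeric track over genomic
intervals (bedGraph; 0-based half-open coordinates throughout the
package). Because RT varies between cell types, the analysis universe
is restricted to *constitutive*-RT regions supplied as a BED; the track
is intersected with them and each output interval inherits the RT value
of its enclosing track interval. The RT value range of the restricted
track is then divided into `n_bins = 4` equal sub-ranges and every
interval is assigned whole (intervals carry a single RT value, so they
cannot straddle a boundary in RT space) to the sub-range containing its
value, left-closed/right-open with the maximum value in the top bin.
Labels E1, E2, L1, L2 run earliest to latest; an `early_is_high` flag
declares the track's polarity (default: higher value = earlier).
Equal-RT-range binning, not equal-genome-mass quartiles, is deliberate:
the resulting bins differ in megabases, and all rates are per-Mb to
compensate.

For a tumor with per-Mb rates `r_b`,

    RT-MRa = log2((r_L1 + r_L2) / (r_E1 + r_E2))
    CA-MRa = log2(r_inactive / r_active)

Zero halves: a pseudocount (default 0.1 mutations/Mb) is added to both
numerator and denominator only when either is zero, keeping scores
finite without perturbing covered tumors. Tumors with fewer than
`min_mutations = 50` constitutive mutations are flagged `qc_pass =
False` and excluded from clustering and downstream tests. Mutations on
contigs absent from the binning are excluded from bin counts but kept in
the per-tumor total, mirroring real cohorts whose RT maps do not cover
every contig.

## Clustering tumors

Tumors are clustered on their 4-vector of per-Mb bin rates with k = 2.
The default divides each vector by its own mean and runs Euclidean
k-means (25 restarts, fixed seed). The normalization cancels mutation
load while *preserving the magnitude* of the early/late contrast — the
quantity that actually distinguishes weak- from strong-association
tumors. Correlation-type distances (1 − Spearman or rank-transformed
Euclidean, both available via `method=`) are affine-invariant on
4-vectors: a tumor with rates (1,1,1.2,1.2) and one with (1,1,3,3) have
identical rank patterns and correlation 1, so such distances are
structurally blind to association strength and cannot recover a planted
weak/strong mixture (adjusted Rand index ≈ 0 in simulation). Clusters
are relabeled so cluster 1 has the lower mean RT-MRa; a cohort of
identical vectors degenerates to a single cluster with a warning.

## Signature association

Contribution matrices (tumors × SBS signatures, rows summing to ≤ 1)
are consumed, not fitted. Three tests:

- **Correlation** (Pearson by default, Spearman optional — the R
  `cor.test` default is assumed where unstated): pan-cancer over tumors
  with contribution > 0; per project only where the project-mean
  contribution exceeds 5%. BH correction runs across signatures within
  each scope (pan-cancer, or each project separately).
- **Kruskal–Wallis** of contribution vs the two cluster labels,
  excluding tumors below 5% contribution. For total n ≤ 8 the p-value
  is computed by exhaustive enumeration over group assignments (the
  chi-square approximation is unusable there); all-tied data returns
  H = 0, p = 1.
- **Subgrouping**: centered contribution vectors are projected on the
  principal components explaining 90% of variance (silhouette in the
  full space is noise-dominated), k ∈ 2..10 is chosen by maximum
  average silhouette width under Euclidean k-means, and RT-MRa is
  compared between each subgroup pair by two-sided Wilcoxon rank-sum
  with BH correction. When even the best silhouette is below 0.25 the
  result carries a `low_separation` flag but is still reported.

## Deleterious-mutation enrichment

Tumors are pooled pan-cancer and the bottom/top 35% by RT-MRa form the
weak/strong groups (`floor(n·0.35)` each, ties broken by tumor id).
Deleteriousness is consumed as a per-record tri-state flag derived from
MAF predictor columns (SIFT "deleterious" OR PolyPhen
"probably_damaging" OR VEP IMPACT "HIGH" → yes; all absent → unknown);
any other consensus rule must be applied upstream.

The binomial null is constructed from the data: `p0 = D_weak /
(D_weak + D_strong)` over all deleterious mutations, so a pathway is
called enriched only beyond the global imbalance between the groups.
Per pathway, the counting unit is a deleteriously mutated (tumor, gene)
pair (a gene counts once per tumor; `dedupe="cohort"` collapses
further); with k weak-group units and n total, `p = P[X ≥ k], X ~
Binom(n, p0)` (so k = 0 gives p = 1 and an empty pathway is flagged
untested). Per gene, mutations are counted instead, and reported counts
are rescaled to events per 100,000 group mutations. BH correction runs
across pathways per run — sub-pathway reruns within a parent are
corrected separately. Group-level covariate checks are one-tailed
t-tests (weak > strong) per project with BH across projects, and a 2×2
chi-square without continuity correction for MSI status. Neoantigen
counting matches consequence strings, after lower-casing and
space/dash→underscore normalization, against the fixed ten-class
protein-altering list.

## Differential expression

Within a project, samples are sorted by RT-MRa and the bottom/top
`floor(n/3)` form the weak/strong tertiles (remainder to mid, keeping
the compared groups balanced; minimum 6 samples). Counts are normalized
by TMM (implemented in-package because no installed Python library
provides it, and cross-checked against Bioconductor edgeR in the test
suite): 30% two-sided trim on M values, 5% on A values,
precision-weighted trimmed mean, reference sample = upper-quartile
fraction closest to the cohort mean, factors rescaled to geometric mean
1. Fold changes and tests operate on log2(CPM + 1).

The DE engine is a per-gene two-sided Wilcoxon rank-sum with midrank
ties; the exact null distribution is used when both groups have ≤ 10
samples and the gene has no ties (count-derived data nearly always has
ties, which the exact distribution cannot accommodate, and exact
computation at larger n buys nothing over the tie-corrected normal
approximation used otherwise). All-tied genes get p = 1. `log2fc` is
the weak-minus-strong difference of group means of log2(CPM+1), so
weak-high genes are positive; significance = BH-adjusted p < 0.1 and
|log2fc| > 1. The experimental-FDR wrapper permutes group labels
(sizes preserved), reruns any conforming DE routine, and declares a
project valid iff the mean randomized significant count is below 10% of
the observed count. Ten randomizations are the default — a single draw
makes the 10% rule high-variance — with `n_randomizations=1`
reproducing the literal single-permutation protocol; zero observed
discoveries yields the verdict "no signal" rather than valid/invalid.

The gene-set bias test computes, per gene, the percentage of projects
whose weak group has the higher mean log2(CPM+1) (group-mean
expression, not DE logFC, is the default reading; both are monotone in
each other per project), recomputes it after randomly re-splitting each
project's compared samples, and runs a paired t-test across genes with
effect size `d = t·sqrt((n1+n2)/(n1·n2))`, `n1 = n2` = evaluable genes.

## Synthetic cohorts

The generator inverts the analysis model so every planted parameter is
recoverable analytically:

- **Genome**: 400 × 1 Mb intervals on synthetic chromosomes, RT ~
  U(0,1) (higher = earlier); 90% of intervals form the constitutive
  set; chromatin is "active"/"active2" above the RT median when
  coupling is on (emulating the tight RT–accessibility alignment of
  real genomes), independent otherwise.
- **Mutations**: per-tumor totals ~ LogNormal(log 5000, 0.4) — enough
  for stable scores at desk scale while spanning a realistic load
  range. Positions are placed by a two-step draw: bin with probability
  ∝ `size_Mb × rate` (rate 1 early, ρ late), then uniform within the
  bin, which makes E[RT-MRa] = log2 ρ exactly rather than emergent.
  ρ follows a two-component mixture, 37% at 1.2 and 63% at 3.0 with
  0.1 log2 jitter — weak tumors as roughly a third of the cohort with
  near-even mutation distribution, strong tumors at the canonical
  severalfold late excess. Each interval hosts one synthetic coding
  gene (G0001…) over its middle half; genic mutations draw a
  consequence class and a deleterious flag (base rate 0.05, tripled for
  one planted pathway's genes in weak tumors). 5% of records are 2-bp
  deletions, the rest SNVs.
- **Signatures**: contribution = softmax(log Dirichlet base +
  β·log2 ρ + noise), scaled just below row-sum 1. Note the closure
  effect: because rows are compositional, a zero-β signature generated
  alongside strongly ρ-linked ones acquires a small spurious
  correlation; the zero-signal contract holds when all β are zero.
- **Expression**: NB counts (dispersion 0.1), gene means LogNormal,
  library sizes LogNormal(0, 0.2); 100 planted DE genes at fold change
  2 and a 50-gene immune-like set (IMM_*) at fold 1.5, both
  up-regulated in the true-weak tertile of each project.
- **Covariates**: age N(60,10), ploidy N(2.1,0.4) clipped to [1,6],
  purity Beta(5,2), MSI ~ Bernoulli(0.03), with an optional purity–ρ
  coupling slope for planted-sign confounder tests.

All randomness flows from one seed through spawned child generators;
outputs are bit-identical across reruns. What the generator does *not*
emulate: trinucleotide context spectra, real gene annotation or gene
length variation, copy-number structure, clonal evolution, and
inter-gene expression correlation — so passing tests demonstrate
correctness of the statistical machinery under the stated model, not
robustness to every artifact of real PCAWG-like data.

## Validation problem sizes

The acceptance battery uses sizes chosen to make every planted effect
decisively detectable while running in minutes on one CPU: 100–200
tumors per planted ratio at 50,000 mutations each for score recovery
(per-tumor sampling error ≈ 0.01 log2 units); 2 × 100 tumors at 5,000
mutations for cluster recovery; 2,000-gene matrices at 20–30 samples
per group for DE calibration and the experimental-FDR rule; 10 projects
of 12 samples for the gene-set bias test; 1,000 catalogs of 10 pathways
(~150 events each) for binomial null calibration, where the discrete
tail makes the rejection rate land slightly below the nominal 5%.

## Known limitations

- The Spearman-distance clustering reading remains available but is not
  the default for the reason given above; on real data the two readings
  may legitimately disagree.
- The binomial enrichment model treats deleterious events as
  independent across tumors and genes; hypermutators can dominate
  `D_weak`/`D_strong` and should be screened via the covariate tests.
- The DESeq2 arm of the original DE comparison is out of scope; the
  experimental-FDR wrapper accepts any routine with the `wilcoxon_de`
  signature so an external engine can be screened identically.
- GO-term enrichment of DE gene lists and immune-cell deconvolution are
  not implemented.
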