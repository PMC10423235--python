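# rtmra

Somatic mutation rates (MR) in cancer genomes normally track replication
timing (RT): late-replicating DNA accumulates more mutations than
early-replicating DNA. Individual tumors, however, vary widely in how
strongly they show this association, and that variation is biologically
informative — it correlates with mutational signatures, DNA-repair
pathway damage and immune-related gene expression. `rtmra` is a Python
toolkit for quantifying and dissecting this per-tumor RT–MR association
in whole-genome tumor cohorts. It is aimed at cancer-genomics analysts
working with per-tumor somatic variant calls (VCF/MAF), signature
contribution tables, and RNA-seq count matrices.

## The statistic

The constitutive-RT portion of the genome is split into four bins of
equal RT-value range, earliest to latest (E1, E2, L1, L2; the bins are
deliberately unequal in megabases). With `r_b` the per-Mb mutation rate
of a tumor in bin `b`, the package's central score is

    RT-MRa = log2( (r_L1 + r_L2) / (r_E1 + r_E2) )

A tumor whose mutations pile up in late-replicating DNA at, say, 4x the
early-replicating rate has RT-MRa = 2; a tumor with an even mutation
distribution has RT-MRa near 0 ("weak association"). CA-MRa is the
analogous log-ratio over inactive vs active chromatin. Around the score
the package implements:

- k-means clustering of tumors on their 4-bin rate vectors into weak
  (cluster 1) and strong (cluster 2) association groups;
- per-project Pearson correlations of RT-MRa with confounders
  (age, mutation load, ploidy, purity);
- signature-contribution association tests (filtered correlation tests,
  Kruskal–Wallis rank tests against the cluster labels, and PCA +
  silhouette-selected k-means subgrouping with pairwise Wilcoxon
  comparisons);
- deleterious-mutation enrichment of pathways/genes in the weak extreme
  (bottom 35% of scores) using a one-sided binomial test whose null
  probability is constructed from the groups' total deleterious-mutation
  imbalance, `p0 = D_weak / (D_weak + D_strong)`;
- Wilcoxon rank-sum differential expression between RT-MRa tertile
  extremes on TMM-normalized log2(CPM+1), screened by a
  permutation-based *experimental FDR* (a project's DE list is valid
  only if label-randomized reruns recover < 10% of it), plus
  cross-project recurrence and a paired-t directional-bias test for gene
  sets with effect size `d = t * sqrt((n1+n2)/(n1*n2))`;
- a synthetic-cohort generator that plants known values of every one of
  these effects (per-tumor late/early ratio rho, cluster structure,
  signature-score coupling, pathway enrichment, DE fold changes) so the
  whole pipeline can be validated against ground truth.

## Worked example

Everything below runs on a synthetic cohort — no access-controlled data
is needed:

```python
import glob
import pandas as pd
import rtmra
from rtmra.simulate import SimulationConfig, simulate_cohort

simulate_cohort(SimulationConfig(seed=42, n_projects=2,
                                 tumors_per_project=15), "demo")

track = rtmra.restrict_to_constitutive(
    rtmra.load_rt_track("demo/rt.bedgraph"),
    rtmra.load_bed3("demo/constitutive.bed"))
bins = rtmra.make_rt_bins(track, n_bins=4)
print({k: round(v, 1) for k, v in bins.bin_sizes_mb.items()})
# {'E1': 92.0, 'E2': 91.0, 'L1': 82.0, 'L2': 95.0}

cov = pd.read_csv("demo/covariates.tsv", sep="\t", index_col=0)
profiles = rtmra.build_cohort_profiles(
    sorted(glob.glob("demo/mutations/*.vcf")), bins,
    projects=cov["project"].to_dict())
table = rtmra.cluster_rate_vectors(profiles, k=2, seed=17)
print(table.head(4).round(3).to_string(index=False))
#    tumor_id project  rt_mra  cluster
# PROJ01_T001  PROJ01   1.682        2
# PROJ01_T002  PROJ01   1.481        2
# PROJ01_T003  PROJ01   1.359        2
# PROJ01_T004  PROJ01   1.743        2
```

The cohort splits into 7 weak-association and 23 strong-association
tumors (the generator plants a 37/63 two-component mixture of late/early
ratios 1.2 and 3.0; `log2(3.0) ≈ 1.58` is where the strong cluster's
scores sit). Enrichment of deleterious mutations in the weak extreme
then recovers the pathway the generator damaged:

```python
mafs = {p.split("/")[-1][:-4]: rtmra.read_mutations(p)
        for p in sorted(glob.glob("demo/mutations/*.maf"))}
weak, strong = rtmra.select_extreme_groups(
    table.set_index("tumor_id")["rt_mra"], 0.35)
null_p = rtmra.compute_null_p(weak, strong, mafs)      # 0.54
res = rtmra.pathway_enrichment(weak, strong,
                               rtmra.load_gmt("demo/pathways.gmt"),
                               mafs, null_p)
print(res.sort_values("p").head(3).to_string(index=False))
#          unit  count_weak  count_strong       p   p_adj
# PW_DNA_REPAIR         184           107 0.00090 0.00721
#         PW_04         139           109 0.28054 0.78874
#         PW_05         141           114 0.36348 0.78874
```

`count_weak`/`count_strong` are deleteriously mutated (tumor, gene)
pairs inside each pathway; only the planted pathway beats the
constructed null (adjusted p = 0.007) — the other pathways sit at the
global weak/strong imbalance that `null_p` already accounts for.

The same stages are available as a shell pipeline
(`rtmra simulate | bin | count | score | cluster | signatures | enrich |
de | bias`); run `rtmra --help` for the options of each stage.

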