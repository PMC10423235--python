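"""Synthetic tumor-cohort generator with known ground truth.

The generator inverts the analysis model: each tumor carries a planted
late/early per-Mb mutation-rate ratio ``rho`` so that its expected
RT-MRa is exactly ``log2(rho)``.  Mutation positions are placed by a
two-step draw — an RT bin is chosen with probability proportional to
``bin_size_mb * rate(bin)`` (rate 1 in early bins, ``rho`` in late
bins), then a position uniformly within that bin's intervals — which
makes the planted ratio analytic rather than emergent.  On top of the
positional model the generator plants every structure the downstream
stages test: a two-subgroup rho mixture (the two clusters), signature
mixtures whose logits shift with ``log2(rho)``, deleterious-mutation
enrichment of one pathway in weak tumors, negative-binomial expression
with fold-change-planted DE genes and a mildly up-regulated immune-like
gene set, and clinical covariates with optional coupling to ``rho``.

Everything is deterministic under a fixed seed; one
:func:`simulate_cohort` call emits every file the pipeline consumes
plus a ``truth.json`` ground-truth record.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .binning import RTBinning, RTTrack, ValidationError, make_chromatin_bins, \
    make_rt_bins

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Synthetic gene symbol">\n'
)

MAF_COLUMNS = [
    "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
    "Tumor_Seq_Allele2", "Variant_Classification", "SIFT", "PolyPhen",
    "IMPACT", "Tumor_Sample_Barcode",
]

_BASES = np.array(list("ACGT"))

# consequence mix for genic mutations (neoantigen classes and silent ones)
_CONSEQUENCES = [
    ("Missense_Mutation", 0.55),
    ("Silent", 0.20),
    ("Nonsense_Mutation", 0.05),
    ("Splice_Site", 0.04),
    ("Splice_Region", 0.04),
    ("Frame_Shift_Del", 0.03),
    ("Frame_Shift_Ins", 0.03),
    ("In_Frame_Del", 0.02),
    ("In_Frame_Ins", 0.02),
    ("3'UTR", 0.02),
]


@dataclass
class GenomeConfig:
    n_intervals: int = 400
    interval_length_bp: int = 1_000_000
    intervals_per_chrom: int = 100
    rt_distribution: str = "uniform"  # rt ~ U(0, 1), higher = earlier
    constitutive_fraction: float = 0.9
    chromatin_coupled_to_rt: bool = True


@dataclass
class MutationConfig:
    # per-tumor total mutations ~ LogNormal
    log_mean: float = float(np.log(5000.0))
    log_sd: float = 0.4
    # the two-cluster rho mixture emulating weak/strong association tumors
    cluster_rhos: tuple[float, ...] = (1.2, 3.0)
    cluster_weights: tuple[float, ...] = (0.37, 0.63)
    rho_log2_jitter_sd: float = 0.10
    indel_fraction: float = 0.05
    deleterious_rate: float = 0.05
    weak_pathway_enrichment: float = 3.0  # deleterious-rate multiplier
    n_coding_genes: int = 240
    n_pathways: int = 8
    pathway_size: int = 30
    enriched_pathway: str = "PW_DNA_REPAIR"


@dataclass
class SignatureConfig:
    names: tuple[str, ...] = ("SBS1", "SBS5", "SBS13", "SBS17")
    betas: tuple[float, ...] = (0.0, 0.0, -0.8, 0.8)
    concentration: tuple[float, ...] = (4.0, 8.0, 2.0, 2.0)
    noise_sd: float = 0.3


@dataclass
class ExpressionConfig:
    n_genes: int = 2000
    n_de_genes: int = 100
    fold_change: float = 2.0
    n_immune_genes: int = 50
    immune_fold_change: float = 1.5
    nb_mean_log_mean: float = float(np.log(100.0))
    nb_mean_log_sd: float = 1.0
    dispersion: float = 0.1
    libsize_log_sd: float = 0.2


@dataclass
class CovariateConfig:
    age_mean: float = 60.0
    age_sd: float = 10.0
    ploidy_mean: float = 2.1
    ploidy_sd: float = 0.4
    purity_alpha: float = 5.0
    purity_beta: float = 2.0
    msi_rate: float = 0.03
    purity_rho_coupling: float = 0.0  # slope of purity shift per log2 rho


@dataclass
class SimulationConfig:
    seed: int = 0
    n_projects: int = 4
    tumors_per_project: int = 30
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    covariate: CovariateConfig = field(default_factory=CovariateConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "genome", "mutation", "signature", "expression", "covariate"
            ):
                sub_cls = {
                    "genome": GenomeConfig, "mutation": MutationConfig,
                    "signature": SignatureConfig, "expression": ExpressionConfig,
                    "covariate": CovariateConfig,
                }[f.name]
                val = sub_cls(**val)
            kwargs[f.name] = val
        return cls(**kwargs)


def coding_gene_names(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def expression_gene_names(cfg: ExpressionConfig) -> list[str]:
    imm = [f"IMM_{i + 1:03d}" for i in range(cfg.n_immune_genes)]
    exp = [f"EXP{i + 1:04d}" for i in range(cfg.n_genes - cfg.n_immune_genes)]
    return exp + imm


def simulate_rt_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[RTTrack, pd.DataFrame, pd.DataFrame]:
    """Synthetic RT track, constitutive-region BED and chromatin BED.

    Intervals are laid out contiguously on synthetic chromosomes; RT
    values are i.i.d. uniform on [0, 1] with higher = earlier.  The
    chromatin label is "active" for above-median RT when coupling is on
    (emulating the tight RT/accessibility alignment of real genomes),
    otherwise assigned independently at random.
    """
    g = config.genome
    if g.n_intervals < 4:
        raise ValidationError("need at least 4 intervals")
    if g.rt_distribution != "uniform":
        raise ValidationError(f"unknown rt_distribution {g.rt_distribution!r}")
    chroms, starts = [], []
    for i in range(g.n_intervals):
        c = i // g.intervals_per_chrom + 1
        j = i % g.intervals_per_chrom
        chroms.append(f"chr{c}")
        starts.append(j * g.interval_length_bp)
    starts = np.array(starts, dtype=np.int64)
    rt = rng.uniform(0.0, 1.0, size=g.n_intervals)
    track_df = pd.DataFrame(
        {"chrom": chroms, "start": starts,
         "end": starts + g.interval_length_bp, "rt": rt}
    )
    track = RTTrack(track_df, early_is_high=True, source="simulated")
    n_const = max(4, int(round(g.constitutive_fraction * g.n_intervals)))
    keep = np.sort(rng.choice(g.n_intervals, size=n_const, replace=False))
    constitutive = track_df.iloc[keep][["chrom", "start", "end"]].reset_index(
        drop=True
    )
    if g.chromatin_coupled_to_rt:
        active = rt > np.median(rt)
    else:
        active = rng.random(g.n_intervals) < 0.5
    chromatin = track_df[["chrom", "start", "end"]].copy()
    chromatin["label"] = np.where(active, "active", "inactive")
    # a sprinkle of the synonymous "active2" label and of ignorable labels
    is_active = chromatin["label"] == "active"
    flip = rng.random(g.n_intervals)
    chromatin.loc[is_active & (flip < 0.3), "label"] = "active2"
    return track, constitutive, chromatin


def build_pathways(cfg: MutationConfig, rng: np.random.Generator
                   ) -> dict[str, set[str]]:
    """Random gene-set catalog; the first pathway is the planted one."""
    genes = coding_gene_names(cfg.n_coding_genes)
    names = [cfg.enriched_pathway] + [
        f"PW_{i + 1:02d}" for i in range(cfg.n_pathways - 1)
    ]
    return {
        name: set(rng.choice(genes, size=cfg.pathway_size, replace=False))
        for name in names
    }


def draw_rho(cfg: MutationConfig, rng: np.random.Generator) -> tuple[float, int]:
    """One tumor's planted rho and its true cluster (1 = weak)."""
    order = np.argsort(cfg.cluster_rhos)  # cluster 1 = lowest rho
    comp = rng.choice(len(cfg.cluster_rhos), p=np.asarray(cfg.cluster_weights))
    rho = cfg.cluster_rhos[comp] * 2.0 ** rng.normal(0.0, cfg.rho_log2_jitter_sd)
    cluster = int(np.where(order == comp)[0][0]) + 1
    return float(rho), cluster


def simulate_tumor(
    config: SimulationConfig,
    binning: RTBinning,
    rho: float,
    rng: np.random.Generator,
    weak: bool = False,
    pathways: dict[str, set[str]] | None = None,
    n_mutations: int | None = None,
) -> pd.DataFrame:
    """Simulate one tumor's mutation table (0-based positions).

    Columns: chrom, pos, ref, alt, gene, consequence, deleterious.
    ``weak`` tumors get the planted pathway's deleterious-rate boost.
    """
    if rho <= 0:
        raise ValidationError("rho must be > 0")
    m = config.mutation
    if n_mutations is None:
        n_mutations = max(1, int(round(rng.lognormal(m.log_mean, m.log_sd))))
    labels = binning.labels  # earliest -> latest; first half early, rest late
    sizes = np.array([binning.bin_sizes_mb[b] for b in labels])
    n_early = binning.n_bins // 2
    rate = np.array([1.0] * n_early + [float(rho)] * (binning.n_bins - n_early))
    probs = sizes * rate
    probs = probs / probs.sum()
    bin_idx = rng.choice(len(labels), size=n_mutations, p=probs)
    chrom = np.empty(n_mutations, dtype=object)
    pos = np.empty(n_mutations, dtype=np.int64)
    gene_ids = np.full(n_mutations, -1, dtype=np.int64)
    iv = binning.intervals
    for j, lab in enumerate(labels):
        sel = bin_idx == j
        k = int(sel.sum())
        if k == 0:
            continue
        sub = iv[iv["bin"] == lab]
        lengths = (sub["end"] - sub["start"]).to_numpy(float)
        pick = rng.choice(len(sub), size=k, p=lengths / lengths.sum())
        offs = rng.integers(0, (sub["end"] - sub["start"]).to_numpy()[pick])
        chrom[sel] = sub["chrom"].to_numpy()[pick]
        pos[sel] = sub["start"].to_numpy()[pick] + offs
        # each interval hosts one coding gene over its middle half
        frac = offs / (sub["end"] - sub["start"]).to_numpy()[pick]
        genic = (frac >= 0.25) & (frac < 0.75)
        host = sub.index.to_numpy()[pick] % m.n_coding_genes
        gene_ids[sel] = np.where(genic, host, -1)
    gene_names = np.array(coding_gene_names(m.n_coding_genes))
    genes = np.where(gene_ids >= 0, gene_names[np.clip(gene_ids, 0, None)], None)
    is_indel = rng.random(n_mutations) < m.indel_fraction
    ref_i = rng.integers(0, 4, size=n_mutations)
    alt_i = (ref_i + rng.integers(1, 4, size=n_mutations)) % 4
    ref = _BASES[ref_i].astype(object)
    alt = _BASES[alt_i].astype(object)
    # indels encoded as a 2-bp deletion: ref "XT" -> alt "X"
    ref[is_indel] = [r + "T" for r in ref[is_indel]]
    alt[is_indel] = [r[0] for r in ref[is_indel]]
    cons_names = [c for c, _ in _CONSEQUENCES]
    cons_p = np.array([w for _, w in _CONSEQUENCES])
    cons_p = cons_p / cons_p.sum()
    consequence = np.where(
        gene_ids >= 0,
        rng.choice(cons_names, size=n_mutations, p=cons_p),
        "IGR",
    )
    enriched = pathways.get(m.enriched_pathway, set()) if pathways else set()
    p_del = np.where(
        gene_ids >= 0,
        np.where(
            np.isin(genes, list(enriched)) & weak,
            np.minimum(m.deleterious_rate * m.weak_pathway_enrichment, 0.9),
            m.deleterious_rate,
        ),
        0.0,
    )
    deleterious = np.where(rng.random(n_mutations) < p_del, "yes",
                           np.where(gene_ids >= 0, "no", "unknown"))
    df = pd.DataFrame(
        {
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": genes, "consequence": consequence,
            "deleterious": deleterious,
        }
    )
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_vcf(df: pd.DataFrame, path: str, contigs: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in df.itertuples(index=False):
            info = f"GENE={row.gene}" if row.gene else "."
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\t"
                f"PASS\t{info}\n"
            )


def write_maf(df: pd.DataFrame, path: str, tumor_id: str) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": df["gene"].fillna("Unknown"),
            "Chromosome": df["chrom"],
            "Start_Position": df["pos"] + 1,
            "Reference_Allele": df["ref"].replace("", "-"),
            "Tumor_Seq_Allele2": df["alt"].replace("", "-"),
            "Variant_Classification": df["consequence"],
            "SIFT": np.where(df["deleterious"] == "yes", "deleterious(0.01)",
                             np.where(df["deleterious"] == "no",
                                      "tolerated(0.60)", "")),
            "PolyPhen": np.where(df["deleterious"] == "yes",
                                 "probably_damaging(0.98)",
                                 np.where(df["deleterious"] == "no",
                                          "benign(0.05)", "")),
            "IMPACT": np.where(df["deleterious"] == "yes", "HIGH",
                               np.where(df["deleterious"] == "no",
                                        "MODERATE", "")),
            "Tumor_Sample_Barcode": tumor_id,
        },
        columns=MAF_COLUMNS,
    )
    out.to_csv(path, sep="\t", index=False)


def simulate_signatures(
    config: SimulationConfig, rhos: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-tumor relative signature contributions.

    Logits are a Dirichlet-distributed baseline (in log space) shifted
    by ``beta_s * log2(rho)`` plus Gaussian noise, pushed through a
    softmax; an attribution fraction just below 1 keeps row sums <= 1.
    """
    s = config.signature
    base = rng.dirichlet(np.asarray(s.concentration), size=len(rhos))
    logits = (
        np.log(np.maximum(base, 1e-12))
        + np.outer(np.log2(rhos.to_numpy(float)), np.asarray(s.betas))
        + rng.normal(0.0, s.noise_sd, size=(len(rhos), len(s.names)))
    )
    expl = np.exp(logits - logits.max(axis=1, keepdims=True))
    contrib = expl / expl.sum(axis=1, keepdims=True)
    contrib *= rng.uniform(0.92, 1.0, size=(len(rhos), 1))
    return pd.DataFrame(contrib, index=rhos.index, columns=list(s.names))


def simulate_expression(
    config: SimulationConfig,
    groups: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Negative-binomial count matrix for one project.

    ``groups`` maps sample id to weak/mid/strong.  DE genes (and the
    immune-like set, at a milder fold change) are up-regulated in the
    weak group; library sizes vary log-normally.
    """
    e = config.expression
    if e.fold_change <= 0 or e.immune_fold_change <= 0:
        raise ValidationError("fold changes must be > 0")
    genes = expression_gene_names(e)
    n_g, n_s = len(genes), len(groups)
    base_mean = rng.lognormal(e.nb_mean_log_mean, e.nb_mean_log_sd, size=n_g)
    exp_pool = [g for g in genes if g.startswith("EXP")]
    de_genes = list(rng.choice(exp_pool, size=min(e.n_de_genes, len(exp_pool)),
                               replace=False))
    imm_genes = [g for g in genes if g.startswith("IMM_")]
    fc = np.ones(n_g)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in de_genes:
        fc[gene_pos[g]] = e.fold_change
    for g in imm_genes:
        fc[gene_pos[g]] = e.immune_fold_change
    lib = rng.lognormal(0.0, e.libsize_log_sd, size=n_s)
    weak = (groups == "weak").to_numpy()
    mu = base_mean[:, None] * np.where(weak[None, :], fc[:, None], 1.0) * lib[None, :]
    size = 1.0 / e.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    df = pd.DataFrame(counts, index=genes, columns=list(groups.index))
    truth = {"de_genes": sorted(de_genes), "immune_genes": imm_genes,
             "fold_change": e.fold_change,
             "immune_fold_change": e.immune_fold_change}
    return df, truth


def simulate_covariates(
    config: SimulationConfig,
    tumors: pd.DataFrame,  # tumor_id index, columns rho, cluster, project, load
    rng: np.random.Generator,
) -> pd.DataFrame:
    c = config.covariate
    n = len(tumors)
    log2rho = np.log2(tumors["rho"].to_numpy(float))
    purity = rng.beta(c.purity_alpha, c.purity_beta, size=n)
    purity = np.clip(purity + c.purity_rho_coupling * (log2rho - log2rho.mean()),
                     0.05, 1.0)
    return pd.DataFrame(
        {
            "project": tumors["project"],
            "age": np.round(rng.normal(c.age_mean, c.age_sd, size=n), 1),
            "ploidy": np.round(np.clip(
                rng.normal(c.ploidy_mean, c.ploidy_sd, size=n), 1.0, 6.0), 3),
            "purity": np.round(purity, 3),
            "msi": rng.random(n) < c.msi_rate,
            "mutation_load": tumors["load"],
        },
        index=tumors.index,
    )


def simulate_cohort(config: SimulationConfig, outdir: str,
                    force: bool = False) -> dict:
    """Emit a complete synthetic cohort under ``outdir``.

    Writes the RT bedGraph, constitutive and chromatin BEDs, per-tumor
    VCF+MAF pairs, the signature and covariate tables, per-project
    expression count matrices, pathway and expression gene-set GMTs, a
    ``truth.json`` ground-truth record and a ``manifest.json`` index.
    Returns the manifest as a dict.
    """
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise ValidationError(f"{outdir} exists and is not empty (use force)")
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "mutations"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "expression"), exist_ok=True)
    root = np.random.default_rng(config.seed)
    rngs = root.spawn(6)
    r_genome, r_rho, r_mut, r_sig, r_expr, r_cov = rngs

    track, constitutive, chromatin = simulate_rt_genome(config, r_genome)
    track.to_bedgraph(os.path.join(outdir, "rt.bedgraph"))
    constitutive.to_csv(os.path.join(outdir, "constitutive.bed"),
                        sep="\t", header=False, index=False)
    chromatin.to_csv(os.path.join(outdir, "chromatin.bed"),
                     sep="\t", header=False, index=False)
    binning = make_rt_bins(track, 4)
    contigs = sorted(track.intervals["chrom"].unique(),
                     key=lambda c: int(c.replace("chr", "")))

    pathways = build_pathways(config.mutation, r_mut)
    with open(os.path.join(outdir, "pathways.gmt"), "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")

    tumor_rows = []
    truth_tumors = {}
    for pi in range(config.n_projects):
        project = f"PROJ{pi + 1:02d}"
        for ti in range(config.tumors_per_project):
            tid = f"{project}_T{ti + 1:03d}"
            rho, cluster = draw_rho(config.mutation, r_rho)
            muts = simulate_tumor(
                config, binning, rho, r_mut, weak=(cluster == 1),
                pathways=pathways,
            )
            write_vcf(muts, os.path.join(outdir, "mutations", f"{tid}.vcf"),
                      contigs)
            write_maf(muts, os.path.join(outdir, "mutations", f"{tid}.maf"),
                      tid)
            tumor_rows.append({"tumor_id": tid, "project": project,
                               "rho": rho, "cluster": cluster,
                               "load": len(muts)})
            truth_tumors[tid] = {"rho": rho, "expected_rt_mra": float(np.log2(rho)),
                                 "cluster": cluster, "project": project,
                                 "n_mutations": int(len(muts))}
    tumors = pd.DataFrame(tumor_rows).set_index("tumor_id")

    sigs = simulate_signatures(config, tumors["rho"], r_sig)
    sigs.rename_axis("tumor_id").to_csv(os.path.join(outdir, "signatures.tsv"),
                                        sep="\t")
    covariates = simulate_covariates(config, tumors, r_cov)
    covariates.rename_axis("tumor_id").to_csv(
        os.path.join(outdir, "covariates.tsv"), sep="\t")

    truth_expr = {}
    for project, sub in tumors.groupby("project"):
        log2rho = np.log2(sub["rho"])
        thirds = pd.qcut(log2rho.rank(method="first"), 3,
                         labels=["weak", "mid", "strong"])
        groups = pd.Series(thirds.astype(str).to_numpy(), index=sub.index)
        counts, truth = simulate_expression(config, groups, r_expr)
        counts.rename_axis("gene").to_csv(
            os.path.join(outdir, "expression", f"{project}_counts.tsv"),
            sep="\t")
        truth["true_groups"] = groups.to_dict()
        truth_expr[project] = truth

    imm = truth_expr[next(iter(truth_expr))]["immune_genes"]
    ctrl = [g for g in expression_gene_names(config.expression)
            if g.startswith("EXP")][: len(imm)]
    with open(os.path.join(outdir, "gene_sets.gmt"), "w") as fh:
        fh.write("\t".join(["IMMUNE_SET", "synthetic immune-like"] + imm) + "\n")
        fh.write("\t".join(["CONTROL_SET", "synthetic control"] + ctrl) + "\n")

    truth = {
        "seed": config.seed,
        "tumors": truth_tumors,
        "enriched_pathway": config.mutation.enriched_pathway,
        "signature_betas": dict(zip(config.signature.names,
                                    config.signature.betas)),
        "expression": truth_expr,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)

    manifest = {
        "rt_track": "rt.bedgraph",
        "constitutive": "constitutive.bed",
        "chromatin": "chromatin.bed",
        "pathways": "pathways.gmt",
        "gene_sets": "gene_sets.gmt",
        "signatures": "signatures.tsv",
        "covariates": "covariates.tsv",
        "mutations": {t: {"vcf": f"mutations/{t}.vcf", "maf": f"mutations/{t}.maf"}
                      for t in sorted(truth_tumors)},
        "expression": {p: f"expression/{p}_counts.tsv" for p in truth_expr},
        "truth": "truth.json",
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
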