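"""Deleterious-mutation enrichment in the weak-association extreme group.

Tumors are pooled pan-cancer and split into the bottom 35% (weak
RT-MRa) and top 35% (strong) of scores.  Because deleterious mutations
are sparse, enrichment is tested at the pathway level: for each pathway,
the deleteriously mutated genes in each group are counted and a
one-sided binomial test asks whether the weak group holds more than its
share.  The null success probability is *constructed from the data*:
p0 = D_weak / (D_weak + D_strong), the groups' share of all deleterious
mutations, so a pathway is called enriched only beyond the global
weak/strong imbalance.  The same machinery runs per gene (counting
mutations rather than mutated genes) and for Reactome-style
sub-pathway hierarchies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, binom_tail_ge
from .binning import ValidationError
from .mutation_io import NEOANTIGEN_CLASSES, MutationRecord, canonical_consequence

logger = logging.getLogger(__name__)

DEFAULT_EXTREME_FRACTION = 0.35
REPORT_ALPHA = 0.1  # adjusted-p reporting threshold


def load_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    catalog: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            if name in catalog:
                raise ValidationError(f"duplicate pathway name {name!r}")
            genes = {g for g in parts[2:] if g}
            if genes:
                catalog[name] = genes
    if not catalog:
        raise ValidationError(f"{path}: no gene sets")
    return catalog


def select_extreme_groups(
    scores: pd.Series, fraction: float = DEFAULT_EXTREME_FRACTION
) -> tuple[list[str], list[str]]:
    """Bottom-``fraction`` (weak) and top-``fraction`` (strong) tumors.

    Scores are sorted ascending with ties broken by tumor id, and each
    group takes ``floor(n * fraction)`` tumors, so the two groups are
    equal-sized and disjoint for fraction <= 0.5.
    """
    if not 0 < fraction <= 0.5:
        raise ValidationError("fraction must be in (0, 0.5]")
    n = len(scores)
    n_sel = int(np.floor(n * fraction))
    if n_sel < 1:
        raise ValidationError(f"too few tumors ({n}) for fraction {fraction}")
    order = scores.reset_index()
    order.columns = ["tumor_id", "score"]
    order = order.sort_values(["score", "tumor_id"], kind="mergesort")
    ids = order["tumor_id"].tolist()
    return ids[:n_sel], ids[-n_sel:]


def _deleterious_events(
    mutations: dict[str, list[MutationRecord]], tumors: list[str]
) -> pd.DataFrame:
    rows = []
    for t in tumors:
        for m in mutations.get(t, []):
            if m.deleterious == "yes" and m.gene:
                rows.append((t, m.gene))
    return pd.DataFrame(rows, columns=["tumor_id", "gene"])


def compute_null_p(
    weak: list[str], strong: list[str],
    mutations: dict[str, list[MutationRecord]],
) -> float:
    """Constructed binomial null: the weak group's share of all
    deleterious mutations, D_weak / (D_weak + D_strong)."""
    d_weak = len(_deleterious_events(mutations, weak))
    d_strong = len(_deleterious_events(mutations, strong))
    if d_weak + d_strong == 0:
        raise ValidationError("no deleterious mutations in either group")
    return d_weak / (d_weak + d_strong)


@dataclass(frozen=True)
class EnrichmentResult:
    unit: str
    count_weak: float
    count_strong: float
    null_p: float
    p: float
    p_adj: float
    tested: bool


def _binomial_frame(rows: list[dict], null_p: float) -> pd.DataFrame:
    out = pd.DataFrame(rows, columns=["unit", "count_weak", "count_strong",
                                      "tested"])
    k = out["count_weak"].to_numpy(float)
    n = k + out["count_strong"].to_numpy(float)
    p = np.ones(len(out))
    tested = out["tested"].to_numpy(bool)
    p[tested] = binom_tail_ge(k[tested], n[tested], null_p)
    out["null_p"] = null_p
    out["p"] = p
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"])
    return out


def pathway_enrichment(
    weak: list[str],
    strong: list[str],
    catalog: dict[str, set[str]],
    mutations: dict[str, list[MutationRecord]],
    null_p: float,
    dedupe: str = "tumor",
) -> pd.DataFrame:
    """One-sided binomial enrichment of deleteriously mutated genes per pathway.

    The counting unit is a deleteriously mutated (tumor, gene) pair
    (``dedupe="tumor"``; ``"cohort"`` collapses to distinct genes).  For
    each pathway, k = weak-group units with the gene in the pathway,
    n = k + strong-group units, and p = P[X >= k], X ~ Binom(n, null_p).
    A pathway with n = 0 is reported untested with p = 1.  BH correction
    runs across tested pathways.
    """
    if not 0 < null_p < 1:
        raise ValidationError("null_p must be in (0, 1)")
    if dedupe not in ("tumor", "cohort"):
        raise ValueError(f"unknown dedupe {dedupe!r}")
    ev_w = _deleterious_events(mutations, weak).drop_duplicates()
    ev_s = _deleterious_events(mutations, strong).drop_duplicates()
    if dedupe == "cohort":
        ev_w = ev_w.drop_duplicates("gene")
        ev_s = ev_s.drop_duplicates("gene")
    rows = []
    for name, genes in catalog.items():
        kw = int(ev_w["gene"].isin(genes).sum())
        ks = int(ev_s["gene"].isin(genes).sum())
        rows.append({"unit": name, "count_weak": kw, "count_strong": ks,
                     "tested": (kw + ks) > 0})
    return _binomial_frame(rows, null_p)


def subpathway_enrichment(
    weak: list[str],
    strong: list[str],
    catalog: dict[str, set[str]],
    hierarchy: pd.DataFrame,
    mutations: dict[str, list[MutationRecord]],
    null_p: float,
    parents: list[str] | None = None,
) -> pd.DataFrame:
    """Re-run pathway enrichment within each parent's child pathways.

    ``hierarchy`` has columns ``parent, child``; BH correction is applied
    separately within each parent's run.
    """
    frames = []
    for parent, sub in hierarchy.groupby("parent"):
        if parents is not None and parent not in parents:
            continue
        children = {c: catalog[c] for c in sub["child"] if c in catalog}
        if not children:
            continue
        res = pathway_enrichment(weak, strong, children, mutations, null_p)
        res.insert(0, "parent", parent)
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["parent", "unit", "count_weak",
                                     "count_strong", "tested", "null_p",
                                     "p", "p_adj"])
    return pd.concat(frames, ignore_index=True)


def gene_enrichment(
    weak: list[str],
    strong: list[str],
    mutations: dict[str, list[MutationRecord]],
    null_p: float,
    per_100k: bool = True,
) -> pd.DataFrame:
    """Per-gene binomial enrichment counting deleterious *mutations*.

    Reported counts are rescaled to events per 100,000 total mutations
    of the group, so groups of different mutational load are comparable.
    """
    if not 0 < null_p < 1:
        raise ValidationError("null_p must be in (0, 1)")

    def _counts(tumors):
        genes: dict[str, int] = {}
        total = 0
        for t in tumors:
            for m in mutations.get(t, []):
                total += 1
                if m.deleterious == "yes" and m.gene:
                    genes[m.gene] = genes.get(m.gene, 0) + 1
        return genes, total

    gw, tot_w = _counts(weak)
    gs, tot_s = _counts(strong)
    rows = []
    for gene in sorted(set(gw) | set(gs)):
        kw, ks = gw.get(gene, 0), gs.get(gene, 0)
        rows.append({"unit": gene, "count_weak": kw, "count_strong": ks,
                     "tested": (kw + ks) > 0})
    out = _binomial_frame(rows, null_p)
    if per_100k:
        out["norm_weak_per_100k"] = out["count_weak"] * 1e5 / max(tot_w, 1)
        out["norm_strong_per_100k"] = out["count_strong"] * 1e5 / max(tot_s, 1)
    return out


def top_enriched_genes(
    gene_results: pd.DataFrame, pathway_genes: set[str], n_top: int = 10
) -> pd.DataFrame:
    """The ``n_top`` lowest-p genes of one pathway's gene set."""
    sub = gene_results[gene_results["unit"].isin(pathway_genes)]
    return sub.sort_values(["p", "unit"], kind="mergesort").head(n_top)


def count_neoantigen_mutations(mutations: list[MutationRecord]) -> int:
    """Count mutations in the ten protein-altering consequence classes
    used as a neoantigen-potential proxy."""
    n = 0
    seen_consequence = False
    for m in mutations:
        if m.consequence is not None:
            seen_consequence = True
            if canonical_consequence(m.consequence) in NEOANTIGEN_CLASSES:
                n += 1
    if mutations and not seen_consequence:
        raise ValidationError("mutations carry no consequence annotation "
                              "(MAF input required)")
    return n


def group_covariate_tests(
    weak: list[str],
    strong: list[str],
    table: pd.DataFrame,
    covariate: str,
) -> pd.DataFrame:
    """Per-project one-tailed t-tests (weak > strong) on a covariate.

    ``table`` is indexed by tumor_id with ``project`` and covariate
    columns.  BH correction across projects.
    """
    tw = table.loc[table.index.isin(weak)]
    ts = table.loc[table.index.isin(strong)]
    rows = []
    for project in sorted(set(tw["project"]) & set(ts["project"])):
        xw = tw.loc[tw["project"] == project, covariate].dropna().to_numpy(float)
        xs = ts.loc[ts["project"] == project, covariate].dropna().to_numpy(float)
        if len(xw) < 2 or len(xs) < 2:
            continue
        if np.ptp(xw) == 0 and np.ptp(xs) == 0:
            p = np.nan if xw[0] != xs[0] else 0.5
            t = 0.0 if xw[0] == xs[0] else np.nan
        else:
            t, p = stats.ttest_ind(xw, xs, alternative="greater")
        rows.append({"project": project, "covariate": covariate,
                     "t": float(t), "p": float(p),
                     "n_weak": len(xw), "n_strong": len(xs)})
    out = pd.DataFrame(rows, columns=["project", "covariate", "t", "p",
                                      "n_weak", "n_strong"])
    out["p_adj"] = bh_adjust(out["p"]) if len(out) else []
    return out


def msi_test(
    weak: list[str], strong: list[str], msi: pd.Series, yates: bool = False
) -> dict:
    """Chi-square test of MSI status vs weak/strong group membership
    (2×2, no continuity correction by default)."""
    msi = msi.astype(bool)
    table = np.array(
        [
            [int(msi.loc[msi.index.isin(weak)].sum()),
             int((~msi.loc[msi.index.isin(weak)]).sum())],
            [int(msi.loc[msi.index.isin(strong)].sum()),
             int((~msi.loc[msi.index.isin(strong)]).sum())],
        ]
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("degenerate 2x2 MSI table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return {"chi2": float(chi2), "p": float(p), "table": table}
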