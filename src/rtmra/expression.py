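"""Differential expression between RT-MRa extreme tertiles.

Each project's samples are split into three equal groups by RT-MRa and
the weak vs strong extremes are compared gene-by-gene with a two-sided
Wilcoxon rank-sum test on TMM-normalized log2(CPM + 1) values.  Because
rank tests on small, heterogeneous cohorts can still yield inflated
discovery lists, each project is additionally screened by an
*experimental FDR*: group labels are permuted, the DE analysis is rerun,
and the project is kept only if the randomized runs recover fewer than
10% of the originally significant genes.

The immune-gene bias test asks, for each gene of a set, in what percent
of (validated) projects the weak group expresses it higher, compares
that list with the one obtained from random group splits by a paired
t-test, and converts t to the effect size d = t*sqrt((n1+n2)/(n1*n2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, cohens_d_from_t
from .binning import ValidationError

logger = logging.getLogger(__name__)

DE_ALPHA = 0.1
DE_LFC_THRESHOLD = 1.0
FDR_VALIDITY_RATIO = 0.10
GROUPS = ("weak", "mid", "strong")


def tertile_split(scores: pd.Series) -> pd.Series:
    """Three equal groups by RT-MRa within one project.

    Samples are sorted ascending by score (ties broken by id); the
    lowest ``floor(n/3)`` are the weak group, the highest ``floor(n/3)``
    the strong group, and the remainder is absorbed by the mid group so
    that the two compared extremes stay balanced.
    """
    n = len(scores)
    if n < 6:
        raise ValidationError(f"need at least 6 scored samples, got {n}")
    order = scores.reset_index()
    order.columns = ["sample", "score"]
    order = order.sort_values(["score", "sample"], kind="mergesort")
    n_ext = n // 3
    labels = ["mid"] * n
    for i in range(n_ext):
        labels[i] = "weak"
        labels[n - 1 - i] = "strong"
    out = pd.Series(labels, index=order["sample"], name="group")
    return out.loc[scores.index]


def _tmm_pair_factor(x: np.ndarray, ref: np.ndarray, n: float, n_ref: float,
                     logratio_trim: float = 0.30, sum_trim: float = 0.05
                     ) -> float:
    ok = (x > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    xs, rs = x[ok] / n, ref[ok] / n_ref
    log_r = np.log2(xs / rs)
    abs_e = 0.5 * np.log2(xs * rs)
    v = (n - x[ok]) / (n * x[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    m = len(log_r)
    lo_l = np.floor(m * logratio_trim) + 1
    hi_l = m + 1 - lo_l
    lo_s = np.floor(m * sum_trim) + 1
    hi_s = m + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (edgeR-style TMM).

    The reference is the sample whose upper-quartile count fraction is
    closest to the cohort mean; M values are trimmed by 30% and A values
    by 5% on each side, and the trimmed mean is precision-weighted.
    Factors are rescaled to have geometric mean 1.
    """
    lib = counts.sum(axis=0).to_numpy(float)
    if np.any(lib <= 0):
        raise ValidationError("every sample must have positive library size")
    x = counts.to_numpy(float)
    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], x[:, ref_j], lib[j], lib[ref_j])
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """TMM-scaled log2(CPM + 1) matrix plus the per-sample factors."""
    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0) * factors
    cpm = counts / eff_lib * 1e6
    return factors, np.log2(cpm + 1.0)


def wilcoxon_de(
    logcpm: pd.DataFrame,
    weak: list[str],
    strong: list[str],
    alpha: float = DE_ALPHA,
    lfc_threshold: float = DE_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test, weak vs strong.

    Midrank ties; exact null distribution for small tie-free groups
    (scipy's ``auto`` policy, used when both groups have <= 10 samples),
    tie-corrected normal approximation otherwise.  A gene whose values
    are all tied gets p = 1.  ``log2fc`` is the weak-group mean minus
    the strong-group mean of log2(CPM + 1), so weak-high genes are
    positive.  Significance = BH-adjusted p < alpha and |log2fc| above
    the threshold.
    """
    if len(weak) < 3 or len(strong) < 3:
        raise ValidationError("need at least 3 samples per group")
    xw = logcpm[list(weak)].to_numpy(float)
    xs = logcpm[list(strong)].to_numpy(float)
    log2fc = xw.mean(axis=1) - xs.mean(axis=1)
    tied = np.array(
        [np.ptp(np.concatenate([a, b])) == 0 for a, b in zip(xw, xs)]
    )
    pvals = np.ones(len(logcpm))
    todo = ~tied
    if todo.any():
        if min(len(weak), len(strong)) <= 10:
            idx = np.flatnonzero(todo)
            for i in idx:
                pvals[i] = stats.mannwhitneyu(
                    xw[i], xs[i], alternative="two-sided", method="auto"
                ).pvalue
        else:
            res = stats.mannwhitneyu(
                xw[todo], xs[todo], axis=1, alternative="two-sided",
                method="asymptotic",
            )
            pvals[todo] = res.pvalue
    out = pd.DataFrame(
        {
            "gene": logcpm.index,
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": bh_adjust(pvals),
        }
    )
    out["significant"] = (out["p_adj"] < alpha) & (out["log2fc"].abs() > lfc_threshold)
    return out


@dataclass
class FdrVerdict:
    n_observed: int
    randomized_counts: list[int]
    mean_randomized: float
    valid: bool | None  # None = "no signal" (nothing observed to validate)

    @property
    def verdict(self) -> str:
        if self.valid is None:
            return "no signal"
        return "valid" if self.valid else "not valid"


def experimental_fdr(
    logcpm: pd.DataFrame,
    weak: list[str],
    strong: list[str],
    n_randomizations: int = 10,
    seed: int = 0,
    de_routine=None,
    alpha: float = DE_ALPHA,
    lfc_threshold: float = DE_LFC_THRESHOLD,
) -> FdrVerdict:
    """Permutation screen of a project's DE list.

    Group labels are permuted (group sizes preserved) and the DE routine
    is rerun; the project is *valid* iff the mean randomized significant
    count is below 10% of the observed count.  Any routine with the
    ``wilcoxon_de`` signature can be plugged in, so an external engine
    (e.g. a DESeq2 adapter) can be screened the same way.
    """
    if n_randomizations < 1:
        raise ValidationError("n_randomizations must be >= 1")
    if de_routine is None:
        de_routine = wilcoxon_de
    run = lambda w, s: de_routine(  # noqa: E731
        logcpm, w, s, alpha=alpha, lfc_threshold=lfc_threshold
    )
    observed = int(run(weak, strong)["significant"].sum())
    if observed == 0:
        return FdrVerdict(0, [], 0.0, None)
    rng = np.random.default_rng(seed)
    pool = list(weak) + list(strong)
    counts = []
    for _ in range(n_randomizations):
        perm = rng.permutation(pool)
        w, s = list(perm[: len(weak)]), list(perm[len(weak):])
        counts.append(int(run(w, s)["significant"].sum()))
    mean_rand = float(np.mean(counts))
    return FdrVerdict(observed, counts, mean_rand,
                      mean_rand < FDR_VALIDITY_RATIO * observed)


def recurrent_genes(
    de_by_project: dict[str, pd.DataFrame],
    min_projects: int = 3,
    direction: str = "weak-high",
) -> pd.DataFrame:
    """Genes significant (in the given direction) in >= ``min_projects``
    projects, with their per-gene project counts."""
    if len(de_by_project) < min_projects:
        raise ValidationError("fewer projects than min_projects")
    sign = 1.0 if direction == "weak-high" else -1.0
    counts: dict[str, int] = {}
    for res in de_by_project.values():
        hits = res[(res["significant"]) & (sign * res["log2fc"] > 0)]["gene"]
        for g in hits:
            counts[g] = counts.get(g, 0) + 1
    rows = [
        {"gene": g, "n_projects": c}
        for g, c in sorted(counts.items())
        if c >= min_projects
    ]
    return pd.DataFrame(rows, columns=["gene", "n_projects"])


@dataclass
class BiasTestResult:
    gene_set: str
    observed_percent: pd.Series  # per gene, % of projects with weak-high mean
    control_percent: pd.Series
    t: float
    p: float
    d: float
    n_projects: int


def _weak_high_percent(
    projects: list[tuple[pd.DataFrame, list[str], list[str]]],
    genes: list[str],
) -> pd.Series:
    pct = {}
    for g in genes:
        hits = total = 0
        for logcpm, weak, strong in projects:
            if g not in logcpm.index:
                continue
            total += 1
            if logcpm.loc[g, list(weak)].mean() > logcpm.loc[g, list(strong)].mean():
                hits += 1
        pct[g] = 100.0 * hits / total if total else np.nan
    return pd.Series(pct, name="percent_weak_high")


def gene_set_bias_test(
    projects: list[tuple[pd.DataFrame, list[str], list[str]]],
    gene_set: set[str],
    seed: int = 0,
    name: str = "gene_set",
) -> BiasTestResult:
    """Directional-bias test of a gene set across projects.

    ``projects`` is a list of (log2(CPM+1) matrix, weak samples, strong
    samples).  For each gene, the observed statistic is the percent of
    projects where the weak-group mean expression exceeds the
    strong-group mean; the control recomputes it after randomly
    re-splitting each project's compared samples into two groups of the
    same sizes.  A paired t-test (pairing genes) compares the two lists
    and the effect size is d = t*sqrt((n1+n2)/(n1*n2)) with
    n1 = n2 = number of evaluable genes.
    """
    genes = sorted(gene_set)
    if len(genes) < 10:
        raise ValidationError("gene set must have at least 10 genes")
    rng = np.random.default_rng(seed)
    observed = _weak_high_percent(projects, genes)
    shuffled = []
    for logcpm, weak, strong in projects:
        pool = list(weak) + list(strong)
        perm = rng.permutation(pool)
        shuffled.append((logcpm, list(perm[: len(weak)]), list(perm[len(weak):])))
    control = _weak_high_percent(shuffled, genes)
    ok = observed.notna() & control.notna()
    obs, ctl = observed[ok], control[ok]
    if obs.std(ddof=1) == 0 and ctl.std(ddof=1) == 0 and (obs == ctl).all():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(obs, ctl)
    n = int(ok.sum())
    return BiasTestResult(
        gene_set=name,
        observed_percent=observed,
        control_percent=control,
        t=float(t),
        p=float(p),
        d=cohens_d_from_t(float(t), n, n),
        n_projects=len(projects),
    )
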