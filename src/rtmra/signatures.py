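"""Mutational-signature association with the RT-MRa score.

A signature-contribution matrix (tumors × SBS signatures, relative
contributions in [0, 1]) is tested against per-tumor RT-MRa scores three
ways: (i) correlation tests, pan-cancer over tumors with non-zero
contribution or per project where the project-mean contribution exceeds
5%; (ii) Kruskal–Wallis rank tests of contribution against the two-way
cluster annotation, excluding tumors below 5% contribution; (iii) PCA of
the contribution vectors followed by silhouette-selected k-means
subgrouping with pairwise Wilcoxon rank-sum comparisons of RT-MRa
between subgroups.  Benjamini–Hochberg correction is applied across
signatures within each scope (pan-cancer, or each project separately).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from ._stats import bh_adjust, kruskal_exact_or_approx
from .binning import ValidationError

logger = logging.getLogger(__name__)

MIN_MEAN_CONTRIB = 0.05
LOW_SEPARATION_SILHOUETTE = 0.25


def validate_signature_matrix(sigs: pd.DataFrame) -> pd.DataFrame:
    """Check a tumors × signatures relative-contribution matrix."""
    vals = sigs.to_numpy(dtype=float)
    if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
        raise ValidationError("signature contributions must lie in [0, 1]")
    if np.any(vals.sum(axis=1) > 1 + 1e-6):
        raise ValidationError("per-tumor contribution rows must sum to <= 1")
    return sigs


def _corr(x: np.ndarray, y: np.ndarray, method: str):
    if method == "pearson":
        return stats.pearsonr(x, y)
    if method == "spearman":
        return stats.spearmanr(x, y)
    raise ValueError(f"unknown correlation method {method!r}")


def signature_correlation(
    scores: pd.Series,
    sigs: pd.DataFrame,
    scope: str = "pan-cancer",
    projects: pd.Series | None = None,
    min_mean_contrib: float = MIN_MEAN_CONTRIB,
    method: str = "pearson",
    min_n: int = 3,
) -> pd.DataFrame:
    """Correlate each signature's contribution with the RT-MRa score.

    Pan-cancer: the test for a signature runs over tumors whose
    contribution of that signature is above zero.  Per project: the test
    runs only in projects whose mean contribution of the signature
    exceeds ``min_mean_contrib`` (all project tumors enter the test).
    """
    validate_signature_matrix(sigs)
    common = scores.index.intersection(sigs.index)
    scores = scores.loc[common]
    sigs = sigs.loc[common]
    rows = []
    if scope == "pan-cancer":
        for sig in sigs.columns:
            contrib = sigs[sig]
            mask = contrib > 0
            if mask.sum() < min_n:
                continue
            x = scores[mask].to_numpy(float)
            y = contrib[mask].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p = _corr(x, y, method)
            rows.append({"signature": sig, "scope": "pan-cancer",
                         "r": float(r), "p": float(p), "n": int(mask.sum())})
        out = pd.DataFrame(rows, columns=["signature", "scope", "r", "p", "n"])
        out["p_adj"] = bh_adjust(out["p"]) if len(out) else []
        if len(out) == 0:
            logger.info("signature_correlation: no eligible signature")
        return out
    if scope != "project":
        raise ValueError(f"unknown scope {scope!r}")
    if projects is None:
        raise ValueError("per-project scope requires a projects series")
    projects = projects.loc[common]
    frames = []
    for project, idx in projects.groupby(projects).groups.items():
        sub_scores = scores.loc[idx]
        sub_sigs = sigs.loc[idx]
        rows = []
        for sig in sub_sigs.columns:
            if sub_sigs[sig].mean() <= min_mean_contrib:
                continue
            if len(idx) < min_n:
                continue
            x = sub_scores.to_numpy(float)
            y = sub_sigs[sig].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p = _corr(x, y, method)
            rows.append({"signature": sig, "scope": project,
                         "r": float(r), "p": float(p), "n": len(idx)})
        sub = pd.DataFrame(rows, columns=["signature", "scope", "r", "p", "n"])
        if len(sub):
            sub["p_adj"] = bh_adjust(sub["p"])
            frames.append(sub)
    if not frames:
        logger.info("signature_correlation: no eligible signature in any project")
        return pd.DataFrame(columns=["signature", "scope", "r", "p", "n", "p_adj"])
    return pd.concat(frames, ignore_index=True)


def signature_rank_test(
    cluster_labels: pd.Series,
    sigs: pd.DataFrame,
    min_contrib: float = MIN_MEAN_CONTRIB,
) -> pd.DataFrame:
    """Kruskal–Wallis rank test of contribution vs cluster annotation.

    For each signature, tumors with contribution below ``min_contrib``
    are excluded; the test is skipped (and logged) if a cluster is empty
    after filtering.  Exact enumeration is used for tiny samples.
    """
    validate_signature_matrix(sigs)
    common = cluster_labels.index.intersection(sigs.index)
    cluster_labels = cluster_labels.loc[common]
    sigs = sigs.loc[common]
    rows = []
    for sig in sigs.columns:
        contrib = sigs[sig]
        mask = contrib >= min_contrib
        groups = [
            contrib[mask & (cluster_labels == c)].to_numpy(float)
            for c in sorted(cluster_labels.unique())
        ]
        if any(len(g) == 0 for g in groups):
            logger.info("signature_rank_test: %s skipped (empty cluster "
                        "after 5%% filter)", sig)
            continue
        h, p = kruskal_exact_or_approx(groups)
        rows.append({"signature": sig, "H": h, "p": p,
                     "n": int(sum(len(g) for g in groups))})
    out = pd.DataFrame(rows, columns=["signature", "H", "p", "n"])
    out["p_adj"] = bh_adjust(out["p"]) if len(out) else []
    return out


@dataclass
class SubgroupResult:
    project: str
    k: int
    labels: pd.Series  # tumor_id -> subgroup 1..k
    silhouette: float
    low_separation: bool
    pairwise: pd.DataFrame  # group_a, group_b, p, p_adj


def signature_subgroups(
    sigs: pd.DataFrame,
    scores: pd.Series,
    project: str = "",
    k_max: int = 10,
    seed: int = 0,
    var_explained: float = 0.90,
) -> SubgroupResult:
    """Subgroup one project's tumors by their signature profiles.

    Contribution vectors are centered, projected on the principal
    components explaining ``var_explained`` of the variance, and
    clustered with k-means for k = 2..k_max; k is chosen by maximum
    average silhouette width (Euclidean).  RT-MRa is then compared
    between every pair of subgroups by two-sided Wilcoxon rank-sum,
    BH-corrected.  When even the best silhouette is below 0.25 the
    result is flagged ``low_separation``.
    """
    validate_signature_matrix(sigs)
    common = scores.index.intersection(sigs.index)
    if len(common) < 6:
        raise ValidationError("need at least 6 tumors for subgrouping")
    scores = scores.loc[common]
    x = sigs.loc[common].to_numpy(float)
    pca = PCA(random_state=seed)
    z_full = pca.fit_transform(x - x.mean(axis=0))
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_explained) + 1)
    z = z_full[:, :n_comp]
    best = (None, -np.inf, None)
    upper = min(k_max, len(common) - 1)
    for k in range(2, upper + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(z)
        if len(np.unique(lab)) < 2:
            continue
        sil = silhouette_score(z, lab)
        if sil > best[1]:
            best = (k, sil, lab)
    k, sil, lab = best
    if k is None:
        raise ValidationError("no valid clustering found")
    labels = pd.Series(lab + 1, index=common, name="subgroup")
    rows = []
    for a in range(1, k + 1):
        for b in range(a + 1, k + 1):
            xa = scores[labels == a].to_numpy(float)
            xb = scores[labels == b].to_numpy(float)
            if len(xa) == 0 or len(xb) == 0:
                continue
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            rows.append({"group_a": a, "group_b": b, "p": p})
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "p"])
    pw["p_adj"] = bh_adjust(pw["p"]) if len(pw) else []
    return SubgroupResult(
        project=project,
        k=int(k),
        labels=labels,
        silhouette=float(sil),
        low_separation=bool(sil < LOW_SEPARATION_SILHOUETTE),
        pairwise=pw,
    )
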