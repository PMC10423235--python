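"""RT-MRa / CA-MRa association scores, tumor clustering, confounders.

The central statistic is the RT–mutation-rate association score

    RT-MRa = log2( (rate_L1 + rate_L2) / (rate_E1 + rate_E2) )

where ``rate_b`` is the per-Mb mutation rate in RT bin ``b``.  A low
score means the tumor's mutations are distributed almost evenly across
replication timing (a *weak* association); the cohort-typical pattern of
excess late-replicating mutations gives a positive score.  CA-MRa is
the analogous log-ratio of inactive over active chromatin rates.

Tumors are clustered on their 4-vector of per-Mb bin rates with
k-means.  The default normalizes each tumor's vector by its mean (so
mutation load cancels but the early/late contrast magnitude is kept)
and clusters with Euclidean k-means; correlation-type distances
(Spearman/rank variants, available behind ``method``) are affine-
invariant on 4-vectors and therefore blind to the *strength* of the
early/late contrast, which is exactly what separates the weak- and
strong-association clusters.  The two clusters are relabeled so
cluster 1 is the weak-association one (lower mean RT-MRa).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binning import EARLY_LABELS, LATE_LABELS, ValidationError
from .mutation_io import TumorMutationProfile

logger = logging.getLogger(__name__)

DEFAULT_MIN_MUTATIONS = 50
DEFAULT_PSEUDOCOUNT = 0.1  # mutations per Mb, applied only on a zero half


@dataclass(frozen=True)
class AssociationScore:
    tumor_id: str
    metric: str  # "RT-MRa" or "CA-MRa"
    value: float
    qc_pass: bool


def _log_ratio(num: float, den: float, pseudocount: float) -> float:
    if num == 0.0 or den == 0.0:
        num += pseudocount
        den += pseudocount
    return float(np.log2(num / den))


def rt_mra(
    profile: TumorMutationProfile,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> AssociationScore:
    """RT-MRa of one tumor: log2 of late over early per-Mb rates.

    The pseudocount is added to both halves only when either half is
    zero, keeping the score finite without biasing covered tumors;
    ``qc_pass`` requires at least ``min_mutations`` constitutive
    mutations.
    """
    labels = set(profile.labels)
    if not set(EARLY_LABELS + LATE_LABELS) <= labels:
        raise ValidationError(f"profile bins {sorted(labels)} are not E1/E2/L1/L2")
    r = profile.rates
    value = _log_ratio(
        r[LATE_LABELS[0]] + r[LATE_LABELS[1]],
        r[EARLY_LABELS[0]] + r[EARLY_LABELS[1]],
        pseudocount,
    )
    return AssociationScore(
        tumor_id=profile.tumor_id,
        metric="RT-MRa",
        value=value,
        qc_pass=profile.total_constitutive >= min_mutations,
    )


def ca_mra(
    profile: TumorMutationProfile,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> AssociationScore:
    """CA-MRa: log2 of inactive- over active-chromatin per-Mb rates."""
    if not {"active", "inactive"} <= set(profile.labels):
        raise ValidationError("profile must come from a chromatin binning")
    r = profile.rates
    value = _log_ratio(r["inactive"], r["active"], pseudocount)
    return AssociationScore(
        tumor_id=profile.tumor_id,
        metric="CA-MRa",
        value=value,
        qc_pass=profile.total_constitutive >= min_mutations,
    )


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def _spearman_distance(xr: np.ndarray, cr: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation of midrank-transformed rows vs centroids.

    ``xr``: (n, d) rank-transformed vectors; ``cr``: (k, d) rank-
    transformed centroids.  A constant vector has undefined correlation;
    its distance is taken as 1 (equivalent to zero correlation).
    """
    xm = xr - xr.mean(axis=1, keepdims=True)
    cm = cr - cr.mean(axis=1, keepdims=True)
    xs = np.sqrt((xm**2).sum(axis=1))
    cs = np.sqrt((cm**2).sum(axis=1))
    num = xm @ cm.T
    den = np.outer(xs, cs)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return 1.0 - corr


def _kmeans_spearman(
    x: np.ndarray, k: int, n_restarts: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(x)
    xr = _rank_rows(x)
    best_labels, best_obj = None, np.inf
    for _ in range(n_restarts):
        centers = x[rng.choice(n, size=k, replace=False)]
        labels = None
        for _ in range(100):
            d = _spearman_distance(xr, _rank_rows(centers))
            new_labels = d.argmin(axis=1)
            # re-seed empty clusters with the worst-fit point
            for j in range(k):
                if not np.any(new_labels == j):
                    far = d[np.arange(n), new_labels].argmax()
                    new_labels[far] = j
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centers = np.vstack([x[labels == j].mean(axis=0) for j in range(k)])
        obj = _spearman_distance(xr, _rank_rows(centers))[np.arange(n), labels].sum()
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, labels
    return best_labels


def _kmeans_rank_euclidean(
    x: np.ndarray, k: int, n_restarts: int, seed: int
) -> np.ndarray:
    from sklearn.cluster import KMeans

    xr = _rank_rows(x)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(xr)


def cluster_rate_vectors(
    profiles: list[TumorMutationProfile],
    k: int = 2,
    n_restarts: int = 25,
    seed: int = 0,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
    method: str = "normalized",
) -> pd.DataFrame:
    """Cluster QC-passing tumors on their per-Mb bin-rate 4-vectors.

    ``method="normalized"`` (default) divides each vector by its own
    mean and runs Euclidean k-means, preserving the magnitude of the
    early/late rate contrast; ``"spearman"`` runs Lloyd k-means with
    distance 1 − Spearman rank correlation to the centroid;
    ``"rank-euclidean"`` rank-transforms the vectors first.  Clusters
    are relabeled 1..k by increasing mean RT-MRa, so cluster 1 is the
    weak-association cluster.

    Returns a frame with tumor_id, project, rt_mra, cluster.
    """
    scored = [(p, rt_mra(p, min_mutations=min_mutations)) for p in profiles]
    kept = [(p, s) for p, s in scored if s.qc_pass]
    if len(kept) < k:
        raise ValidationError(f"need at least k={k} QC-passing tumors, got {len(kept)}")
    x = np.array([[p.rates[b] for b in ("E1", "E2", "L1", "L2")] for p, _ in kept])
    if np.allclose(x, x[0]):
        warnings.warn("all rate vectors identical; clustering is degenerate")
        labels = np.zeros(len(x), dtype=int)
    elif method == "normalized":
        from sklearn.cluster import KMeans

        xn = x / x.mean(axis=1, keepdims=True)
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(xn)
    elif method == "spearman":
        rng = np.random.default_rng(seed)
        labels = _kmeans_spearman(x, k, n_restarts, rng)
    elif method == "rank-euclidean":
        labels = _kmeans_rank_euclidean(x, k, n_restarts, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    values = np.array([s.value for _, s in kept])
    # relabel so cluster 1 has the lowest mean RT-MRa
    means = {j: values[labels == j].mean() for j in np.unique(labels)}
    order = sorted(means, key=means.get)
    remap = {j: i + 1 for i, j in enumerate(order)}
    out = pd.DataFrame(
        {
            "tumor_id": [p.tumor_id for p, _ in kept],
            "project": [p.project_id for p, _ in kept],
            "rt_mra": values,
            "cluster": [remap[j] for j in labels],
        }
    )
    return out


def confounder_correlations(
    table: pd.DataFrame, covariate: str, min_n: int = 3
) -> pd.DataFrame:
    """Per-project Pearson correlation of RT-MRa with one covariate.

    Missing covariate values are dropped pairwise; projects with fewer
    than ``min_n`` complete pairs are skipped (logged); a zero-variance
    covariate yields a missing (NaN) correlation.
    """
    rows = []
    for project, sub in table.groupby("project"):
        pair = sub[["rt_mra", covariate]].dropna()
        if len(pair) < min_n:
            logger.info("confounder_correlations: skipping %s (n=%d)",
                        project, len(pair))
            continue
        x = pair["rt_mra"].to_numpy(float)
        y = pair[covariate].to_numpy(float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            rows.append({"project": project, "covariate": covariate,
                         "r": np.nan, "p": np.nan, "n": len(pair)})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"project": project, "covariate": covariate,
                     "r": float(r), "p": float(p), "n": len(pair)})
    return pd.DataFrame(rows, columns=["project", "covariate", "r", "p", "n"])


def project_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-project median RT-MRa, percent of tumors in cluster 1, and n."""
    rows = []
    for project, sub in table.groupby("project"):
        if len(sub) == 0:
            continue
        rows.append(
            {
                "project": project,
                "median_rt_mra": float(sub["rt_mra"].median()),
                "pct_cluster1": float(100.0 * (sub["cluster"] == 1).mean()),
                "n": int(len(sub)),
            }
        )
    out = pd.DataFrame(rows, columns=["project", "median_rt_mra", "pct_cluster1", "n"])
    return out.sort_values("median_rt_mra", kind="mergesort").reset_index(drop=True)
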