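"""Consensus clustering subtype discovery.

Repeated average-linkage hierarchical clustering on 1 - Pearson correlation
over subsampled cohorts; the consensus matrix records the fraction of co-draws
in which two samples co-cluster.  Stability of the consensus CDF across k
selects the cluster count, silhouette widths on the consensus-derived distance
summarize assignment confidence, and a Gaussian-null cluster-index test
assesses pairwise cluster significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import squareform

__all__ = [
    "ConsensusResult",
    "PairwiseSignificance",
    "consensus_cluster",
    "select_k",
    "silhouette_widths",
    "sigclust_pairwise",
    "cluster_index",
]


@dataclass
class ConsensusResult:
    sample_ids: tuple[str, ...]
    consensus: dict[int, np.ndarray]       # k -> samples x samples in [0,1]
    assignments: dict[int, np.ndarray]     # k -> cluster id per sample (1-based)
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]                  # proportion of ambiguous pairs
    chosen_k: int
    silhouette: dict[int, np.ndarray]      # per-sample widths at each k
    no_structure: bool = False


@dataclass
class PairwiseSignificance:
    cluster_a: int
    cluster_b: int
    statistic: float   # 2-means cluster index in (0, 1]
    p_value: float
    n_null_draws: int


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson correlation distance between columns of x."""
    c = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(c, 1.0)
    d = np.clip(1.0 - c, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def consensus_cluster(m, k_range, n_resamples: int = 1000,
                      sample_frac: float = 0.8, seed: int = 0,
                      delta_threshold: float = 0.025) -> ConsensusResult:
    """Resampled consensus clustering of the samples of ``m``.

    For each resample, ceil(sample_frac * n) samples are drawn without
    replacement, clustered by average-linkage agglomeration on 1 - Pearson
    distance over genes, and cut at each k in ``k_range``.  The consensus
    entry for a sample pair is its co-clustering count divided by its co-draw
    count.  The final assignment at each k clusters (1 - consensus) by average
    linkage.  Deterministic given ``seed``.
    """
    x = m.values if not hasattr(m, "unit") or m.unit == "log2TPM" \
        else np.log2(m.values + 1.0)
    sample_ids = tuple(m.sample_ids) if hasattr(m, "sample_ids") \
        else tuple(f"S{i}" for i in range(x.shape[1]))
    n = x.shape[1]
    k_range = sorted(set(int(k) for k in k_range))
    if len(k_range) < 2:
        raise ValueError("k_range must contain at least 2 values")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if max(k_range) >= n:
        raise ValueError("k_max must be smaller than the sample count")
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must be in (0, 1]")

    rng = np.random.default_rng(seed)
    n_draw = int(np.ceil(sample_frac * n))
    co_draw = np.zeros((n, n))
    co_cluster = {k: np.zeros((n, n)) for k in k_range}

    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=n_draw, replace=False))
        link = average(_pearson_distance(x[:, idx]))
        pair_mask = np.zeros((n, n), dtype=bool)
        pair_mask[np.ix_(idx, idx)] = True
        co_draw += pair_mask
        for k in k_range:
            labels = fcluster(link, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            block = np.zeros((n, n), dtype=bool)
            block[np.ix_(idx, idx)] = same
            co_cluster[k] += block

    if np.any(co_draw == 0):
        i, j = np.argwhere(co_draw == 0)[0]
        raise ValueError(
            f"samples {sample_ids[i]!r} and {sample_ids[j]!r} were never "
            "co-drawn; increase n_resamples or sample_frac"
        )

    consensus, assignments, silhouettes, areas, pac = {}, {}, {}, {}, {}
    for k in k_range:
        c = co_cluster[k] / co_draw
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
        consensus[k] = c
        link = average(squareform(np.clip(1.0 - c, 0.0, 1.0), checks=False))
        labels = fcluster(link, t=k, criterion="maxclust")
        assignments[k] = labels
        silhouettes[k] = silhouette_widths(c, labels)
        areas[k] = _cdf_area(c)
        off = c[np.triu_indices_from(c, k=1)]
        pac[k] = float(np.mean((off > 0.1) & (off < 0.9)))

    delta = {}
    prev = None
    for k in k_range:
        if prev is None:
            delta[k] = areas[k]
        else:
            delta[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 \
                else 0.0
        prev = k

    result = ConsensusResult(sample_ids=sample_ids, consensus=consensus,
                             assignments=assignments, cdf_area=areas,
                             delta_area=delta, pac=pac, chosen_k=0,
                             silhouette=silhouettes)
    result.chosen_k = select_k(result, delta_threshold=delta_threshold)
    return result


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    vals = np.sort(consensus[np.triu_indices_from(consensus, k=1)])
    if vals.size == 0:
        return 0.0
    # A = sum over sorted entries of (x_{i+1} - x_i) * CDF(x_i), the usual
    # consensus-CDF area; grid includes 0 and 1 endpoints.
    grid = np.concatenate(([0.0], vals, [1.0]))
    cdf = np.concatenate(([0.0], np.arange(1, vals.size + 1) / vals.size, [1.0]))
    return float(np.sum(np.diff(grid) * cdf[:-1]))


def select_k(result: ConsensusResult, delta_threshold: float = 0.025,
             pac_threshold: float = 0.2, min_cluster_frac: float = 0.05) -> int:
    """Largest k whose relative gain in consensus-CDF area meets the
    threshold, guarded against unstructured data.

    A candidate k is rejected when its consensus matrix is predominantly
    ambiguous (proportion of off-diagonal entries between 0.1 and 0.9 above
    ``pac_threshold``) or when its cut produces a near-empty cluster (below
    ``min_cluster_frac`` of the cohort) — both signatures of average linkage
    splitting noise into a dominant cluster plus outliers.  When no candidate
    survives, the smallest k is returned with a no-structure warning.
    """
    ks = sorted(result.delta_area)
    if len(ks) < 2:
        raise ValueError("need delta areas for at least 2 values of k")
    eligible = [k for k in ks if result.delta_area[k] >= delta_threshold]
    if result.pac:
        eligible = [k for k in eligible if result.pac[k] <= pac_threshold]
    if result.assignments:
        n = len(result.sample_ids)
        eligible = [
            k for k in eligible
            if np.bincount(result.assignments[k]).max(initial=0) > 0
            and np.min(np.bincount(result.assignments[k])[1:]) >= max(
                2, min_cluster_frac * n)
        ]
    if not eligible or eligible == [ks[0]]:
        warnings.warn("no consensus structure beyond the smallest k")
        result.no_structure = True
        return ks[0]
    return max(eligible)


def silhouette_widths(consensus: np.ndarray, assignments) -> np.ndarray:
    """Silhouette widths s(i) = (b - a) / max(a, b) on distance 1 - consensus.

    Samples in singleton clusters get width 0 by convention.
    """
    labels = np.asarray(assignments)
    d = np.clip(1.0 - np.asarray(consensus, dtype=float), 0.0, None)
    np.fill_diagonal(d, 0.0)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = labels.size
    widths = np.zeros(n)
    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    if any(s == 1 for s in sizes.values()):
        warnings.warn("singleton cluster; its silhouette width set to 0")
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            continue
        a = d[i, labels == own].sum() / (sizes[own] - 1)
        b = min(d[i, labels == c].mean() for c in uniq if c != own)
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths


def cluster_index(x: np.ndarray, n_restarts: int = 5,
                  seed: int | None = None) -> float:
    """2-means cluster index: within-cluster SS / total SS, best of
    ``n_restarts`` k-means runs on samples x features data."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    total_ss = float(np.sum(centered ** 2))
    if total_ss == 0:
        raise ValueError("degenerate data: zero total variance")
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_restarts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            centroids, labels = kmeans2(x, 2, minit="++",
                                        seed=rng.integers(2**31 - 1))
        within = float(np.sum((x - centroids[labels]) ** 2))
        best = min(best, within)
    return best / total_ss


def _null_spectrum(pooled: np.ndarray, edge_buffer: float = 1.1) -> np.ndarray:
    """Diagonal null-covariance scales for a pooled cluster pair.

    Background variance is the median per-gene variance; sample-covariance
    eigenvalues are kept as signal directions only when they clear the
    Marchenko–Pastur bulk edge (with a small buffer against edge
    fluctuations) and are then debiased under the spiked-covariance model.
    """
    n_pair, d = pooled.shape
    gene_var = pooled.var(axis=0, ddof=1)
    sigma_bg = float(np.median(gene_var))
    if sigma_bg == 0:
        raise ValueError("degenerate pair: zero variance")
    centered = pooled - pooled.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(centered, compute_uv=False)
    ev = sv**2 / max(n_pair - 1, 1)
    gamma = d / n_pair
    edge = sigma_bg * (1.0 + np.sqrt(gamma)) ** 2
    lam = np.full(d, sigma_bg)
    for j in range(min(len(ev), d)):
        if ev[j] > edge_buffer * edge:
            b = ev[j] + sigma_bg * (1.0 - gamma)
            lam[j] = max(
                (b + np.sqrt(max(b * b - 4.0 * ev[j] * sigma_bg, 0.0))) / 2.0,
                sigma_bg)
        else:
            break  # spectrum is sorted; no later eigenvalue clears the edge
    return np.sqrt(lam)


def sigclust_pairwise(m, assignments, n_sim: int = 100,
                      seed: int = 0) -> list[PairwiseSignificance]:
    """Gaussian-null significance of every cluster pair.

    The statistic is the 2-means cluster index of the pooled pair.  The null
    is a single multivariate Gaussian with diagonal covariance: background
    variance (median per-gene variance) in the bulk directions plus the
    debiased above-edge eigenvalues of the pooled sample covariance
    (see ``_null_spectrum``).  p = fraction of null cluster indices at or
    below the observed one.
    """
    x = m.values.T if hasattr(m, "values") else np.asarray(m, dtype=float)
    labels = np.asarray(assignments)
    if labels.size != x.shape[0]:
        raise ValueError("one assignment per sample required")
    rng = np.random.default_rng(seed)
    uniq = np.unique(labels)
    out = []
    for ai in range(uniq.size):
        for bi in range(ai + 1, uniq.size):
            a, b = uniq[ai], uniq[bi]
            mask = (labels == a) | (labels == b)
            if np.sum(labels == a) < 3 or np.sum(labels == b) < 3:
                raise ValueError(
                    f"clusters {a} and {b} need >= 3 samples each")
            pooled = x[mask]
            stat = cluster_index(pooled, seed=rng.integers(2**31 - 1))
            n_pair, d = pooled.shape
            try:
                scales = _null_spectrum(pooled)
            except ValueError as exc:
                raise ValueError(f"degenerate pair ({a}, {b}): {exc}") from exc
            null_stats = np.empty(n_sim)
            for s in range(n_sim):
                z = rng.standard_normal((n_pair, d)) * scales
                null_stats[s] = cluster_index(
                    z, seed=rng.integers(2**31 - 1))
            p = float(np.mean(null_stats <= stat))
            p = max(p, 1.0 / (n_sim + 1))
            out.append(PairwiseSignificance(
                cluster_a=int(a), cluster_b=int(b), statistic=stat,
                p_value=p, n_null_draws=n_sim))
    return out
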