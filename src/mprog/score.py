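"""Per-sample scoring: single-sample GSEA, the MPscore, stemness index,
immune population scores, ROC/AUC, random-forest marker ranking, and
group comparison statistics.

The MPscore of a sample is the single-sample GSEA enrichment of the
progressive subtype's up-regulated signature minus that of its down-regulated
signature:

    MPscore(s) = ssGSEA_up(s) - ssGSEA_down(s)

ssGSEA is implemented from first principles as a rank-weighted running sum:
genes are ranked by decreasing expression within the sample (ties receive
average ranks), and the score is the accumulated difference between the
weighted in-set CDF (weights |rank|^tau) and the uniform out-of-set CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .degsig import SignatureSet

__all__ = [
    "SsgseaParams",
    "MarkerRanking",
    "ssgsea",
    "ssgsea_matrix",
    "mpscore",
    "mpscore_table",
    "stemness_index",
    "immune_scores",
    "roc_auc",
    "rf_marker_ranking",
    "group_compare",
]


@dataclass(frozen=True)
class SsgseaParams:
    """Rank-weight exponent and cohort-range normalization flag.

    Defaults follow the reference single-sample GSEA implementation:
    tau = 0.25 and cohort-range normalization on (it only applies to
    cohort-level scoring; single-sample calls return the raw running sum).
    """

    tau: float = 0.25
    normalize: bool = True

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class MarkerRanking:
    importance: pd.Series        # mean decrease in OOB accuracy, per gene
    rank: pd.Series              # 1 = most important
    cv_error: pd.Series          # cross-validated error per retained count


def _rank_scores(values: np.ndarray) -> np.ndarray:
    """Rank score per gene: 1 for the lowest expression up to G for the
    highest, average ranks on ties (so the top-ranked gene carries the
    largest weight)."""
    return stats.rankdata(values, method="average")


def ssgsea(sample_expr: pd.Series | np.ndarray, gene_set,
           params: SsgseaParams = SsgseaParams(),
           gene_ids=None) -> float:
    """Single-sample GSEA enrichment score of ``gene_set`` in one sample.

    The score is sum_i (P_in(i) - P_out(i)) along the expression-ranked gene
    list, where P_in accumulates |rank|^tau over set members and P_out is the
    uniform CDF over non-members.
    """
    if isinstance(sample_expr, pd.Series):
        gene_ids = list(sample_expr.index)
        values = sample_expr.to_numpy(dtype=float)
    else:
        values = np.asarray(sample_expr, dtype=float)
        if gene_ids is None:
            raise ValueError("gene_ids required with an array input")
        gene_ids = list(gene_ids)
    in_set = np.isin(gene_ids, list(gene_set))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the measured genes")
    if n_hit == len(gene_ids):
        raise ValueError("gene set covers every measured gene")

    rho = _rank_scores(values)
    order = np.argsort(-rho, kind="mergesort")  # decreasing expression
    hits = in_set[order]
    w = np.abs(rho[order]) ** params.tau
    w[~hits] = 0.0
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~hits) / (len(gene_ids) - n_hit)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(m, gene_set, params: SsgseaParams = SsgseaParams()) -> pd.Series:
    """ssGSEA score of one gene set for every sample of an expression
    matrix; with ``params.normalize``, scores are divided by their range
    (max - min) across the cohort."""
    frame = m.to_frame() if hasattr(m, "to_frame") else pd.DataFrame(m)
    scores = pd.Series(
        {s: ssgsea(frame[s], gene_set,
                   SsgseaParams(tau=params.tau, normalize=False))
         for s in frame.columns},
        name="ssgsea",
    )
    if params.normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return scores


def mpscore(sample_expr, signature: SignatureSet,
            params: SsgseaParams = SsgseaParams(), gene_ids=None) -> float:
    """MPscore of one sample: ssGSEA(up) - ssGSEA(down)."""
    if not signature.up or not signature.down:
        raise ValueError("signature needs non-empty up and down lists")
    return ssgsea(sample_expr, signature.up, params, gene_ids) \
        - ssgsea(sample_expr, signature.down, params, gene_ids)


def mpscore_table(m, signature: SignatureSet,
                  params: SsgseaParams = SsgseaParams()) -> pd.DataFrame:
    """Per-sample ssGSEA up/down scores and their difference (the MPscore)."""
    if not signature.up or not signature.down:
        raise ValueError("signature needs non-empty up and down lists")
    up = ssgsea_matrix(m, signature.up, params)
    down = ssgsea_matrix(m, signature.down, params)
    return pd.DataFrame({"ssgsea_up": up, "ssgsea_down": down,
                         "mpscore": up - down})


def stemness_index(m, weights: pd.Series) -> pd.DataFrame:
    """Spearman-correlation stemness index per sample, min-max rescaled to
    [0, 1] across the cohort.

    ``weights`` is a per-gene stem-cell signature weight vector; at least 10
    genes must overlap the matrix.
    """
    frame = m.to_frame() if hasattr(m, "to_frame") else pd.DataFrame(m)
    common = frame.index.intersection(weights.index)
    if len(common) < 10:
        raise ValueError(
            f"only {len(common)} genes overlap the weight vector (need >= 10)")
    w = weights.loc[common].to_numpy(dtype=float)
    raw = {}
    for s in frame.columns:
        x = frame.loc[common, s].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"sample {s!r} has zero expression variance")
        raw[s] = stats.spearmanr(w, x).statistic
    raw = pd.Series(raw, name="si_raw")
    lo, hi = raw.min(), raw.max()
    si = (raw - lo) / (hi - lo) if hi > lo else raw * 0.0
    return pd.DataFrame({"si_raw": raw, "si": si})


def immune_scores(m, panels: dict[str, list[str]]) -> pd.DataFrame:
    """Marker-aggregation immune population scores.

    Score of a population in a sample = arithmetic mean of the log2
    expression of that population's marker genes (samples x populations).
    """
    frame = m.to_frame() if hasattr(m, "to_frame") else pd.DataFrame(m)
    if hasattr(m, "unit") and m.unit == "TPM":
        frame = np.log2(frame + 1.0)
    out = {}
    for pop, markers in panels.items():
        present = [g for g in markers if g in frame.index]
        if not present:
            raise ValueError(f"panel {pop!r} has no measured marker genes")
        out[pop] = frame.loc[present].mean(axis=0)
    return pd.DataFrame(out)


def roc_auc(scores, labels) -> float:
    """Mann–Whitney AUC with ties counted 0.5; orientation is the caller's
    (higher score taken to indicate the positive class)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# --- bagged random forest with OOB permutation importance -------------------

def _fit_bagged_forest(x, y, n_trees, rng):
    trees = []
    n = x.shape[0]
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)))
        tree.fit(x[boot], y[boot])
        trees.append((tree, oob))
    return trees


def _oob_permutation_importance(trees, x, y, rng):
    """Mean decrease in out-of-bag accuracy under per-feature permutation."""
    n_features = x.shape[1]
    drops = np.zeros(n_features)
    counts = np.zeros(n_features)
    for tree, oob in trees:
        if oob.size == 0:
            continue
        base = np.mean(tree.predict(x[oob]) == y[oob])
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            xp = x[oob].copy()
            xp[:, j] = xp[rng.permutation(oob.size), j]
            perm = np.mean(tree.predict(xp) == y[oob])
            drops[j] += base - perm
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        imp = np.where(counts > 0, drops / np.maximum(counts, 1), 0.0)
    return imp


def _cv_error(x, y, n_trees, cv_folds, rng) -> float:
    folds = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                            random_state=int(rng.integers(2**31 - 1)))
    errs = []
    for train, test in folds.split(x, y):
        trees = _fit_bagged_forest(x[train], y[train], n_trees, rng)
        votes = np.zeros((test.size, 2))
        for tree, _ in trees:
            pred = tree.predict(x[test]).astype(int)
            votes[np.arange(test.size), pred] += 1
        pred = votes.argmax(axis=1)
        errs.append(np.mean(pred != y[test]))
    return float(np.mean(errs))


def rf_marker_ranking(m, subtype_labels, target_subtype, n_trees: int = 200,
                      cv_folds: int = 10, step: float = 1.5,
                      seed: int = 0) -> MarkerRanking:
    """Rank genes by random-forest importance for one-vs-rest subtype
    discrimination, with recursive elimination.

    A bagged ensemble of decision trees (bootstrap rows, random sqrt-feature
    subsets per split) is fit on target-vs-rest labels; importance is the
    mean decrease in out-of-bag accuracy when the feature is permuted.
    Recursive elimination divides the retained-variable count by ``step``
    each round, recording the cross-validated error at each size.
    """
    if step <= 1:
        raise ValueError("step must be > 1")
    x = m.values.T if hasattr(m, "values") else np.asarray(m, dtype=float)
    gene_ids = list(m.gene_ids) if hasattr(m, "gene_ids") \
        else [f"G{i}" for i in range(x.shape[1])]
    labels = np.asarray(subtype_labels)
    y = (labels == target_subtype).astype(int)
    if min(y.sum(), (1 - y).sum()) < 5:
        raise ValueError("need >= 5 samples per class")

    rng = np.random.default_rng(seed)
    trees = _fit_bagged_forest(x, y, n_trees, rng)
    imp = _oob_permutation_importance(trees, x, y, rng)
    importance = pd.Series(imp, index=gene_ids, name="importance")
    order = importance.sort_values(ascending=False, kind="mergesort")
    rank = pd.Series(np.arange(1, len(gene_ids) + 1), index=order.index,
                     name="rank").reindex(gene_ids)

    cv_errors = {}
    keep = len(gene_ids)
    while keep >= 1:
        top = order.index[:keep]
        cols = [gene_ids.index(g) for g in top]
        cv_errors[keep] = _cv_error(x[:, cols], y, n_trees, cv_folds, rng)
        if keep == 1:
            break
        keep = max(1, int(keep / step))
    cv_error = pd.Series(cv_errors, name="cv_error").sort_index()
    return MarkerRanking(importance=importance, rank=rank, cv_error=cv_error)


def group_compare(values, groups) -> dict:
    """One-way ANOVA with Tukey HSD post hoc.

    Returns ``{"f": F, "p": p, "tukey": DataFrame}`` where the Tukey table
    has one row per group pair with the studentized-range p-value.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = [g for g in pd.unique(groups)]
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[groups == g] for g in uniq]
    if any(a.size < 2 for a in arrays):
        small = uniq[int(np.argmin([a.size for a in arrays]))]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(values) == 0:
        f, p = 0.0, 1.0
        rows = [{"group_a": a, "group_b": b, "diff": 0.0, "p": 1.0}
                for i, a in enumerate(uniq) for b in uniq[i + 1:]]
        return {"f": f, "p": p, "tukey": pd.DataFrame(rows)}
    f, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            rows.append({
                "group_a": uniq[i],
                "group_b": uniq[j],
                "diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                "p": float(tk.pvalue[i, j]),
            })
    return {"f": float(f), "p": float(p), "tukey": pd.DataFrame(rows)}
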