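"""One-vs-rest differential expression with empirical-Bayes moderated t, BH
multiple-testing correction, and signature extraction.

The per-gene two-group linear model's residual variances are shrunk toward a
pooled inverse-gamma prior fitted by the method of moments on log s^2, and
the moderated t is referred to a t distribution with augmented degrees of
freedom.  The up/down gene lists of the progressive subtype become the
MPscore reference signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DegResult",
    "SignatureSet",
    "moderated_de",
    "bh_adjust",
    "extract_signature",
    "fit_variance_prior",
]


@dataclass(frozen=True)
class SignatureSet:
    """Named up/down gene lists; up and down must be disjoint."""

    name: str
    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "up", tuple(self.up))
        object.__setattr__(self, "down", tuple(self.down))
        if set(self.up) & set(self.down):
            raise ValueError("up and down lists overlap")


@dataclass
class DegResult:
    """Per-gene one-vs-rest differential expression table."""

    table: pd.DataFrame  # log2fc, t, p_value, adj_p_value, ave_expr
    prior_df: float
    prior_var: float


def _solve_trigamma(y: float) -> float:
    """Invert the trigamma function (Newton, as in the moment fit of a
    scaled-F distribution to the sample variances)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the inverse-gamma variance prior.

    Returns (prior_df d0, prior_var s0^2) such that marginally
    s^2 ~ s0^2 * F(df, d0).  d0 may be inf when the variances are more
    concordant than the sampling noise alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        # variances more concordant than sampling noise alone: complete
        # pooling, prior = arithmetic mean of the sample variances
        d0 = np.inf
        s0 = float(np.mean(s2[ok]))
    else:
        d0 = 2.0 * _solve_trigamma(e_var)
        s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                          - np.log(d0 / 2.0)))
    return float(d0), s0


def moderated_de(m, groups, target=None, prior_df: float | None = None) -> DegResult:
    """Empirical-Bayes moderated two-group differential expression.

    Parameters
    ----------
    m
        ExpressionMatrix in log2 units (or any genes x samples array-like
        with ``values``/``gene_ids``/``sample_ids``).
    groups
        Per-sample labels; with ``target`` given, the contrast is
        ``target`` vs rest, otherwise ``groups`` must be boolean/binary with
        True/1 the group of interest.
    prior_df
        Override the fitted prior degrees of freedom; 0 disables shrinkage
        (ordinary pooled t), None fits it from the data.
    """
    if isinstance(m, pd.DataFrame):
        x = m.to_numpy(dtype=float)
        gene_ids = list(m.index)
    elif hasattr(m, "gene_ids"):
        x = m.values
        gene_ids = list(m.gene_ids)
    else:
        x = np.asarray(m, dtype=float)
        gene_ids = [f"G{i}" for i in range(x.shape[0])]
    labels = np.asarray(groups)
    mask = labels == target if target is not None else labels.astype(bool)
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples on each side of the contrast")

    x1, x0 = x[:, mask], x[:, ~mask]
    mean1, mean0 = x1.mean(axis=1), x0.mean(axis=1)
    log2fc = mean1 - mean0
    df_resid = n1 + n0 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) \
        + ((x0 - mean0[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0 = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0 = fit_variance_prior(s2, df_resid) if d0 > 0 else (0.0, 1.0)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    zero_var = s2_post == 0
    if np.any(zero_var):
        warnings.warn(f"{int(zero_var.sum())} genes have zero variance on "
                      "both sides; their p set to 1")
    se = np.sqrt(np.where(zero_var, 1.0, s2_post) * (1.0 / n1 + 1.0 / n0))
    t = log2fc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(zero_var, 1.0, p)
    t = np.where(zero_var, 0.0, t)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p_value": p,
            "adj_p_value": bh_adjust(p),
            "ave_expr": x.mean(axis=1),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return DegResult(table=table, prior_df=float(d0), prior_var=float(s0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def extract_signature(deg: DegResult, name: str = "signature",
                      fdr: float = 0.05, lfc: float = 2.0) -> SignatureSet:
    """Split significant genes into up/down lists at strict thresholds.

    up: adjusted p < fdr and log2FC > lfc; down: adjusted p < fdr and
    log2FC < -lfc; each sorted by adjusted p ascending.
    """
    if fdr <= 0 or lfc <= 0:
        raise ValueError("thresholds must be positive")
    t = deg.table
    sig = t[t["adj_p_value"] < fdr].sort_values(
        ["adj_p_value", "p_value"], kind="mergesort")
    up = tuple(sig.index[sig["log2fc"] > lfc])
    down = tuple(sig.index[sig["log2fc"] < -lfc])
    if not up and not down:
        raise ValueError(
            f"no signature at thresholds fdr<{fdr}, |log2FC|>{lfc}")
    return SignatureSet(name=name, up=up, down=down)
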