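"""DNA-methylation decision rules: CIMP detection, differentially methylated
CpG signatures, arm-level copy-number loss calls, and rule-based subtype
assignment for a methylation-only cohort.

Beta values (fraction methylated, in [0, 1]) are used for interpretation and
the CIMP rule; M values, log2(beta / (1 - beta)), for the moderated-t
differential methylation statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .degsig import moderated_de

__all__ = [
    "beta_to_m",
    "call_cimp",
    "dm_signature",
    "call_arm_loss",
    "assign_methylation_subtype",
]

BETA_CLIP = 1e-6


def beta_to_m(beta: pd.DataFrame) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)) with beta clipped to [1e-6, 1 - 1e-6]."""
    b = beta.clip(BETA_CLIP, 1.0 - BETA_CLIP)
    return np.log2(b / (1.0 - b))


def _check_beta(beta: pd.DataFrame) -> None:
    vals = beta.to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("beta values must lie in [0, 1]")


def call_cimp(beta: pd.DataFrame, group_labels, sd_threshold: float = 0.2,
              hyper_beta: float = 0.5) -> pd.Series:
    """CpG-island methylator phenotype flag per group.

    A group's variable loci are those whose within-group beta standard
    deviation exceeds ``sd_threshold``; the group is CIMP-positive when the
    majority (> 50%) of its variable loci have group-mean beta above
    ``hyper_beta``.  Groups with no variable loci get a missing flag and a
    warning.
    """
    _check_beta(beta)
    labels = pd.Series(np.asarray(group_labels), index=beta.columns)
    flags = {}
    for g, cols in labels.groupby(labels).groups.items():
        if len(cols) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        sub = beta[list(cols)]
        sd = sub.std(axis=1, ddof=1)
        variable = sd > sd_threshold
        if not variable.any():
            warnings.warn(f"group {g!r} has no variable loci; CIMP undefined")
            flags[g] = np.nan
            continue
        hyper = sub.loc[variable].mean(axis=1) > hyper_beta
        flags[g] = bool(hyper.mean() > 0.5)
    return pd.Series(flags, name="cimp")


def dm_signature(beta: pd.DataFrame, groups, delta_m: float = 2.0,
                 fdr: float = 0.05) -> dict:
    """Subtype-specific CpG signatures from pairwise moderated-t contrasts
    on M values.

    A locus belongs to a group's signature when it is significant
    (BH-adjusted p < ``fdr`` and |ΔM| > ``delta_m``) in every pairwise
    contrast of that group against each other group.  Returns
    group -> DataFrame(mean_delta_m) indexed by CpG id.
    """
    _check_beta(beta)
    m = beta_to_m(beta)
    labels = pd.Series(np.asarray(groups), index=beta.columns)
    uniq = list(pd.unique(labels))
    out = {}
    for g in uniq:
        sig_mask = None
        deltas = []
        for h in uniq:
            if h == g:
                continue
            cols = labels.index[(labels == g) | (labels == h)]
            contrast = moderated_de(
                m[cols], (labels.loc[cols] == g).to_numpy())
            t = contrast.table
            hit = (t["adj_p_value"] < fdr) & (t["log2fc"].abs() > delta_m)
            sig_mask = hit if sig_mask is None else (sig_mask & hit)
            deltas.append(t["log2fc"])
        loci = sig_mask[sig_mask].index
        mean_delta = pd.concat(deltas, axis=1).mean(axis=1).loc[loci]
        out[g] = pd.DataFrame({"mean_delta_m": mean_delta})
    return out


def call_arm_loss(cn: pd.DataFrame, arm: str,
                  threshold: float = 0.1) -> pd.Series:
    """Arm-level loss call: mean copy-number value strictly below
    ``threshold``."""
    if arm not in cn.columns:
        raise ValueError(f"arm {arm!r} not present in the copy-number table")
    vals = cn[arm].astype(float)
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite copy-number values for arm {arm!r}")
    return vals < threshold


def assign_methylation_subtype(loss_1p, loss_22q, si,
                               si_threshold: float = 0.5) -> pd.Series:
    """Rule-based subtype for a methylation-only cohort.

    Decision order per sample:
      1. chr1p loss AND chr22q loss         -> subtype 3
      2. chr22q loss alone                  -> subtype 2
      3. stemness index > ``si_threshold``  -> subtype 4
      4. no chr1p and no chr22q loss        -> subtype 1
      otherwise (chr1p loss alone, low SI)  -> unassigned (0) with a warning
    """
    loss_1p = pd.Series(loss_1p)
    loss_22q = pd.Series(loss_22q)
    si = pd.Series(si)
    idx = loss_1p.index
    if not (loss_22q.index.equals(idx) and si.index.equals(idx)):
        raise ValueError("inputs must share the same sample index")
    if loss_1p.isna().any() or loss_22q.isna().any() or si.isna().any():
        raise ValueError("missing arm calls or stemness index values")
    if ((si < 0) | (si > 1)).any():
        raise ValueError("stemness index must lie in [0, 1]")

    out = pd.Series(0, index=idx, dtype=int, name="subtype")
    out[loss_1p & loss_22q] = 3
    remaining = out == 0
    out[remaining & ~loss_1p & loss_22q] = 2
    remaining = out == 0
    out[remaining & (si > si_threshold)] = 4
    remaining = out == 0
    out[remaining & ~loss_1p & ~loss_22q] = 1
    if (out == 0).any():
        warnings.warn(f"{int((out == 0).sum())} samples unassigned "
                      "(chr1p loss alone with low stemness index)")
    return out
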