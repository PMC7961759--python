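"""Survival validation of the MPscore: Kaplan–Meier curves, log-rank test,
multivariable Cox proportional-hazards regression, and MPscore
dichotomization.

Estimation is delegated to lifelines (product-limit estimator, log-rank
statistic, Cox partial likelihood with Breslow tie handling); this module
provides the validated interfaces, input checking, and the reporting layout
(coefficients on the log scale with 95% CI and hazard ratios alongside).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "dichotomize_mpscore",
]


def _check_records(records: pd.DataFrame) -> None:
    if "time" not in records.columns or "event" not in records.columns:
        raise ValueError("records need 'time' and 'event' columns")
    if (records["time"] <= 0).any():
        raise ValueError("follow-up times must be strictly positive")
    if not records["event"].isin([0, 1, True, False]).all():
        raise ValueError("event flags must be 0/1")


def km_estimate(records: pd.DataFrame, group_labels=None) -> dict[object, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns group -> DataFrame indexed by event time with columns
    ``survival`` (S(t), right-censoring handled, S(0) = 1), ``n_at_risk``
    and ``n_events``.
    """
    _check_records(records)
    if group_labels is None:
        group_labels = pd.Series("all", index=records.index)
    labels = pd.Series(np.asarray(group_labels), index=records.index)
    out = {}
    for g, idx in labels.groupby(labels).groups.items():
        sub = records.loc[list(idx)]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"].astype(int))
        table = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        out[g] = pd.DataFrame(
            {
                "survival": surv,
                "n_at_risk": table["at_risk"].reindex(surv.index),
                "n_events": table["observed"].reindex(surv.index),
            }
        )
    return out


def logrank_test(records: pd.DataFrame, group_labels) -> dict:
    """Two-group log-rank test (observed minus expected, 1 df)."""
    _check_records(records)
    labels = pd.Series(np.asarray(group_labels), index=records.index)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    a = records[labels == uniq[0]]
    b = records[labels == uniq[1]]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if int(a["event"].sum()) + int(b["event"].sum()) == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"].astype(int),
                      event_observed_B=b["event"].astype(int))
    return {"statistic": float(res.test_statistic),
            "p_value": float(res.p_value), "df": 1}


def cox_fit(records: pd.DataFrame, covariates: list[str],
            reference_levels: dict | None = None) -> pd.DataFrame:
    """Multivariable Cox proportional-hazards fit (Breslow ties).

    Categorical covariates are dummy-coded against the stated (or first
    observed) reference level.  Returns one row per coefficient with the
    log-scale estimate, its 95% CI, the hazard-ratio scale equivalents, and
    the Wald p-value.
    """
    _check_records(records)
    reference_levels = reference_levels or {}
    design = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov not in records.columns:
            raise ValueError(f"covariate {cov!r} missing from records")
        col = records[cov]
        if col.nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant across samples")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(pd.unique(col))
            ref = reference_levels.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not in {cov!r}")
            for lev in levels:
                if lev == ref:
                    continue
                design[f"{cov}[{lev}]"] = (col == lev).astype(float)
        else:
            design[cov] = col.astype(float)

    n_events = int(records["event"].sum())
    if n_events < design.shape[1] + 1:
        raise ValueError(
            f"{n_events} events cannot support {design.shape[1]} coefficients")

    frame = design.copy()
    frame["time"] = records["time"].astype(float)
    frame["event"] = records["event"].astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # pragma: no cover - lifelines diagnostics
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc

    summary = cph.summary
    return pd.DataFrame(
        {
            "coefficient": summary["coef"],
            "coef_lower95": summary["coef lower 95%"],
            "coef_upper95": summary["coef upper 95%"],
            "hazard_ratio": summary["exp(coef)"],
            "hr_lower95": summary["exp(coef) lower 95%"],
            "hr_upper95": summary["exp(coef) upper 95%"],
            "p_value": summary["p"],
        }
    )


def dichotomize_mpscore(scores) -> tuple[pd.Series, float]:
    """Median split of the MPscore; ties go to "low".

    Returns the high/low label per sample and the cutpoint used.
    """
    scores = pd.Series(scores)
    if scores.size < 2:
        raise ValueError("need at least 2 samples")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; no dichotomization possible")
    cut = float(scores.median())
    labels = pd.Series(np.where(scores > cut, "high", "low"),
                       index=scores.index, name="mpscore_group")
    return labels, cut
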