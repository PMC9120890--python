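"""Clinical endpoints and the statistical layer.

Response endpoints (6-month ORR and clinical benefit rate), ctDNA status
categories, Kaplan-Meier / log-rank / Cox proportional hazards (via
lifelines, Efron tie handling), Fisher's exact test (two-sided
probability-mass rule) and the Wilcoxon rank-sum test (exact by
enumeration for small untied samples, normal approximation with tie
correction otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

log = logging.getLogger(__name__)

RESPONSE_CATEGORIES = {"CR", "PR", "SD", "PD", "NE"}
OBJECTIVE_RESPONSES = {"CR", "PR"}


# ---------------------------------------------------------------------------
# Response endpoints
# ---------------------------------------------------------------------------

def _window_assessments(assessments, window_months: float):
    for month, cat in assessments:
        if cat not in RESPONSE_CATEGORIES:
            raise ValueError(f"unknown response category {cat!r}")
    return [(m, c) for m, c in assessments if c != "NE"]


def orr_6m(assessments, window_months: float = 6.0):
    """6-month objective response: any CR/PR within the first 6 months.

    ``assessments`` is an iterable of ``(month, category)``.  Returns
    ``True``/``False``, or ``None`` (not evaluable) when no assessment
    falls inside the window.
    """
    usable = _window_assessments(assessments, window_months)
    in_window = [(m, c) for m, c in usable if m <= window_months]
    if not in_window:
        log.info("no response assessment within %.1f months: not evaluable", window_months)
        return None
    return any(c in OBJECTIVE_RESPONSES for _, c in in_window)


def cbr_6m(assessments, window_months: float = 6.0):
    """6-month clinical benefit: objective response within 6 months, or
    disease stabilization maintained through 6 months (no progression in
    the window and SD-or-better at >= 6 months)."""
    orr = orr_6m(assessments, window_months)
    if orr is None:
        return None
    if orr:
        return True
    usable = _window_assessments(assessments, window_months)
    progressed = any(c == "PD" and m <= window_months for m, c in usable)
    stable_at_6 = any(c in {"SD", "PR", "CR"} and m >= window_months for m, c in usable)
    return (not progressed) and stable_at_6


def week7_status(baseline_tf: float, week7_tf: float, detection_threshold: float = 0.0) -> str:
    """ctDNA kinetics category after 7 weeks on treatment.

    ``cleared_or_stable_zero`` when the week-7 tumor fraction is at or
    below the detection threshold (TF decreased to 0 or remained 0);
    ``persistent_or_new`` otherwise (TF remained > 0 or became > 0).
    """
    if baseline_tf is None or week7_tf is None:
        raise ValueError("both baseline and week-7 TF are required")
    if week7_tf <= detection_threshold:
        return "cleared_or_stable_zero"
    return "persistent_or_new"


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """One coefficient of a proportional-hazards fit: hazard ratio with
    Wald 95% CI and p-value."""

    hr: float
    ci95: tuple[float, float]
    p_wald: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")


def km(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a right-continuous step function as a DataFrame with columns
    ``time`` and ``survival`` (``S(0) = 1`` included).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    if len(times) != len(events) or len(times) == 0:
        raise ValueError("times and events must be equal-length and non-empty")
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    sf = fitter.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def km_at(table: pd.DataFrame, t: float) -> float:
    """Evaluate a KM step function (right-continuous) at time ``t``."""
    mask = table["time"].to_numpy() <= t
    if not mask.any():
        return 1.0
    return float(table["survival"].to_numpy()[mask][-1])


def logrank(times, events, groups) -> float:
    """Two-or-more-sample log-rank test p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank requires at least two groups")
    if events.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.p_value)


def cox(
    df: pd.DataFrame,
    duration_col: str = "pfs_months",
    event_col: str = "pfs_event",
    covariates: list[str] | None = None,
) -> dict[str, SurvivalFit]:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Returns one :class:`SurvivalFit` per covariate.  Raises on zero
    events or non-convergence (lifelines reports the iteration trace in
    its error message).
    """
    if covariates is None:
        covariates = [c for c in df.columns if c not in (duration_col, event_col)]
    data = df[[duration_col, event_col, *covariates]].dropna()
    if data[event_col].sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    fitter = CoxPHFitter()
    fitter.fit(data, duration_col=duration_col, event_col=event_col)
    out: dict[str, SurvivalFit] = {}
    summ = fitter.summary
    for cov in covariates:
        row = summ.loc[cov]
        out[cov] = SurvivalFit(
            hr=float(row["exp(coef)"]),
            ci95=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
            p_wald=float(row["p"]),
            n=int(len(data)),
            n_events=int(data[event_col].sum()),
        )
    return out


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, summing hypergeometric
    probabilities not exceeding the observed table's probability.

    A table with a zero margin carries no information: p = 1 by
    convention (logged).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        log.info("2x2 table with a zero margin: p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration when ``min(n) <= 10`` and there are no ties;
    otherwise the normal approximation with tie correction (no
    continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= 10 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(min(res.pvalue, 1.0))
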