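"""Survival and categorical statistics shared by panel selection and evaluation.

Implements the Kaplan-Meier product-limit estimator and a tie-aware two-group
log-rank test directly on numpy arrays (the log-rank is the genetic
algorithm's inner loop and is evaluated hundreds of thousands of times per
search, so it needs a vectorized fast path). Cox proportional-hazards fitting
is delegated to :mod:`lifelines` (Efron tie handling, Newton-Raphson with
step-halving); Fisher's exact test and the Wilcoxon rank-sum test wrap
:mod:`scipy.stats`.

Conventions: two-sided p-values throughout; at tied times events precede
censorings (censored subjects remain in the risk set at their own time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "LogRankResult",
    "CoxFit",
    "DegenerateGroupsError",
    "km_estimate",
    "logrank_test",
    "logrank_arrays",
    "cox_fit",
    "cox_score_test",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "records_to_arrays",
]


class DegenerateGroupsError(ValueError):
    """Raised when a two-group comparison is undefined (empty group or no events).

    Callers that treat degenerate splits as uninformative (e.g. the GA fitness
    penalty) catch this and substitute p = 1.
    """


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-event observation for one patient.

    ``time`` is a nonnegative follow-up duration (months); ``event`` is 1 if
    death was observed, 0 if censored. ``covariates`` carries optional named
    values (age, gender, Lauren class, stage, ...).
    """

    sample_id: str
    time: float
    event: int
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event!r}")


@dataclass
class KMEstimate:
    """Product-limit survival curve over the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    observed: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: log-HRs, Wald CIs/p-values, diagnostics."""

    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    separation: bool
    n: int
    n_events: int


def records_to_arrays(
    records: Sequence[SurvivalRecord],
) -> tuple[np.ndarray, np.ndarray]:
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=np.int64)
    return time, event


def _km_steps(time: np.ndarray, event: np.ndarray):
    """Distinct-time risk/event counts for product-limit computation."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ut, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    n_at = len(t) - first
    return ut, d, n_at


def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    Censored times reduce the risk set without introducing a step. Returns the
    curve at the distinct *event* times only.
    """
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    time, event = records_to_arrays(records)
    ut, d, n_at = _km_steps(time, event)
    has_event = d > 0
    factors = 1.0 - d[has_event] / n_at[has_event]
    return KMEstimate(
        event_times=ut[has_event],
        survival=np.cumprod(factors),
        at_risk=n_at[has_event],
        observed=d[has_event],
    )


def _chi2_1df_sf(x: float) -> float:
    """Survival function of chi-square with 1 df; equals erfc(sqrt(x/2))."""
    import math

    return math.erfc(math.sqrt(x / 2.0))


def _logrank_p_sorted(
    e: np.ndarray, g: np.ndarray, t: np.ndarray, nb: int
) -> float:
    """Log-rank p for arrays already sorted by time (GA fast path).

    ``e`` int events, ``g`` bool group, ``t`` sorted times, ``nb`` group-B
    size. Raises :class:`DegenerateGroupsError` on an empty group or zero
    events; same math as :func:`logrank_arrays`.
    """
    n = len(t)
    if nb == 0 or nb == n:
        raise DegenerateGroupsError("one of the groups is empty")
    first = np.flatnonzero(np.concatenate(([True], t[1:] != t[:-1])))
    d = np.add.reduceat(e, first)
    db = np.add.reduceat(e * g, first)
    n_at = n - first
    cg = np.cumsum(g)
    nb_at = nb - np.where(first > 0, cg[first - 1], 0)
    mask = d > 0
    if not mask.any():
        raise DegenerateGroupsError("no events in either group")
    d, db, n_at, nb_at = d[mask], db[mask], n_at[mask], nb_at[mask]
    frac = nb_at / n_at
    oe = float((db - d * frac).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n_at > 1, d * frac * (1.0 - frac) * (n_at - d) / (n_at - 1.0), 0.0
        )
    v = float(var.sum())
    if v <= 0.0:
        return 1.0
    return _chi2_1df_sf(oe * oe / v)


def logrank_arrays(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Two-group log-rank on raw arrays (fast path, no record objects).

    ``group`` is boolean (True = group B). Returns
    ``(chi2, p, observed_b, expected_b, total_events)``. Uses the standard
    tie-aware hypergeometric variance at each distinct event time.

    Raises :class:`DegenerateGroupsError` if either group is empty or there
    are no events at all.
    """
    group = np.asarray(group, dtype=bool)
    nb = int(group.sum())
    if nb == 0 or nb == len(group) or len(group) == 0:
        raise DegenerateGroupsError("one of the groups is empty")
    total_events = float(np.sum(event))
    if total_events == 0:
        raise DegenerateGroupsError("no events in either group")

    order = np.argsort(time, kind="stable")
    e = event[order].astype(np.int64)
    g = group[order]
    t = time[order]
    ut, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    db = np.add.reduceat(e * g, first)
    n_at = len(t) - first
    cg = np.cumsum(g)
    nb_at = nb - np.where(first > 0, cg[first - 1], 0)

    mask = d > 0
    d, db, n_at, nb_at = d[mask], db[mask], n_at[mask], nb_at[mask]
    frac = nb_at / n_at
    expected_b = d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n_at > 1,
            d * frac * (1.0 - frac) * (n_at - d) / (n_at - 1.0),
            0.0,
        )
    observed_b = float(db.sum())
    eb = float(expected_b.sum())
    v = float(var.sum())
    if v <= 0.0:
        return 0.0, 1.0, observed_b, eb, total_events
    chi2 = (observed_b - eb) ** 2 / v
    return float(chi2), _chi2_1df_sf(chi2), observed_b, eb, total_events


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Standard two-group log-rank test (chi-square, 1 df, two-sided)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise DegenerateGroupsError("both groups must contain at least one record")
    ta, ea = records_to_arrays(group_a)
    tb, eb = records_to_arrays(group_b)
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    group = np.concatenate(
        [np.zeros(len(ta), dtype=bool), np.ones(len(tb), dtype=bool)]
    )
    chi2, p, ob, exb, total = logrank_arrays(time, event, group)
    return LogRankResult(
        statistic=chi2,
        p_value=p,
        observed=(total - ob, ob),
        expected=(total - exb, exb),
    )


def _encode_covariates(
    records: Sequence[SurvivalRecord], covariates: Sequence[str]
) -> pd.DataFrame:
    """Design matrix: numeric covariates as-is, categoricals treatment-coded
    with the most frequent level as reference."""
    raw = pd.DataFrame(
        {c: [r.covariates.get(c) for r in records] for c in covariates}
    )
    cols = {}
    for c in covariates:
        col = raw[c]
        if col.isna().any():
            raise ValueError(f"covariate {c!r} has missing values")
        if pd.api.types.is_numeric_dtype(col) and col.dtype != bool:
            if col.nunique() < 2:
                raise ValueError(f"covariate {c!r} is constant")
            cols[c] = col.astype(float)
        else:
            levels = col.astype(str).value_counts().index.tolist()
            if len(levels) < 2:
                raise ValueError(f"covariate {c!r} is constant")
            for lev in levels[1:]:  # levels[0] = most frequent -> reference
                cols[f"{c}[{lev}]"] = (col.astype(str) == lev).astype(float)
    return pd.DataFrame(cols)


def cox_fit(
    records: Sequence[SurvivalRecord], covariates: Sequence[str]
) -> CoxFit:
    """Cox proportional-hazards regression (Efron ties, Newton-type solver).

    Wald 95% confidence intervals and p-values per covariate. Non-convergence
    and monotone-likelihood (separation) are surfaced as flags on the result
    rather than producing silent garbage.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    if len(records) < 2:
        raise ValueError("cox_fit requires at least two records")
    time, event = records_to_arrays(records)
    if event.sum() == 0:
        raise ValueError("cox_fit requires at least one observed event")
    X = _encode_covariates(records, covariates)
    if X.drop_duplicates().shape[0] < 2:
        raise ValueError("need >=2 distinct covariate patterns")
    df = X.copy()
    df["__time"] = time
    df["__event"] = event

    cph = CoxPHFitter()
    converged = True
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="__time", event_col="__event")
        except ConvergenceError as err:
            raise ValueError(f"Cox model failed to converge: {err}") from err
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            msg = str(w.message).lower()
            if "separation" in msg or "monotone" in msg or "infinite" in msg:
                separation = True
            else:
                converged = False

    summ = cph.summary
    names = list(summ.index)
    return CoxFit(
        coefficients={k: float(summ.loc[k, "coef"]) for k in names},
        hazard_ratios={k: float(summ.loc[k, "exp(coef)"]) for k in names},
        ci_lower={k: float(summ.loc[k, "exp(coef) lower 95%"]) for k in names},
        ci_upper={k: float(summ.loc[k, "exp(coef) upper 95%"]) for k in names},
        p_values={k: float(summ.loc[k, "p"]) for k in names},
        standard_errors={k: float(summ.loc[k, "se(coef)"]) for k in names},
        converged=converged,
        separation=separation,
        n=len(records),
        n_events=int(event.sum()),
    )


def cox_score_test(
    time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> float:
    """Cox partial-likelihood score statistic at beta = 0 for one covariate.

    With a single binary covariate and no tied event times this equals the
    log-rank chi-square exactly, which makes it a useful independent
    cross-check of both routines. Computed directly from the score
    U(0) = sum over events of (x_i - mean of x over the risk set) and the
    observed information at zero.
    """
    order = np.argsort(time, kind="stable")
    t, e, xv = time[order], event[order].astype(bool), x[order].astype(float)
    n = len(t)
    # risk set for the subject at sorted position i is positions i..n-1
    s1 = np.cumsum(xv[::-1])[::-1]
    s2 = np.cumsum((xv**2)[::-1])[::-1]
    m = n - np.arange(n)
    # at tied times every subject with the same time shares one risk set:
    # map each position to the first position with that time
    first_same = np.searchsorted(t, t, side="left")
    mean = s1[first_same] / m[first_same]
    var = s2[first_same] / m[first_same] - mean**2
    u = float(np.sum(xv[e] - mean[e]))
    info = float(np.sum(var[e]))
    if info <= 0:
        return 0.0
    return u**2 / info


def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums the probabilities of all tables (with the observed margins) whose
    hypergeometric probability does not exceed the observed table's.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if arr.sum() < 1:
        raise ValueError("table total must be >= 1")
    return float(stats.fisher_exact(arr.astype(np.int64), alternative="two-sided")[1])


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the combined sample size is <= 10 and there are no
    ties; otherwise the tie-corrected normal approximation. Degenerate input
    (every value identical across both samples) returns p = 1 with a warning.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([xa, ya])
    if np.all(combined == combined[0]):
        warnings.warn("all values identical across both samples; p = 1")
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))
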