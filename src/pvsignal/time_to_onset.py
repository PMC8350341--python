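"""Time-to-onset profiling: latency extraction, quartile summaries, and
Weibull hazard-shape classification.

Latency is the number of days from the start of administration of a
suspected drug to the onset of a matching adverse event, using only
(report, drug, event) combinations where both dates are complete, within
an analysis window (default 90 days). The latency sample is summarized by
median and quartiles and fitted with a two-parameter Weibull distribution;
the shape parameter β read together with its 95% CI classifies the onset
hazard as increasing (CI above 1), decreasing (CI below 1), or compatible
with constant (CI spans 1).

The Weibull fit is a maximum-likelihood fit on (ln α, ln β) with Wald
intervals from the observed information matrix — log-scale intervals keep
both bounds positive. Same-day onsets (0 days) enter the likelihood as
half a day, the usual convention for day-resolution data; medians and
quartiles keep the raw zeros.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dates import complete_dates
from .event_dictionary import PtSet
from .srs_store import SrsDatabase, match_drug_rows

DEFAULT_WINDOW_DAYS = 90
ZERO_DAY_SHIFT = 0.5  # same-day onset enters the likelihood as half a day
Z_95 = 1.96


@dataclass(frozen=True)
class OnsetDuration:
    report_id: str
    drug_name: str
    pt_name: str
    days: int

    def __post_init__(self):
        if self.days < 0:
            raise ValueError("negative onset latency")


@dataclass
class DurationSet:
    """Retained latencies plus an exclusion tally for auditability."""

    durations: list[OnsetDuration]
    exclusions: dict[str, int] = field(default_factory=dict)

    def __len__(self):
        return len(self.durations)

    def __iter__(self):
        return iter(self.durations)

    def days(self) -> np.ndarray:
        return np.array([d.days for d in self.durations], dtype=float)


@dataclass(frozen=True)
class TimeSummary:
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class WeibullFit:
    n: int
    converged: bool
    scale_alpha: float | None = None
    alpha_ci: tuple[float, float] | None = None
    shape_beta: float | None = None
    beta_ci: tuple[float, float] | None = None


class HazardClass(enum.Enum):
    INCREASING = "increasing"
    CONSTANT_COMPATIBLE = "constant_compatible"
    DECREASING = "decreasing"


def _as_days(durations) -> np.ndarray:
    if isinstance(durations, DurationSet):
        return durations.days()
    arr = [d.days if isinstance(d, OnsetDuration) else float(d) for d in durations]
    return np.asarray(arr, dtype=float)


def compute_durations(
    db: SrsDatabase,
    drug_group: list[str],
    pt_set: PtSet,
    window_days: int = DEFAULT_WINDOW_DAYS,
    contains: bool = False,
    anchor: str = "start",
) -> DurationSet:
    """Latencies for one drug group × one case definition.

    For every (report, matching suspected drug, matching event) with
    complete dates: days = onset − earliest complete anchor date of that
    drug in that report, retained when 0 ≤ days ≤ window. One latency per
    (report, drug, PT). ``anchor`` is "start" (administration start,
    default) or "end" (last administration date).
    """
    date_col = {"start": "start_date", "end": "end_date"}[anchor]
    drows = match_drug_rows(db, drug_group, contains=contains)
    drows = drows[drows["involvement"] == "suspected"].copy()
    drows["_anchor"] = complete_dates(drows[date_col])

    # earliest complete anchor per (report, drug); drugs with no complete
    # anchor keep NaT so the incomplete tally can count their pairings
    anchor_by = (
        drows.groupby(["report_id", "drug_name_norm"], sort=True)["_anchor"]
        .min()
        .reset_index()
    )

    erows = db.reac[db.reac["pt_name"].isin(pt_set.pts)].copy()
    erows["_onset"] = complete_dates(erows["onset_date"])
    # earliest complete onset per (report, PT)
    erows = (
        erows.sort_values("_onset", kind="stable", na_position="last")
        .drop_duplicates(subset=["report_id", "pt_name"], keep="first")
    )

    pairs = anchor_by.merge(erows[["report_id", "pt_name", "_onset"]], on="report_id")
    tallies = {"incomplete_date": 0, "negative": 0, "beyond_window": 0}
    if len(pairs) == 0:
        return DurationSet([], tallies)

    complete = pairs["_anchor"].notna() & pairs["_onset"].notna()
    tallies["incomplete_date"] = int((~complete).sum())
    pairs = pairs[complete]
    days = (pairs["_onset"] - pairs["_anchor"]).dt.days
    tallies["negative"] = int((days < 0).sum())
    tallies["beyond_window"] = int((days > window_days).sum())
    keep = (days >= 0) & (days <= window_days)

    out = [
        OnsetDuration(report_id=r, drug_name=dn, pt_name=pt, days=int(dy))
        for r, dn, pt, dy in zip(
            pairs.loc[keep, "report_id"],
            pairs.loc[keep, "drug_name_norm"],
            pairs.loc[keep, "pt_name"],
            days[keep],
        )
    ]
    return DurationSet(out, tallies)


def summarize_times(durations, method: str = "linear") -> TimeSummary:
    """Median and quartiles (linear interpolation between order statistics
    by default — the "type 7" rule; ``method`` passes through to numpy)."""
    days = _as_days(durations)
    if days.size == 0:
        raise ValueError("cannot summarize an empty latency sample")
    q1, med, q3 = np.percentile(days, [25, 50, 75], method=method)
    return TimeSummary(n=int(days.size), median=float(med), q1=float(q1), q3=float(q3))


def _weibull_nll_grad(params: np.ndarray, log_t: np.ndarray) -> tuple[float, np.ndarray]:
    la, lb = params
    beta = math.exp(lb)
    n = log_t.size
    z = beta * (log_t - la)
    ez = np.exp(z)
    ll = n * lb + z.sum() - log_t.sum() - ez.sum()
    dla = beta * (ez.sum() - n)
    dlb = n + z.sum() - (z * ez).sum()
    return -ll, -np.array([dla, dlb])


def _hessian_fd(params: np.ndarray, log_t: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    h = np.zeros((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = eps
        _, gp = _weibull_nll_grad(params + step, log_t)
        _, gm = _weibull_nll_grad(params - step, log_t)
        h[:, j] = (gp - gm) / (2 * eps)
    return (h + h.T) / 2


def fit_weibull(
    durations,
    min_n: int = 3,
    ci_method: str = "wald",
    n_boot: int = 500,
    seed: int | None = None,
    fix_shape: float | None = None,
) -> WeibullFit:
    """Two-parameter Weibull MLE on the zero-shifted latency sample.

    Returns an unfitted (``converged=False``) result when n < min_n or the
    shifted sample has fewer than two distinct values, mirroring the "-"
    cells of onset tables. ``fix_shape`` pins β (the exponential sub-model
    at β=1 has the closed form α̂ = sample mean). ``ci_method`` is "wald"
    (observed information on the log scale) or "bootstrap" (percentile,
    seeded).
    """
    t = _as_days(durations)
    n = int(t.size)
    t = np.where(t <= 0, ZERO_DAY_SHIFT, t)
    if n < min_n or np.unique(t).size < 2:
        return WeibullFit(n=n, converged=False)

    log_t = np.log(t)

    if fix_shape is not None:
        beta = float(fix_shape)
        alpha = float(np.mean(t**beta) ** (1.0 / beta))
        return WeibullFit(n=n, converged=True, scale_alpha=alpha,
                          alpha_ci=None, shape_beta=beta, beta_ci=None)

    # Gumbel-moment initialisation for ln t
    s = float(np.std(log_t, ddof=1))
    beta0 = math.pi / (math.sqrt(6) * max(s, 1e-3))
    la0 = float(np.mean(log_t)) + 0.5772 / beta0
    x0 = np.array([la0, math.log(beta0)])

    res = minimize(_weibull_nll_grad, x0, args=(log_t,), jac=True, method="L-BFGS-B")
    if not res.success:
        return WeibullFit(n=n, converged=False)
    la, lb = res.x
    alpha, beta = math.exp(la), math.exp(lb)

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            sample = rng.choice(t, size=n, replace=True)
            if np.unique(sample).size < 2:
                continue
            sub = fit_weibull(sample, min_n=min_n, ci_method="none")
            if sub.converged:
                boots.append((sub.scale_alpha, sub.shape_beta))
        if len(boots) < max(20, n_boot // 10):
            return WeibullFit(n=n, converged=False)
        arr = np.array(boots)
        alo, ahi = np.percentile(arr[:, 0], [2.5, 97.5])
        blo, bhi = np.percentile(arr[:, 1], [2.5, 97.5])
        return WeibullFit(n=n, converged=True, scale_alpha=alpha,
                          alpha_ci=(float(alo), float(ahi)),
                          shape_beta=beta, beta_ci=(float(blo), float(bhi)))

    if ci_method == "none":
        return WeibullFit(n=n, converged=True, scale_alpha=alpha, alpha_ci=None,
                          shape_beta=beta, beta_ci=None)

    hess = _hessian_fd(res.x, log_t)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return WeibullFit(n=n, converged=False)
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        return WeibullFit(n=n, converged=False)
    se_la, se_lb = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    alpha_ci = (alpha * math.exp(-Z_95 * se_la), alpha * math.exp(Z_95 * se_la))
    beta_ci = (beta * math.exp(-Z_95 * se_lb), beta * math.exp(Z_95 * se_lb))
    return WeibullFit(n=n, converged=True, scale_alpha=alpha, alpha_ci=alpha_ci,
                      shape_beta=beta, beta_ci=beta_ci)


def classify_hazard(fit: WeibullFit) -> HazardClass:
    """Increasing hazard when the β CI sits above 1, decreasing when below,
    otherwise compatible with a constant hazard."""
    if not fit.converged or fit.beta_ci is None:
        raise ValueError("hazard classification requires a converged fit with a CI")
    lo, hi = fit.beta_ci
    if lo > 1.0:
        return HazardClass.INCREASING
    if hi < 1.0:
        return HazardClass.DECREASING
    return HazardClass.CONSTANT_COMPATIBLE
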