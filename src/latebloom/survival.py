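"""Survival-statistics primitives.

Implements the product-limit estimator, landmark time-window restriction,
Cox partial-likelihood fitting with the Efron tie correction and Wald
inference, the scaled-Schoenfeld correlation test of the proportional
hazards assumption, kernel (Epanechnikov) hazard-rate smoothing of
Nelson-Aalen increments, the Wilcoxon rank-sum test with small-sample exact
enumeration, and 2x2 contingency tests.

Survival data enter as a :class:`pandas.DataFrame` with columns
``time_years`` (strictly positive) and ``event`` (1 = distant event,
0 = censored); covariates are additional columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TIME_COL = "time_years"
EVENT_COL = "event"


class SurvivalError(ValueError):
    pass


class ConvergenceError(SurvivalError):
    pass


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise SurvivalError("no survival records")
    for col in (TIME_COL, EVENT_COL):
        if col not in records.columns:
            raise SurvivalError(f"missing required column {col!r}")
    t = records[TIME_COL].to_numpy(dtype=float)
    d = records[EVENT_COL].to_numpy()
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise SurvivalError("times must be finite and > 0")
    if not np.all(np.isin(d, (0, 1))):
        raise SurvivalError("event indicator must be 0 or 1")
    return records


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times.

    ``times`` are the distinct times with >=1 event; censoring tied with an
    event time is handled after the events (still at risk).  ``survival``
    is right-continuous; Greenwood standard errors accompany each step.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    std_err: np.ndarray
    n: int
    total_events: int

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """Right-continuous S(t); S = 1 before the first event time."""
        if len(self.times) == 0:
            out = np.ones_like(np.atleast_1d(t), dtype=float)
            return out if np.ndim(t) else 1.0
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if np.ndim(t) else float(out[0])


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance."""
    validate_records(records)
    t = records[TIME_COL].to_numpy(dtype=float)
    d = records[EVENT_COL].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    n = len(t)
    ev_times = np.unique(t[d == 1])
    surv = np.empty(len(ev_times))
    at_risk = np.empty(len(ev_times), dtype=int)
    n_ev = np.empty(len(ev_times), dtype=int)
    se = np.empty(len(ev_times))
    s = 1.0
    gw = 0.0  # Greenwood sum of d / (n (n - d))
    for k, tk in enumerate(ev_times):
        nk = int(np.sum(t >= tk))
        dk = int(np.sum((t == tk) & (d == 1)))
        s *= 1.0 - dk / nk
        if nk > dk:
            gw += dk / (nk * (nk - dk))
        at_risk[k], n_ev[k], surv[k] = nk, dk, s
        se[k] = s * math.sqrt(gw) if s > 0 else 0.0
    return KMCurve(ev_times, surv, at_risk, n_ev, se, n=n, total_events=int(d.sum()))


def nelson_aalen(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Distinct event times and Nelson-Aalen increments d_k / n_k."""
    validate_records(records)
    t = records[TIME_COL].to_numpy(dtype=float)
    d = records[EVENT_COL].to_numpy(dtype=int)
    ev_times = np.unique(t[d == 1])
    increments = np.array([
        np.sum((t == tk) & (d == 1)) / np.sum(t >= tk) for tk in ev_times
    ])
    return ev_times, increments


# ---------------------------------------------------------------------------
# Landmark restriction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeWindow:
    """Half-open analysis window (t0, t1]; t1 may be infinite."""

    t0: float
    t1: float = math.inf

    def __post_init__(self) -> None:
        if not (0 <= self.t0 < self.t1):
            raise SurvivalError(f"invalid window ({self.t0}, {self.t1})")

    @property
    def label(self) -> str:
        hi = "inf" if math.isinf(self.t1) else f"{self.t1:g}"
        return f"{self.t0:g}-{hi}"


def landmark_restrict(records: pd.DataFrame, window: TimeWindow) -> pd.DataFrame:
    """Restrict to patients event-free at t0 and truncate follow-up at t1.

    Entry requires T > t0 strictly; times are re-origined to T - t0; records
    surviving past t1 are censored at t1 - t0; events in (t0, t1] stay events.
    """
    validate_records(records)
    kept = records[records[TIME_COL] > window.t0].copy()
    if len(kept) == 0:
        raise SurvivalError(f"empty risk set at landmark t0={window.t0}")
    t = kept[TIME_COL].to_numpy(dtype=float)
    d = kept[EVENT_COL].to_numpy(dtype=int)
    beyond = t > window.t1
    d = np.where(beyond, 0, d)
    t = np.minimum(t, window.t1) - window.t0
    kept[TIME_COL] = t
    kept[EVENT_COL] = d
    return kept


# ---------------------------------------------------------------------------
# Cox model with Efron ties
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Wald inference for one fitted Cox model."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    window: TimeWindow | None = None
    converged: bool = True
    warnings: list[str] = field(default_factory=list)
    cov: np.ndarray | None = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - 1.96 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + 1.96 * self.se)

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.names,
            "coef": self.coef,
            "se": self.se,
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
        })


def _efron_loglik_parts(t, d, X, beta):
    """Log partial likelihood, score and information under Efron ties.

    Returns (loglik, gradient, information, event_data) where event_data
    caches the per-event-time structures reused by the Schoenfeld residuals.
    """
    n, p = X.shape
    order = np.argsort(-t, kind="stable")  # descending time
    t, d, X = t[order], d[order], X[order]
    eta = X @ beta
    # cap to keep exp finite under diverging beta
    w = np.exp(np.clip(eta, -500, 500))
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    event_times: list[float] = []
    event_xbars: list[np.ndarray] = []   # mean of Efron-weighted risk means
    event_xsums: list[np.ndarray] = []   # sum of covariates of tied deaths
    event_counts: list[int] = []
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # accumulate everyone at this time into the risk set
        S0 += w[i:j].sum()
        S1 += wX[i:j].sum(axis=0)
        S2 += wXX[i:j].sum(axis=0)
        dead = np.flatnonzero(d[i:j] == 1) + i
        m = len(dead)
        if m:
            sD0 = w[dead].sum()
            sD1 = wX[dead].sum(axis=0)
            sD2 = wXX[dead].sum(axis=0)
            xsum = X[dead].sum(axis=0)
            loglik += eta[dead].sum()
            xbar_sum = np.zeros(p)
            for l in range(m):
                f = l / m
                denom = S0 - f * sD0
                num1 = S1 - f * sD1
                num2 = S2 - f * sD2
                loglik -= math.log(denom)
                xbar = num1 / denom
                xbar_sum += xbar
                grad -= xbar
                info += num2 / denom - np.outer(xbar, xbar)
            grad += xsum
            event_times.append(float(t[i]))
            event_xbars.append(xbar_sum / m)
            event_xsums.append(xsum)
            event_counts.append(m)
        i = j
    ev = {
        "times": np.array(event_times[::-1]),
        "xbars": np.array(event_xbars[::-1]).reshape(-1, p),
        "xsums": np.array(event_xsums[::-1]).reshape(-1, p),
        "counts": np.array(event_counts[::-1], dtype=int),
    }
    return loglik, grad, info, ev


def cox_fit(records: pd.DataFrame,
            covariates: list[str],
            window: TimeWindow | None = None,
            max_iter: int = 50,
            tol: float = 1e-8) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Ties are handled by the Efron correction.  Convergence requires the
    information-scaled Newton step to fall below ``tol`` in max norm (or 50
    iterations, flagged as non-converged).  Standard errors come from the
    inverse observed information; confidence limits are exp(beta +- 1.96 se).

    A window triggers :func:`landmark_restrict` first.  Monotone likelihood
    (separation) is flagged with a diverging-coefficient warning rather than
    raised; a singular information matrix raises :class:`SurvivalError`.
    """
    if window is not None:
        records = landmark_restrict(records, window)
    validate_records(records)
    sub = records[[TIME_COL, EVENT_COL, *covariates]].dropna()
    dropped = len(records) - len(sub)
    if dropped:
        logger.info("cox_fit: %d records dropped for missing covariates", dropped)
    t = sub[TIME_COL].to_numpy(dtype=float)
    d = sub[EVENT_COL].to_numpy(dtype=int)
    X = sub[covariates].to_numpy(dtype=float)
    n_events = int(d.sum())
    if n_events == 0:
        raise SurvivalError("no events in fitting window")

    p = X.shape[1]
    # center covariates for numerical stability; beta is unaffected
    center = X.mean(axis=0)
    Xc = X - center
    scale = Xc.std(axis=0)
    scale[scale == 0] = 1.0  # constant column -> singular info, caught below
    beta = np.zeros(p)
    warnings: list[str] = []
    converged = False
    diverged = False
    loglik = -math.inf
    for _ in range(max_iter):
        loglik, grad, info, _ = _efron_loglik_parts(t, d, Xc, beta)
        if np.linalg.cond(info) > 1e12:
            if np.max(np.abs(beta * scale)) > 10:
                diverged = True  # flat likelihood along a diverging direction
                break
            raise SurvivalError(
                "singular information matrix (collinear covariates?)")
        step = np.linalg.solve(info, grad)
        # scale-invariant stopping rule (covariate-sd units)
        if np.max(np.abs(step * scale)) < tol:
            converged = True
            break
        # step halving if the likelihood would decrease
        new_beta = beta + step
        new_ll = _efron_loglik_parts(t, d, Xc, new_beta)[0]
        halvings = 0
        while new_ll < loglik and halvings < 10:
            step /= 2.0
            new_beta = beta + step
            new_ll = _efron_loglik_parts(t, d, Xc, new_beta)[0]
            halvings += 1
        beta = new_beta
        if np.max(np.abs(beta * scale)) > 15:
            diverged = True
            break
    loglik, grad, info, _ = _efron_loglik_parts(t, d, Xc, beta)
    if diverged:
        warnings.append(
            "diverging coefficient (monotone likelihood / complete separation?)"
        )
        logger.warning("cox_fit: %s", warnings[-1])
    elif not converged:
        warnings.append(f"not converged in {max_iter} iterations")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        if diverged:
            cov = np.linalg.pinv(info)
        else:
            raise SurvivalError("singular information matrix at optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxResult(list(covariates), beta, se, loglik, n=len(sub),
                     n_events=n_events, window=window, converged=converged,
                     warnings=warnings, cov=cov)


def make_dummies(records: pd.DataFrame, column: str, reference: str,
                 prefix: str | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Expand a categorical column into 0/1 contrasts against ``reference``."""
    levels = [lv for lv in pd.unique(records[column].dropna()) if lv != reference]
    if reference not in set(records[column].dropna()):
        raise SurvivalError(
            f"reference level {reference!r} absent from column {column!r}"
        )
    out = records.copy()
    prefix = prefix or column
    if not levels:
        logger.info("dropping constant covariate %s (only level %r present)",
                    column, reference)
    names = []
    for lv in sorted(map(str, levels)):
        name = f"{prefix}[{lv}]"
        out[name] = np.where(records[column].isna(), np.nan,
                             (records[column].astype(str) == lv).astype(float))
        names.append(name)
    return out, names


# ---------------------------------------------------------------------------
# Scaled Schoenfeld PH test
# ---------------------------------------------------------------------------

@dataclass
class PHTestResult:
    """Correlation test of scaled Schoenfeld residuals against g(time)."""

    names: list[str]
    statistic: np.ndarray
    p: np.ndarray
    global_statistic: float
    global_p: float
    transform: str


def _km_transform(records: pd.DataFrame, event_times: np.ndarray) -> np.ndarray:
    """g(t) = 1 - S_KM(t-) evaluated at the event times (left-continuous)."""
    km = km_estimate(records)
    idx = np.searchsorted(km.times, event_times, side="left") - 1
    s_left = np.where(idx < 0, 1.0, km.survival[np.clip(idx, 0, None)])
    return 1.0 - s_left


def schoenfeld_residuals(result: CoxResult, records: pd.DataFrame,
                         return_counts: bool = False):
    """Per-event-time Schoenfeld residuals (summed over tied deaths).

    Returns (event_times, residual matrix of shape n_event_times x p),
    plus the tied-death counts when ``return_counts`` is set.  For tied
    deaths the Efron-weighted risk-set means are averaged.
    """
    if result.window is not None:
        records = landmark_restrict(records, result.window)
    sub = records[[TIME_COL, EVENT_COL, *result.names]].dropna()
    t = sub[TIME_COL].to_numpy(dtype=float)
    d = sub[EVENT_COL].to_numpy(dtype=int)
    X = sub[result.names].to_numpy(dtype=float)
    center = X.mean(axis=0)
    _, _, _, ev = _efron_loglik_parts(t, d, X - center, result.coef)
    resid = ev["xsums"] - ev["counts"][:, None] * ev["xbars"]
    if return_counts:
        return ev["times"], resid, ev["counts"]
    return ev["times"], resid


def schoenfeld_ph_test(result: CoxResult, records: pd.DataFrame,
                       transform: str = "km") -> PHTestResult:
    """Score test for a time trend in the scaled Schoenfeld residuals.

    Per covariate: chi-square(1) statistic
    ``d * (g' r V)_k^2 / (V_kk * sum g^2)`` with g the centered transformed
    event times, r the residual matrix and V the coefficient covariance;
    globally: ``d * (g'r) V (g'r)' / sum g^2`` on p degrees of freedom.
    ``transform`` is ``"km"`` (1 - left-continuous KM) or ``"identity"``.
    """
    times, resid, counts = schoenfeld_residuals(result, records,
                                                return_counts=True)
    if result.n_events < 3 or resid.shape[0] < 2:
        raise SurvivalError("PH test needs >=3 events over >=2 distinct times")
    if transform == "km":
        if result.window is not None:
            rec = landmark_restrict(records, result.window)
        else:
            rec = records
        g = _km_transform(rec[[TIME_COL, EVENT_COL]].dropna(), times)
    elif transform == "identity":
        g = times.astype(float)
    else:
        raise SurvivalError(f"unknown time transform {transform!r}")
    # residual rows are summed over tied deaths, so g enters with event
    # multiplicity weights (each tied death shares its time's g value)
    V = result.cov
    d_tot = result.n_events
    gbar = float(np.sum(counts * g)) / d_tot
    gc = g - gbar
    gr = gc @ resid  # length p
    ssg = float(np.sum(counts * gc ** 2))
    # per-covariate statistic: d * (V g'r)_k^2 / (V_kk sum g^2), chi2(1)
    per = d_tot * ((V @ gr) ** 2 / np.diag(V)) / ssg
    glob = float(d_tot * gr @ V @ gr / ssg)
    p_per = stats.chi2.sf(per, df=1)
    p_glob = float(stats.chi2.sf(glob, df=len(result.names)))
    return PHTestResult(list(result.names), per, p_per, glob, p_glob, transform)


# ---------------------------------------------------------------------------
# Kernel hazard estimation
# ---------------------------------------------------------------------------

@dataclass
class HazardCurve:
    grid: np.ndarray
    hazard: np.ndarray
    bandwidth: float
    kernel: str = "epanechnikov"


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u ** 2), 0.0)


def _epanechnikov_cdf(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, -1.0, 1.0)
    return 0.25 * (2.0 + 3.0 * u - u ** 3)


def kernel_hazard(records: pd.DataFrame,
                  bandwidth: float | None = None,
                  grid: np.ndarray | None = None) -> HazardCurve:
    """Epanechnikov-smoothed Nelson-Aalen hazard with boundary correction.

    h(t) = sum_k K_b(t - t_k) dLambda(t_k), each kernel renormalized by its
    mass inside the observed follow-up range [0, t_max] so the estimate does
    not sag near either boundary.  Default bandwidth is t_max / 8.
    """
    validate_records(records)
    t_max = float(records[TIME_COL].max())
    if bandwidth is None:
        bandwidth = t_max / 8.0
    if bandwidth <= 0:
        raise SurvivalError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(0.0, t_max, 101)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > t_max + 1e-12):
        raise SurvivalError("grid must lie inside the observed follow-up range")
    ev_times, increments = nelson_aalen(records)
    if len(ev_times) == 0:
        logger.warning("kernel_hazard: no events; returning zero curve")
        return HazardCurve(grid, np.zeros_like(grid), bandwidth)
    u = (grid[:, None] - ev_times[None, :]) / bandwidth
    k = _epanechnikov(u) / bandwidth
    # renormalize each (grid point, event) kernel by its mass within [0, t_max]
    mass = (_epanechnikov_cdf((t_max - ev_times) / bandwidth)
            - _epanechnikov_cdf((0.0 - ev_times) / bandwidth))
    mass = np.clip(mass, 1e-12, None)
    hazard = (k / mass[None, :]) @ increments
    return HazardCurve(grid, np.clip(hazard, 0.0, None), bandwidth)


# ---------------------------------------------------------------------------
# Rank-sum and contingency tests
# ---------------------------------------------------------------------------

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating the null distribution of
    the smaller sample's rank sum (no ties)."""
    if len(x) > len(y):
        x, y = y, x
    n1, n = len(x), len(x) + len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    # distribution of sum of n1 ranks chosen from 1..n: DP over rank values
    # table[k] maps achievable sums -> counts for subsets of size k
    max_sum = n1 * n
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            counts[k, r:] += counts[k - 1, :-r or None]
    dist = counts[n1]
    total = dist.sum()
    lo = dist[: int(round(w_obs)) + 1].sum() / total
    hi = dist[int(round(w_obs)):].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when min(n_x, n_y) <= 8 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise SurvivalError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= 8 and not has_ties:
        return _exact_ranksum_p(x, y)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def contingency_test(table, method: str = "chi2_cc") -> float:
    """Two-sided p for a 2x2 table.

    ``chi2_cc``: chi-square with Yates continuity correction on 1 df
    (falls back to Fisher with a warning when a margin is zero);
    ``fisher``: exact two-sided hypergeometric test.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0) or np.any(tab != np.round(tab)):
        raise SurvivalError("table must be 2x2 nonnegative integer counts")
    if method == "chi2_cc":
        rows, cols = tab.sum(axis=1), tab.sum(axis=0)
        if np.any(rows == 0) or np.any(cols == 0):
            logger.warning("zero margin in 2x2 table; falling back to Fisher")
            return contingency_test(tab, method="fisher")
        expected = np.outer(rows, cols) / tab.sum()
        # Yates correction clamped at zero so proportional tables give p = 1
        stat = float(np.sum(np.maximum(np.abs(tab - expected) - 0.5, 0.0) ** 2
                            / expected))
        return float(stats.chi2.sf(stat, df=1))
    if method == "fisher":
        _, p = stats.fisher_exact(tab.astype(int), alternative="two-sided")
        return float(p)
    raise SurvivalError(f"unknown contingency method {method!r}")
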