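"""Survival machinery implemented from first principles.

Kaplan-Meier product-limit estimation, the two-group log-rank test,
maximally selected rank statistics for optimal dichotomization of a
continuous covariate, and univariate Cox proportional-hazards regression
(Newton-Raphson on the partial likelihood, Efron or Breslow tie handling).
These are combined into a per-variable survival screen: for each immune
variable x compartment x endpoint the covariate is split at the cutpoint
maximizing the absolute standardized log-rank statistic over all admissible
splits, and the Cox hazard ratio of high vs low is reported with a Wald CI
and p-value. p-values are unadjusted; the selection-induced inflation of
the cutpoint screen is a documented property, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm


class SurvivalError(ValueError):
    pass


class UntestableError(SurvivalError):
    """No events (or otherwise empty information) — test undefined."""


class NoCutpointError(SurvivalError):
    """No admissible cutpoint under the minprop constraint."""


class SingularError(SurvivalError):
    """Constant covariate — partial likelihood has no information."""


class ConvergenceError(SurvivalError):
    """Monotone partial likelihood (perfect separation) or failed Newton steps."""

    def __init__(self, message: str, direction: int = 0):
        super().__init__(message)
        self.direction = direction


def _validate_times(time, event) -> Tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise SurvivalError("time and event must have equal length")
    if time.size == 0:
        raise SurvivalError("empty sample")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise SurvivalError("all survival times must be finite and > 0")
    if not np.all(np.isin(event, [0, 1])):
        raise SurvivalError("event indicators must be 0/1")
    return time, event


# --- Kaplan-Meier ----------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit estimate S(t)."""

    event_times: np.ndarray   # distinct times with >= 1 event, ascending
    survival: np.ndarray      # S(t) just after each event time
    n: int
    n_events: int
    median: Optional[float]

    def evaluate(self, t) -> np.ndarray:
        """S(t) for scalar or vector t (S(0) = 1)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx]


def km_curve(time, event) -> KaplanMeierCurve:
    """Kaplan-Meier estimator with median survival.

    The median is the first observed time at which S(t) <= 0.5, or None if
    the curve never reaches 0.5.
    """
    time, event = _validate_times(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    n = t.size
    ev_times, surv = [], []
    s = 1.0
    for gi, start in enumerate(uniq):
        stop = uniq[gi + 1] if gi + 1 < uniq.size else n
        d = int(e[start:stop].sum())
        if d == 0:
            continue
        at_risk = n - start
        s *= 1.0 - d / at_risk
        ev_times.append(t[start])
        surv.append(s)
    ev_times = np.asarray(ev_times)
    surv = np.asarray(surv)
    below = np.flatnonzero(surv <= 0.5)
    median = float(ev_times[below[0]]) if below.size else None
    return KaplanMeierCurve(event_times=ev_times, survival=surv,
                            n=n, n_events=int(event.sum()), median=median)


# --- log-rank --------------------------------------------------------------

@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed_minus_expected: float  # for the second (lexicographically larger) group
    variance: float
    n: int
    n_events: int


def logrank(time, event, group) -> LogRankResult:
    """Two-group log-rank test.

    Observed-minus-expected events with hypergeometric variance summed over
    distinct event times; chi-square with 1 df. Invariant to relabeling the
    groups.
    """
    time, event = _validate_times(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise SurvivalError(f"log-rank needs exactly two groups, got {labels.size}")
    if event.sum() == 0:
        raise UntestableError("all observations censored: log-rank undefined")
    g = (group == labels[1]).astype(int)

    order = np.argsort(time, kind="stable")
    t, e, gg = time[order], event[order], g[order]
    uniq = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    n = t.size
    # suffix count of group-1 members at risk
    g_suffix = np.cumsum(gg[::-1])[::-1]
    U = 0.0
    V = 0.0
    for gi, start in enumerate(uniq):
        stop = uniq[gi + 1] if gi + 1 < uniq.size else n
        d = int(e[start:stop].sum())
        if d == 0:
            continue
        at_risk = n - start
        n1 = int(g_suffix[start])
        d1 = int((e[start:stop] * gg[start:stop]).sum())
        p1 = n1 / at_risk
        U += d1 - d * p1
        if at_risk > 1:
            V += d * p1 * (1.0 - p1) * (at_risk - d) / (at_risk - 1)
    chi = (U * U / V) if V > 0 else 0.0
    p = float(chi2_dist.sf(chi, 1)) if V > 0 else 1.0
    return LogRankResult(chi_square=float(chi), p_value=p,
                         observed_minus_expected=float(U), variance=float(V),
                         n=n, n_events=int(event.sum()))


# --- maximally selected rank statistic -------------------------------------

@dataclass
class CutpointResult:
    variable: Optional[str]
    cutpoint: float
    standardized_statistic: float  # signed z for the high (> cutpoint) group
    n_low: int
    n_high: int
    minprop: float


def max_sel_cutpoint(time, event, covariate, minprop: float = 0.1,
                     variable: Optional[str] = None) -> CutpointResult:
    """Optimal dichotomization by the maximally selected log-rank statistic.

    Every distinct observed covariate value c for which both groups
    {x <= c} and {x > c} contain at least ceil(minprop * n) subjects is a
    candidate; the standardized log-rank (score) statistic of high vs low
    is computed at each, and the c with the largest absolute statistic is
    returned (ties broken by the smallest c).
    """
    time, event = _validate_times(time, event)
    x = np.asarray(covariate, dtype=float)
    if x.shape != time.shape:
        raise SurvivalError("covariate length mismatch")
    if not np.all(np.isfinite(x)):
        raise SurvivalError("covariate values must be finite")
    values = np.unique(x)
    if values.size < 2:
        raise NoCutpointError("constant covariate: no cutpoint exists")
    if event.sum() == 0:
        raise UntestableError("all observations censored")
    n = x.size
    k = math.ceil(minprop * n)
    sorted_x = np.sort(x)
    n_low_per = np.searchsorted(sorted_x, values, side="right")
    admissible = (n_low_per >= k) & ((n - n_low_per) >= k)
    cands = values[admissible]
    if cands.size == 0:
        raise NoCutpointError(
            f"no cutpoint leaves >= {k} subjects on each side (minprop={minprop})"
        )

    order = np.argsort(time, kind="stable")
    t, e, xs = time[order], event[order], x[order]
    uniq = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    # high-group indicator per candidate: (n_cand, n)
    high = xs[None, :] > cands[:, None]
    high_suffix = np.cumsum(high[:, ::-1], axis=1)[:, ::-1]
    U = np.zeros(cands.size)
    V = np.zeros(cands.size)
    for gi, start in enumerate(uniq):
        stop = uniq[gi + 1] if gi + 1 < uniq.size else n
        ev_block = e[start:stop]
        d = int(ev_block.sum())
        if d == 0:
            continue
        at_risk = n - start
        n1 = high_suffix[:, start]
        d1 = high[:, start:stop] @ ev_block
        p1 = n1 / at_risk
        U += d1 - d * p1
        if at_risk > 1:
            V += d * p1 * (1.0 - p1) * (at_risk - d) / (at_risk - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(V > 0, U / np.sqrt(V), np.nan)
    absz = np.abs(z)
    if not np.any(np.isfinite(absz)):
        raise NoCutpointError("log-rank variance is zero at every admissible cutpoint")
    absz = np.where(np.isfinite(absz), absz, -np.inf)
    best = int(np.argmax(absz))  # first max -> smallest cutpoint on ties
    c = float(cands[best])
    n_high = int((x > c).sum())
    return CutpointResult(variable=variable, cutpoint=c,
                          standardized_statistic=float(z[best]),
                          n_low=n - n_high, n_high=n_high, minprop=minprop)


# --- Cox proportional hazards ----------------------------------------------

@dataclass
class CoxResult:
    variable: Optional[str]
    log_hazard: float
    standard_error: float
    hazard_ratio: float
    ci95: Tuple[float, float]
    p_value: float
    ties_method: str
    n: int
    n_events: int
    score_chi_square: float  # score test at beta = 0
    log_likelihood: float
    iterations: int


def _cox_quantities(t, e, x, beta: float, uniq, ties: str):
    """Log partial likelihood, score and information at beta (sorted input)."""
    n = t.size
    eta = beta * x
    w = np.exp(eta)
    wx = w * x
    wx2 = wx * x
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1])[::-1]
    S2 = np.cumsum(wx2[::-1])[::-1]
    ll = 0.0
    U = 0.0
    I = 0.0
    for gi, start in enumerate(uniq):
        stop = uniq[gi + 1] if gi + 1 < uniq.size else n
        ev = e[start:stop].astype(bool)
        d = int(ev.sum())
        if d == 0:
            continue
        xD = x[start:stop][ev]
        wD = w[start:stop][ev]
        s0r, s1r, s2r = S0[start], S1[start], S2[start]
        ll += beta * xD.sum()
        if ties == "breslow" or d == 1:
            phi0 = np.full(d, s0r)
            phi1 = np.full(d, s1r)
            phi2 = np.full(d, s2r)
        else:
            frac = np.arange(d) / d
            phi0 = s0r - frac * wD.sum()
            phi1 = s1r - frac * (wD * xD).sum()
            phi2 = s2r - frac * (wD * xD * xD).sum()
        ll -= np.log(phi0).sum()
        r1 = phi1 / phi0
        U += xD.sum() - r1.sum()
        I += (phi2 / phi0 - r1 * r1).sum()
    return ll, U, I


def cox_univariate(time, event, covariate, ties: str = "efron",
                   variable: Optional[str] = None, tol: float = 1e-9,
                   max_iter: int = 50) -> CoxResult:
    """Univariate Cox regression by Newton-Raphson on the partial likelihood.

    Efron (default) or Breslow handling of tied event times; standard error
    from the observed information; Wald 95% CI and p-value. The score test
    at beta=0 is also reported (it equals the log-rank chi-square for a
    binary covariate on tie-free data).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    time, event = _validate_times(time, event)
    x = np.asarray(covariate, dtype=float)
    if x.shape != time.shape:
        raise SurvivalError("covariate length mismatch")
    if event.sum() == 0:
        raise UntestableError("no events: partial likelihood is flat")
    if np.ptp(x) == 0:
        raise SingularError("constant covariate")

    order = np.argsort(time, kind="stable")
    t, e, xs = time[order], event[order], x[order]
    uniq = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])

    ll0, U0, I0 = _cox_quantities(t, e, xs, 0.0, uniq, ties)
    if I0 <= 0:
        raise SingularError("covariate constant within every risk set")
    score_chi = U0 * U0 / I0

    beta = 0.0
    ll, U, I = ll0, U0, I0
    it = 0
    for it in range(1, max_iter + 1):
        if I <= 0:
            # information collapses when exp(beta*x) saturates: separation
            raise ConvergenceError(
                "monotone partial likelihood (information collapsed)",
                direction=int(np.sign(beta)) or int(np.sign(U)))
        step = U / I
        step = float(np.clip(step, -5.0, 5.0))
        new_beta = beta + step
        new_ll, new_U, new_I = _cox_quantities(t, e, xs, new_beta, uniq, ties)
        # step-halving if the likelihood worsens
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_U, new_I = _cox_quantities(t, e, xs, new_beta, uniq, ties)
            halvings += 1
        beta, ll, U, I = new_beta, new_ll, new_U, new_I
        if abs(beta) > 50:
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation); "
                f"estimate diverges toward {'+inf' if beta > 0 else '-inf'}",
                direction=int(np.sign(beta)),
            )
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations",
                               direction=int(np.sign(beta)))
    if I <= 0:
        raise SingularError("non-positive observed information at the optimum")
    se = 1.0 / math.sqrt(I)
    zcrit = norm.ppf(0.975)
    zstat = beta / se
    p = 2.0 * float(norm.sf(abs(zstat)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return CoxResult(
        variable=variable, log_hazard=float(beta), standard_error=float(se),
        hazard_ratio=float(math.exp(beta)),
        ci95=(float(math.exp(beta - zcrit * se)), float(math.exp(beta + zcrit * se))),
        p_value=p, ties_method=ties, n=int(t.size), n_events=int(e.sum()),
        score_chi_square=float(score_chi), log_likelihood=float(ll), iterations=it,
    )


# --- survival screen -------------------------------------------------------

SCREEN_COLUMNS = ["endpoint", "variable", "compartment", "column", "cutpoint",
                  "n_low", "n_high", "hr", "ci_low", "ci_high", "p", "flag", "error"]


def survival_screen(table: pd.DataFrame, variables: Sequence[str],
                    compartments: Sequence[str] = ("tumoral", "stromal", "total"),
                    endpoints: Sequence[str] = ("os", "pfs"),
                    minprop: float = 0.1, ties: str = "efron",
                    alpha: float = 0.05, mode: str = "cutpoint") -> pd.DataFrame:
    """Optimal-cutpoint univariate Cox screen over variables x compartments.

    For each endpoint (columns ``{e}_months`` / ``{e}_event``) and each
    density column ``{variable}_{compartment}_density``: dichotomize at the
    maximally selected cutpoint (high = value > cutpoint) and report the
    Cox hazard ratio of high vs low with 95% CI and unadjusted p; rows with
    a missing covariate are dropped for that combination only. mode
    "continuous" fits the per-unit Cox model on the raw covariate instead.
    Per-combination failures are recorded in the ``error`` column and the
    screen continues.
    """
    rows: List[dict] = []
    for endpoint in endpoints:
        tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
        for var in variables:
            for comp in compartments:
                col = f"{var}_{comp}_density"
                row = {"endpoint": endpoint, "variable": var, "compartment": comp,
                       "column": col, "cutpoint": np.nan, "n_low": np.nan,
                       "n_high": np.nan, "hr": np.nan, "ci_low": np.nan,
                       "ci_high": np.nan, "p": np.nan, "flag": False, "error": ""}
                try:
                    if col not in table.columns:
                        raise SurvivalError(f"missing column {col}")
                    sub = table[[tcol, ecol, col]].dropna()
                    t = sub[tcol].to_numpy(float)
                    e = sub[ecol].to_numpy(int)
                    x = sub[col].to_numpy(float)
                    if mode == "cutpoint":
                        cp = max_sel_cutpoint(t, e, x, minprop=minprop, variable=col)
                        high = (x > cp.cutpoint).astype(float)
                        cox = cox_univariate(t, e, high, ties=ties, variable=col)
                        row.update(cutpoint=cp.cutpoint, n_low=cp.n_low, n_high=cp.n_high)
                    elif mode == "continuous":
                        cox = cox_univariate(t, e, x, ties=ties, variable=col)
                        row.update(n_low=np.nan, n_high=np.nan)
                    else:
                        raise ValueError(f"unknown screen mode {mode!r}")
                    row.update(hr=cox.hazard_ratio, ci_low=cox.ci95[0],
                               ci_high=cox.ci95[1], p=cox.p_value,
                               flag=bool(cox.p_value < alpha))
                except (SurvivalError, ValueError) as exc:
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)
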