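"""Kaplan–Meier estimation, log-rank testing and univariate Cox regression.

These three statistics drive every survival readout in the pipeline: the
per-regulator prognosis screens, the prognostic filter on cluster DEGs, and
the cluster / score-group / TMB survival comparisons.

* Kaplan–Meier: the product-limit estimator S(t) = Π_{t_i ≤ t} (1 − d_i/n_i).
* Log-rank: the Mantel–Haenszel statistic — observed-minus-expected deaths
  per group accumulated over event times, with the hypergeometric covariance,
  chi-square on g − 1 df.
* Cox: Newton–Raphson maximisation of the Efron-tie partial likelihood with
  step-halving, SE from the inverse observed information, convergence at
  |Δβ| < 1e-8 (Breslow ties available for cross-checks). A constant
  covariate short-circuits to β = 0 with p = 1; a monotone likelihood
  (perfect separation) is flagged and β capped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

_BETA_CAP = 50.0


@dataclass
class SurvCurve:
    """Product-limit curve on the unique event-time grid."""

    time: np.ndarray            # unique event times, ascending
    surv: np.ndarray            # S(t) just after each event time
    at_risk: np.ndarray         # n_i at each event time
    n_events: np.ndarray        # d_i at each event time
    censor_times: np.ndarray    # times of censored observations

    def at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CoxResult:
    covariate: str
    beta: float
    hr: float
    se: float
    z: float
    p: float
    converged: bool
    iterations: int
    flag: str = ""
    loglik_trace: list[float] = field(default_factory=list)


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival input")
    if not (times > 0).all():
        raise ValueError("all survival times must be > 0")
    if not np.isin(events, (0.0, 1.0)).all():
        raise ValueError("events must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events) -> SurvCurve:
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    event_times = np.unique(t[e == 1])
    n = len(t)
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=float)
    d = np.array([((t == u) & (e == 1)).sum() for u in event_times], dtype=float)
    if len(event_times):
        surv = np.cumprod(1.0 - d / at_risk)
    else:
        surv = np.array([])
    return SurvCurve(event_times, surv, at_risk.astype(int), d.astype(int), np.sort(t[e == 0]))


def logrank_test(times, events, groups) -> LogrankResult:
    """Mantel–Haenszel log-rank test across ≥ 2 groups."""
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    if len(groups) != len(times):
        raise ValueError("groups length must match times")
    levels = np.unique(groups)
    g = len(levels)
    if g < 2:
        raise ValueError("log-rank test needs ≥ 2 groups")
    if events.sum() == 0:
        warnings.warn("no events; log-rank p set to 1")
        return LogrankResult(0.0, g - 1, 1.0)

    gidx = np.searchsorted(levels, groups)
    event_times = np.unique(times[events == 1])
    O = np.zeros(g)
    E = np.zeros(g)
    V = np.zeros((g, g))
    for u in event_times:
        risk = times >= u
        n_t = risk.sum()
        n_j = np.bincount(gidx[risk], minlength=g).astype(float)
        dead = (times == u) & (events == 1)
        d_t = dead.sum()
        d_j = np.bincount(gidx[dead], minlength=g).astype(float)
        O += d_j
        E += d_t * n_j / n_t
        if n_t > 1:
            # hypergeometric covariance: V_jj = c n_j (n − n_j)/n², V_jl = −c n_j n_l /n²
            c = d_t * (n_t - d_t) / (n_t - 1.0)
            V += c * (np.diag(n_j * n_t) - np.outer(n_j, n_j)) / n_t**2
    diff = (O - E)[:-1]
    Vr = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vr, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vr) @ diff)
    df = g - 1
    return LogrankResult(chi2, df, float(stats.chi2.sf(chi2, df)))


class CoxData:
    """Preprocessed (times, events) structure reused across many covariates.

    Caches the stable time ordering, the risk-set start index of every unique
    event time and the death positions, so that fitting hundreds of genes
    against the same survival outcome avoids re-sorting.
    """

    def __init__(self, times, events):
        times, events = _check_surv(times, events)
        if events.sum() < 1:
            raise ValueError("Cox regression needs ≥ 1 event")
        self.order = np.argsort(times, kind="stable")
        self.t = times[self.order]
        self.e = events[self.order]
        self.n = len(self.t)
        event_times = np.unique(self.t[self.e == 1])
        self.risk_start = np.searchsorted(self.t, event_times, side="left")
        self.death_groups = [np.flatnonzero((self.t == u) & (self.e == 1)) for u in event_times]

    def loglik(self, beta: float, x_sorted: np.ndarray, ties: str = "efron") -> tuple[float, float, float]:
        """(log partial likelihood, gradient, hessian) at beta."""
        w = np.exp(beta * x_sorted)
        wx = w * x_sorted
        wxx = wx * x_sorted
        # suffix sums: risk set at event time u = everyone with t >= u
        s0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        s1 = np.concatenate([np.cumsum(wx[::-1])[::-1], [0.0]])
        s2 = np.concatenate([np.cumsum(wxx[::-1])[::-1], [0.0]])
        ll = 0.0
        grad = 0.0
        hess = 0.0
        for start, deaths in zip(self.risk_start, self.death_groups):
            r0, r1, r2 = s0[start], s1[start], s2[start]
            xd = x_sorted[deaths]
            d = len(deaths)
            ll += beta * xd.sum()
            grad += xd.sum()
            if ties == "efron" and d > 1:
                wd = w[deaths]
                t0, t1v, t2v = wd.sum(), (wd * xd).sum(), (wd * xd * xd).sum()
                for l in range(d):
                    f = l / d
                    den = r0 - f * t0
                    e1 = (r1 - f * t1v) / den
                    e2 = (r2 - f * t2v) / den
                    ll -= np.log(den)
                    grad -= e1
                    hess -= e2 - e1 * e1
            else:  # breslow, or no ties
                e1 = r1 / r0
                e2 = r2 / r0
                ll -= d * np.log(r0)
                grad -= d * e1
                hess -= d * (e2 - e1 * e1)
        return ll, grad, hess


def cox_univariate(x, times, events, name: str = "x", ties: str = "efron",
                   tol: float = 1e-8, max_iter: int = 50,
                   data: CoxData | None = None) -> CoxResult:
    """Univariate Cox proportional-hazards fit by safeguarded Newton–Raphson."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    if data is None:
        data = CoxData(times, events)
    if len(x) != data.n:
        raise ValueError("covariate length must match times")
    if np.ptp(x) == 0:
        return CoxResult(name, 0.0, 1.0, np.inf, 0.0, 1.0, True, 0, flag="constant")

    xs = x[data.order]
    beta = 0.0
    ll, grad, hess = data.loglik(beta, xs, ties)
    trace = [ll]
    converged = False
    flag = ""
    it = 0
    for it in range(1, max_iter + 1):
        info = -hess
        if info <= 0:
            flag = "singular_information"
            break
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_hess = data.loglik(new_beta, xs, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = data.loglik(new_beta, xs, ties)
            halvings += 1
        delta = new_beta - beta
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        trace.append(ll)
        if abs(beta) > _BETA_CAP:
            beta = np.sign(beta) * _BETA_CAP
            ll, grad, hess = data.loglik(beta, xs, ties)
            flag = "separation"
            break
        if abs(delta) < tol:
            converged = True
            break

    info = -hess
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(name, float(beta), float(np.exp(beta)), se, float(z), p,
                     converged, it, flag=flag, loglik_trace=trace)


def prognostic_filter(x: ExpressionMatrix, clinical: pd.DataFrame, genes,
                      p_threshold: float = 0.05,
                      ties: str = "efron") -> tuple[list[str], pd.DataFrame]:
    """Genes whose univariate Cox raw p < ``p_threshold`` on overall survival.

    Returns the passing genes (matrix order) and the full per-gene Cox table.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    genes = [g for g in genes if g in set(x.gene_ids)]
    if not genes:
        raise ValueError("empty candidate gene list after matching the matrix")
    clin = clinical.set_index("sample_id").loc[x.sample_ids]
    data = CoxData(clin["os_time"].to_numpy(), clin["os_event"].to_numpy())
    rows = []
    for g in genes:
        res = cox_univariate(x.values.loc[g].to_numpy(), clin["os_time"].to_numpy(),
                             clin["os_event"].to_numpy(), name=g, ties=ties, data=data)
        rows.append((g, res.beta, res.hr, res.se, res.z, res.p, res.converged, res.flag))
    table = pd.DataFrame(rows, columns=["gene", "beta", "hr", "se", "z", "p",
                                        "converged", "flag"]).set_index("gene")
    passing = [g for g in genes if table.loc[g, "p"] < p_threshold]
    return passing, table
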