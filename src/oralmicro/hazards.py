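"""Proportional-hazards engines: Cox partial likelihood and the Fine-Gray
subdistribution-hazard model for competing risks.

Both models share one Newton-Raphson maximizer of the weighted Cox partial
likelihood in counting-process form (entry, exit] with case weights and the
Efron approximation for tied event times. The Fine-Gray model is reduced to
that weighted likelihood by the usual risk-set expansion: a subject whose
competing event occurs at T stays in the risk set afterwards with
inverse-probability-of-censoring weights w(t) = G(t-) / G(T-), where G is
the Kaplan-Meier estimate of the censoring distribution. With no competing
events every weight is 1 and the Fine-Gray fit coincides with the Cox fit.

The public surface is a small Model/Results pair: ``CoxModel(df, ...)`` /
``FineGrayModel(df, ...)`` with ``.fit()`` returning a ``HazardResults``
carrying coefficients, Wald confidence intervals and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError

__all__ = ["HazardFit", "HazardResults", "CoxModel", "FineGrayModel"]

_SEPARATION_BOUND = 20.0  # |log HR| beyond this signals monotone likelihood


@dataclass
class HazardFit:
    """One covariate's estimate from a proportional-hazards fit."""

    covariate: str
    coef: float
    hr: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    model: str
    n_used: int
    excluded: list[str] = field(default_factory=list)
    converged: bool = True
    separation: bool = False
    note: str = ""


@dataclass
class HazardResults:
    """Joint fit results with per-covariate Wald inference."""

    model: str
    covariates: list[str]
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n_used: int
    excluded: list[str] = field(default_factory=list)
    converged: bool = True
    separation: bool = False

    def fit_for(self, covariate: str, alpha: float = 0.05) -> HazardFit:
        j = self.covariates.index(covariate)
        b = float(self.params[j])
        se = float(np.sqrt(self.cov[j, j])) if np.isfinite(self.cov[j, j]) else np.inf
        z = stats.norm.ppf(1 - alpha / 2)
        if se == 0 or not np.isfinite(se):
            p = 1.0
            lo, hi = (np.nan, np.nan) if not np.isfinite(se) else (b, b)
        else:
            p = float(2 * stats.norm.sf(abs(b) / se))
            lo, hi = np.clip([b - z * se, b + z * se], -700, 700)
        return HazardFit(
            covariate=covariate,
            coef=b,
            hr=float(np.exp(b)),
            se=se,
            ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)),
            p=p,
            model=self.model,
            n_used=self.n_used,
            excluded=list(self.excluded),
            converged=self.converged,
            separation=self.separation,
        )

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for c in self.covariates:
            f = self.fit_for(c, alpha=alpha)
            rows.append(
                {
                    "covariate": c,
                    "coef": f.coef,
                    "HR": f.hr,
                    "se": f.se,
                    f"HR {100*(1-alpha):g}% CI low": f.ci_low,
                    f"HR {100*(1-alpha):g}% CI high": f.ci_high,
                    "p": f.p,
                    "model": self.model,
                    "n": self.n_used,
                }
            )
        return pd.DataFrame(rows)


def _efron_loglik_grad_hess(beta, start, stop, event, X, w):
    """Weighted Cox partial log-likelihood with Efron ties; returns
    (loglik, gradient, observed information)."""
    p = X.shape[1]
    eta = X @ beta
    r = w * np.exp(eta)
    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(stop[event == 1]):
        dead = (stop == t) & (event == 1)
        risk = (start < t) & (t <= stop)
        m = int(dead.sum())
        wbar = w[dead].sum() / m
        s = r[risk].sum()
        u = r[risk] @ X[risk]
        M = (r[risk][:, None] * X[risk]).T @ X[risk]
        s_d = r[dead].sum()
        u_d = r[dead] @ X[dead]
        M_d = (r[dead][:, None] * X[dead]).T @ X[dead]
        loglik += float(w[dead] @ eta[dead])
        grad += w[dead] @ X[dead]
        for ell in range(m):
            f = ell / m
            phi = s - f * s_d
            U = u - f * u_d
            Mm = M - f * M_d
            loglik -= wbar * np.log(phi)
            grad -= wbar * U / phi
            info += wbar * (Mm / phi - np.outer(U, U) / phi**2)
    return loglik, grad, info


def _newton_cox(start, stop, event, X, w, tol=1e-10, max_iter=60):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, g, info = _efron_loglik_grad_hess(beta, start, stop, event, X, w)
    converged = False
    separation = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step halving to keep the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, info_new = _efron_loglik_grad_hess(
                cand, start, stop, event, X, w
            )
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        beta, ll, g, info = cand, ll_new, g_new, info_new
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            separation = True
            beta = np.clip(beta, -_SEPARATION_BOUND, _SEPARATION_BOUND)
            break
        if np.max(np.abs(factor * step)) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.inf)
    return beta, cov, ll, converged, separation


class _BaseHazardModel:
    """Shared fitting plumbing for Cox and Fine-Gray."""

    model_name = "Cox"

    def __init__(self, data: pd.DataFrame, covariates: list[str],
                 duration_col: str = "time", event_col: str = "event"):
        if not covariates:
            raise ValidationError("at least one covariate required")
        for c in [duration_col, event_col, *covariates]:
            if c not in data.columns:
                raise ValidationError(f"column {c!r} missing from data")
        self.data = data.reset_index(drop=True).copy()
        self.covariates = list(covariates)
        self.duration_col = duration_col
        self.event_col = event_col
        self.excluded: list[str] = []
        if (self.data[duration_col] <= 0).any():
            raise ValidationError("durations must be positive")

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.covariates].to_numpy(dtype=float)
        return X

    def _counting_process(self):
        raise NotImplementedError

    def fit(self) -> HazardResults:
        start, stop, event, X, w = self._counting_process()
        if event.sum() == 0:
            n = X.shape[1]
            return HazardResults(
                model=self.model_name,
                covariates=self.covariates,
                params=np.zeros(n),
                cov=np.full((n, n), np.inf),
                loglik=0.0,
                n_used=self._n_subjects,
                excluded=self.excluded,
                converged=False,
                separation=False,
            )
        # zero-variance covariates carry no partial-likelihood information
        live = np.flatnonzero(X.std(axis=0) > 0)
        p = X.shape[1]
        params = np.zeros(p)
        cov = np.zeros((p, p))
        converged, separation = True, False
        ll = 0.0
        if live.size:
            b, c, ll, converged, separation = _newton_cox(
                start, stop, event, X[:, live], w
            )
            params[live] = b
            cov[np.ix_(live, live)] = c
        dead = [j for j in range(p) if j not in set(live)]
        for j in dead:
            cov[j, j] = np.inf
        return HazardResults(
            model=self.model_name,
            covariates=self.covariates,
            params=params,
            cov=cov,
            loglik=ll,
            n_used=self._n_subjects,
            excluded=self.excluded,
            converged=converged,
            separation=separation,
        )


class CoxModel(_BaseHazardModel):
    """Cox proportional-hazards model (Efron tie handling).

    ``event_col`` must be a 0/1 indicator: recode multi-cause event codes
    before fitting (any-event for overall survival, or cause-specific).
    """

    model_name = "Cox"

    def _counting_process(self):
        df = self.data
        self._n_subjects = len(df)
        time = df[self.duration_col].to_numpy(dtype=float)
        event = df[self.event_col].to_numpy()
        if not set(np.unique(event)) <= {0, 1}:
            raise ValidationError(
                "CoxModel needs a 0/1 event indicator; recode competing events first"
            )
        X = self._design(df)
        start = np.zeros_like(time)
        w = np.ones_like(time)
        return start, time, event.astype(int), X, w


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier of the censoring distribution (event==0 is the 'event').

    Returns a function G(t-) giving the left-continuous survival of the
    censoring time at t.
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    cens_sorted = (event[order] == 0).astype(int)
    uniq = np.unique(t_sorted)
    surv = []
    s = 1.0
    n = len(t_sorted)
    at_risk = n
    for t in uniq:
        here = t_sorted == t
        d = int(cens_sorted[here].sum())
        if at_risk > 0 and d > 0:
            s *= 1 - d / at_risk
        surv.append(s)
        at_risk -= int(here.sum())
    uniq = np.asarray(uniq)
    surv = np.asarray(surv)

    def g_left(t: float) -> float:
        idx = np.searchsorted(uniq, t, side="left") - 1  # strictly before t
        return 1.0 if idx < 0 else float(surv[idx])

    return g_left


class FineGrayModel(_BaseHazardModel):
    """Fine-Gray subdistribution-hazard regression.

    ``event_col`` uses the coding 0 = censored, ``event_of_interest`` = event
    modelled, any other positive code = competing event.
    """

    model_name = "Fine-Gray"

    def __init__(self, data, covariates, duration_col="time", event_col="event",
                 event_of_interest: int = 1):
        super().__init__(data, covariates, duration_col, event_col)
        self.event_of_interest = event_of_interest

    def _counting_process(self):
        df = self.data
        self._n_subjects = len(df)
        time = df[self.duration_col].to_numpy(dtype=float)
        code = df[self.event_col].to_numpy()
        X = self._design(df)
        eoi = self.event_of_interest
        g_left = _censoring_km(time, code)
        etimes = np.unique(time[code == eoi])
        starts, stops, events, weights, rows = [], [], [], [], []
        for i in range(len(df)):
            t_i, c_i = time[i], code[i]
            if c_i == eoi:
                starts.append(0.0); stops.append(t_i); events.append(1)
                weights.append(1.0); rows.append(i)
            elif c_i == 0:
                starts.append(0.0); stops.append(t_i); events.append(0)
                weights.append(1.0); rows.append(i)
            else:  # competing event: stays at risk with IPCW weights
                starts.append(0.0); stops.append(t_i); events.append(0)
                weights.append(1.0); rows.append(i)
                g_t = g_left(t_i)
                if g_t <= 0:
                    continue
                prev = t_i
                for t_k in etimes[etimes > t_i]:
                    w_k = g_left(t_k) / g_t
                    if w_k > 0:
                        starts.append(prev); stops.append(t_k); events.append(0)
                        weights.append(w_k); rows.append(i)
                    prev = t_k
        return (
            np.asarray(starts),
            np.asarray(stops),
            np.asarray(events, dtype=int),
            X[np.asarray(rows, dtype=int)],
            np.asarray(weights),
        )
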