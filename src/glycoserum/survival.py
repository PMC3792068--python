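"""Time-to-surgery analysis: Kaplan-Meier, log-rank, and Cox regression.

The prognostic workflow mirrors common clinical practice: a biomarker is
dichotomized at an empirical quantile (median by default), groups are
compared with the Kaplan-Meier product-limit estimator and the log-rank
test, and hazard ratios come from Cox proportional-hazards fits — first a
univariate screen (entry rule p < 0.1), then a multivariate model after
dropping one member of any covariate pair with |Pearson r| above a
collinearity threshold (the member with the larger univariate p).

The Cox fit maximizes the log partial likelihood by Newton-Raphson with
Breslow handling of tied event times (Efron available via ``ties=``),
stopping at gradient max-norm < 1e-8 or 100 iterations, with Wald
standard errors, 95% CIs exp(b +/- 1.96 se) and p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "km_estimate",
    "km_by_group",
    "logrank_test",
    "cox_fit",
    "CoxResult",
    "ConvergenceError",
    "univariate_screen",
    "multivariate_cox",
    "dichotomize",
    "diagnostic_accuracy",
]


class ConvergenceError(RuntimeError):
    """Cox Newton-Raphson failed (non-convergence or monotone likelihood)."""


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if np.any(time < 0):
        raise ValueError("negative survival times")
    if not np.isin(event, (0.0, 1.0)).all():
        raise ValueError("event flags must be 0 or 1")
    return time, event.astype(int)


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns one row per distinct observed time with columns time, n_risk,
    n_event, n_censored and survival (the step value just after that
    time); S(0) = 1 implicitly precedes the first row.
    """
    time, event = _check_surv(time, event)
    if len(time) == 0:
        raise ValueError("no subjects")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n_risk = len(time)
    for t in np.unique(time):
        at_t = time == t
        d = int(event[at_t].sum())
        c = int(at_t.sum() - d)
        if d > 0:
            s *= 1.0 - d / n_risk
        rows.append(
            {"time": float(t), "n_risk": n_risk, "n_event": d, "n_censored": c, "survival": s}
        )
        n_risk -= d + c
    return pd.DataFrame(rows)


def km_by_group(time, event, group) -> dict[str, pd.DataFrame]:
    """Per-group Kaplan-Meier curves keyed by group value."""
    time, event = _check_surv(time, event)
    group = np.asarray(group)
    out = {}
    for g in pd.unique(group):
        mask = group == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        out[str(g)] = km_estimate(time[mask], event[mask])
    return out


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, 1-df p-value)."""
    time, event = _check_surv(time, event)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups (got {list(levels)})")
    in1 = group == levels[0]
    if in1.sum() == 0 or in1.sum() == len(group):
        raise ValueError("one group is empty")
    if event.sum() == 0:
        raise ValueError("no events observed")
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(event[time == t].sum())
        d1 = int(event[(time == t) & in1].sum())
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        raise ValueError("log-rank variance is zero (no usable event times)")
    chi2 = obs_minus_exp**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


@dataclass
class CoxResult:
    """Cox proportional-hazards fit summary."""

    summary: pd.DataFrame  # per covariate: coef, se, hr, hr_low, hr_high, p
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    iterations: int
    dropped: tuple[str, ...] = ()

    def __getitem__(self, covariate: str) -> pd.Series:
        return self.summary.loc[covariate]


def _cox_loglik(beta, time, event, X, ties):
    """Log partial likelihood, gradient and information (Breslow/Efron)."""
    n, p = X.shape
    eta = X @ beta
    # clip to keep exp finite during aggressive Newton steps
    w = np.exp(np.clip(eta, -500, 500))
    order = np.argsort(-time, kind="stable")  # descending: cumsum = risk set
    t_s, e_s, X_s, w_s = time[order], event[order], X[order], w[order]
    wx_s = w_s[:, None] * X_s
    wxx_s = w_s[:, None, None] * (X_s[:, :, None] * X_s[:, None, :])
    S0 = np.cumsum(w_s)
    S1 = np.cumsum(wx_s, axis=0)
    S2 = np.cumsum(wxx_s, axis=0)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # risk set for this time = first j sorted entries (ties included)
        deaths = np.nonzero(e_s[i:j] == 1)[0] + i
        d = len(deaths)
        if d > 0:
            s1 = S1[j - 1]
            s0 = S0[j - 1]
            s2 = S2[j - 1]
            xsum = X_s[deaths].sum(axis=0)
            ll += float(eta[order][deaths].sum())
            if ties == "breslow":
                ll -= d * np.log(s0)
                grad += xsum - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
            elif ties == "efron":
                d0 = w_s[deaths].sum()
                d1 = wx_s[deaths].sum(axis=0)
                d2 = wxx_s[deaths].sum(axis=0)
                grad += xsum
                for l in range(d):
                    f = l / d
                    z0 = s0 - f * d0
                    z1 = s1 - f * d1
                    z2 = s2 - f * d2
                    ll -= np.log(z0)
                    grad -= z1 / z0
                    info += z2 / z0 - np.outer(z1, z1) / z0**2
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j
    return ll, grad, info


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``covariates`` is a samples x p DataFrame (binary or continuous).
    Raises :class:`ConvergenceError` on non-convergence or a monotone
    likelihood (perfect separation) rather than returning silent output.
    """
    time, event = _check_surv(time, event)
    X_df = pd.DataFrame(covariates)
    names = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] != len(time):
        raise ValueError("covariate matrix shape does not match survival data")
    if event.sum() < 1:
        raise ValueError("Cox model requires at least one event")
    const = [nm for nm, col in zip(names, X.T) if np.ptp(col) == 0]
    if const:
        raise ValueError(f"constant covariates cannot be fit: {const}")
    # center for numerical stability; coefficients are unaffected
    X = X - X.mean(axis=0)
    beta = np.zeros(X.shape[1])
    ll, grad, info = _cox_loglik(beta, time, event, X, ties)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iteration {it}") from exc
        # step-halving line search on the log partial likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _cox_loglik(cand, time, event, X, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            raise ConvergenceError(f"line search failed at iteration {it}")
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations (|grad|={np.max(np.abs(grad)):.2e})")
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    # a monotone partial likelihood drifts to huge |coef| with a flat
    # information matrix; both symptoms are flagged rather than reported
    if np.max(np.abs(beta)) > 50 or np.max(se) > 100:
        raise ConvergenceError(
            "monotone likelihood (perfect separation?): runaway coefficient or "
            "standard error"
        )
    z = beta / se
    p = 2 * sps.norm.sf(np.abs(z))
    zcrit = 1.959963984540054  # Wald 95%
    summary = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "hr_low": np.exp(beta - zcrit * se),
            "hr_high": np.exp(beta + zcrit * se),
            "z": z,
            "p": p,
        },
        index=pd.Index(names, name="covariate"),
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(ll),
        converged=converged,
        n=len(time),
        n_events=int(event.sum()),
        iterations=it,
    )


def univariate_screen(
    time, event, covariates: pd.DataFrame, entry_p: float = 0.1, ties: str = "breslow"
) -> tuple[pd.DataFrame, list[str]]:
    """Separate univariate Cox fit per covariate; select those with p < entry_p.

    Returns (table of all univariate fits in input order, selected names).
    """
    rows = []
    selected = []
    for name in covariates.columns:
        res = cox_fit(time, event, covariates[[name]], ties=ties)
        row = res.summary.loc[name]
        rows.append(row)
        if row["p"] < entry_p:
            selected.append(name)
    table = pd.DataFrame(rows)
    table.index = pd.Index(covariates.columns, name="covariate")
    return table, selected


def multivariate_cox(
    time,
    event,
    covariates: pd.DataFrame,
    collinearity_r: float = 0.7,
    ties: str = "breslow",
    univariate_p: pd.Series | None = None,
) -> CoxResult:
    """Joint Cox fit after collinearity pruning.

    For every covariate pair with |Pearson r| > ``collinearity_r`` the
    member with the larger univariate p-value is dropped (computed here if
    not supplied).  With a single remaining covariate the fit equals the
    univariate fit.
    """
    cov_df = pd.DataFrame(covariates)
    if cov_df.shape[1] < 1:
        raise ValueError("no covariates supplied")
    if univariate_p is None:
        table, _ = univariate_screen(time, event, cov_df, entry_p=np.inf, ties=ties)
        univariate_p = table["p"]
    corr = cov_df.astype(float).corr()
    dropped: list[str] = []
    names = list(cov_df.columns)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if a in dropped or b in dropped:
                continue
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > collinearity_r:
                loser = a if univariate_p[a] > univariate_p[b] else b
                dropped.append(loser)
                log.warning(
                    "dropping %s from multivariate model: |r|=%.3f with %s "
                    "and larger univariate p", loser, abs(r), a if loser == b else b,
                )
    kept = [n for n in names if n not in dropped]
    res = cox_fit(time, event, cov_df[kept], ties=ties)
    res.dropped = tuple(dropped)
    return res


def dichotomize(values, rule: str | float = "median") -> tuple[pd.Series, float]:
    """Split values at an empirical quantile into high (> cutoff) / low flags.

    ``rule`` is "median" or a quantile in (0, 1); the cutoff uses the
    linear-interpolation quantile definition, and values equal to the
    cutoff are low (strict >).  Returns (boolean high flags, cutoff).
    """
    s = pd.Series(values, dtype=float)
    if s.nunique() < 2:
        raise ValueError("cannot dichotomize: fewer than 2 distinct values")
    q = 0.5 if rule == "median" else float(rule)
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {rule!r}")
    cutoff = float(np.quantile(s.to_numpy(), q, method="linear"))
    high = s > cutoff
    high.name = f"{s.name or 'value'}_high"
    return high, cutoff


def diagnostic_accuracy(high_flags, event_flags) -> tuple[float, float]:
    """Sensitivity/specificity of a high/low marker flag for an ever-event.

    sensitivity = P(high | event); specificity = P(low | no event).  The
    event is "operation ever during follow-up"; censoring is ignored,
    which overstates certainty for short follow-up (caveat logged).  An
    undefined component (no events, or no non-events) is returned as NaN.
    """
    high = np.asarray(high_flags, dtype=bool)
    event = np.asarray(event_flags, dtype=bool)
    if high.shape != event.shape:
        raise ValueError("flag vectors must have the same length")
    log.debug("diagnostic accuracy treats censored subjects as event-free")
    n_event = int(event.sum())
    n_noevent = int((~event).sum())
    if n_event == 0:
        log.warning("no events: sensitivity undefined")
        sens = float("nan")
    else:
        sens = float(high[event].mean())
    if n_noevent == 0:
        log.warning("no non-events: specificity undefined")
        spec = float("nan")
    else:
        spec = float((~high[~event]).mean())
    return sens, spec
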