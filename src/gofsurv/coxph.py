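"""Weighted Cox proportional-hazards estimation.

Implements the inverse-probability-weighted (IPW) Cox partial likelihood
used to analyse outcome-dependent two-phase samples: each subject carries a
weight ``w_i = 1 / P(selected)`` and enters both the event terms and the
risk-set sums of the partial likelihood.  Estimation is Newton-Raphson with
step-halving; inference offers the model-based covariance (inverse observed
information) and the robust sandwich ``A^{-1} B A^{-1}`` where ``B`` stacks
per-subject weighted score residuals.  The sandwich treats weights as fixed
and known, which is appropriate when selection probabilities come from an
external model rather than being estimated from the analysed sample.

Ties are handled by the Breslow approximation by default (Efron optional);
simulated continuous event times make ties measure-zero, but tabular
round-trips can introduce them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class CoxEstimationError(ValueError):
    """Raised for degenerate design matrices or singular information."""


@dataclass
class SurvivalData:
    """Right-censored survival data with sampling weights.

    Parameters
    ----------
    time : (n,) array of nonnegative follow-up times T = min(T*, C).
    event : (n,) 0/1 array, 1 for observed events.
    covariates : (n, p) design matrix.
    weights : (n,) positive sampling weights; all ones for a full-cohort
        analysis.
    names : covariate column names (optional, for reporting).
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    weights: np.ndarray | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.time.shape[0]:
            self.covariates = self.covariates.T
        n = self.time.shape[0]
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.names is None:
            self.names = [f"x{j}" for j in range(self.covariates.shape[1])]
        if self.event.shape != (n,) or self.weights.shape != (n,):
            raise CoxEstimationError("time, event and weights must have equal length")
        if not set(np.unique(self.event)) <= {0.0, 1.0}:
            raise CoxEstimationError("event must be binary 0/1")
        if np.any(self.time < 0):
            raise CoxEstimationError("negative follow-up time")
        if not np.all(np.isfinite(self.covariates)):
            raise CoxEstimationError("non-finite covariate values")
        if np.any(self.weights <= 0) or not np.all(np.isfinite(self.weights)):
            raise CoxEstimationError("weights must be positive and finite")
        if self.event.sum() < 1:
            raise CoxEstimationError("no events in data")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        duration_col: str = "time",
        event_col: str = "event",
        weight_col: str | None = None,
        covariate_cols: list[str] | None = None,
    ) -> "SurvivalData":
        if covariate_cols is None:
            drop = {duration_col, event_col, weight_col, "subject_id"}
            covariate_cols = [c for c in df.columns if c not in drop]
        w = df[weight_col].to_numpy() if weight_col else None
        return cls(
            time=df[duration_col].to_numpy(),
            event=df[event_col].to_numpy(),
            covariates=df[covariate_cols].to_numpy(),
            weights=w,
            names=list(covariate_cols),
        )


@dataclass
class CoxFit:
    """Result of a weighted Cox fit."""

    coef: np.ndarray
    vcov_model: np.ndarray
    vcov_robust: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int
    names: list[str] = field(default_factory=list)
    n: int = 0
    n_events: int = 0

    @property
    def se_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_model))

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_robust))

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se_robust
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.coef,
                "se_model": self.se_model,
                "se_robust": self.se_robust,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


class _Workspace:
    """Sorted views and tie-group indexing shared across Newton iterations."""

    def __init__(self, data: SurvivalData):
        order = np.argsort(data.time, kind="stable")
        self.t = data.time[order]
        self.d = data.event[order]
        self.X = data.covariates[order]
        self.w = data.weights[order]
        self.order = order
        # tie groups over observed times (any subject defines a potential
        # risk-set boundary; events within a group share the denominator)
        self.ut, self.first, self.inv = np.unique(
            self.t, return_index=True, return_inverse=True
        )
        self.is_event = self.d == 1
        # weighted number of events per unique time
        self.dw = np.bincount(self.inv, weights=self.w * self.d, minlength=self.ut.size)
        self.has_event = self.dw > 0
        # covariate centering improves exp() conditioning; the maximizer is
        # invariant to column shifts
        self.xmean = np.average(self.X, axis=0, weights=self.w)
        self.Xc = self.X - self.xmean


def _suffix_sum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _breslow_quantities(ws: _Workspace, coef: np.ndarray):
    """Log-likelihood, score and information under Breslow ties.

    All quantities use the standard weighted form: weights appear both in
    the risk-set sums and multiplying each event's contribution.  When every
    event carries unit weight (the all-cases-selected design) this maximizer
    coincides with the design-form partial likelihood where the weight sits
    only inside the ratio; see :func:`weighted_log_partial_likelihood`.
    """
    Xc, w, d = ws.Xc, ws.w, ws.d
    lp = Xc @ coef
    rexp = w * np.exp(lp)
    s0 = _suffix_sum(rexp)[ws.first]                       # (U,)
    s1 = _suffix_sum(rexp[:, None] * Xc)[ws.first]         # (U, p)
    xouter = Xc[:, :, None] * Xc[:, None, :]
    s2 = _suffix_sum(rexp[:, None, None] * xouter)[ws.first]   # (U, p, p)
    xbar = s1 / s0[:, None]

    ev = ws.is_event
    gi = ws.inv[ev]
    loglik = float(np.sum(w[ev] * (lp[ev] - np.log(s0[gi]))))
    score = (w[ev, None] * (Xc[ev] - xbar[gi])).sum(axis=0)
    he = ws.has_event
    v = s2[he] / s0[he, None, None] - xbar[he, :, None] * xbar[he, None, :]
    info = np.einsum("u,upq->pq", ws.dw[he], v)
    return loglik, score, info, lp, rexp, s0, xbar


def _efron_quantities(ws: _Workspace, coef: np.ndarray):
    """Efron tie correction; reduces to Breslow when no tied events."""
    loglik, score, info, lp, rexp, s0, xbar = _breslow_quantities(ws, coef)
    Xc, w = ws.Xc, ws.w
    # adjust groups with >= 2 events
    counts = np.bincount(ws.inv, weights=ws.d.astype(float), minlength=ws.ut.size)
    for u in np.nonzero(counts >= 2)[0]:
        members = np.nonzero((ws.inv == u) & ws.is_event)[0]
        dd = members.size
        re_e = rexp[members]
        s0e, s1e = re_e.sum(), (re_e[:, None] * Xc[members]).sum(axis=0)
        s2e = np.einsum("i,ip,iq->pq", re_e, Xc[members], Xc[members])
        s1u = xbar[u] * s0[u]
        s2u = None  # recompute via breslow pieces below
        # remove the Breslow contribution of this group
        wsum = w[members].sum()
        loglik += wsum * np.log(s0[u])
        score += wsum * xbar[u]
        # s2 at this group
        at_risk = ws.t >= ws.ut[u]
        s2u = np.einsum("i,ip,iq->pq", rexp[at_risk], Xc[at_risk], Xc[at_risk])
        info -= ws.dw[u] * (s2u / s0[u] - np.outer(xbar[u], xbar[u]))
        for ell in range(dd):
            f = ell / dd
            s0l = s0[u] - f * s0e
            s1l = s1u - f * s1e
            s2l = s2u - f * s2e
            loglik -= (wsum / dd) * np.log(s0l)
            score -= (wsum / dd) * s1l / s0l
            m = s1l / s0l
            info += (ws.dw[u] / dd) * (s2l / s0l - np.outer(m, m))
    return loglik, score, info, lp, rexp, s0, xbar


def weighted_log_partial_likelihood(
    coef: np.ndarray, data: SurvivalData
) -> float:
    """Design-form weighted log partial likelihood.

    Literal transcription of the IPW partial likelihood

    ``sum_{i: event} [ log w_i + coef'x_i - log sum_{j: T_j >= T_i} w_j exp(coef'x_j) ]``

    where the weight of the event subject enters once inside the ratio and
    risk-set sums are weighted.  Because all cases carry weight 1 in the
    all-cases two-phase designs, its maximizer agrees there with the
    standard weighted form used by :func:`fit_coxph` (weights multiplying
    each event term), which matches ``coxph(..., weights=)``.
    """
    coef = np.asarray(coef, dtype=float)
    ws = _Workspace(data)
    lp = ws.X @ coef
    rexp = ws.w * np.exp(lp)
    s0 = _suffix_sum(rexp)[ws.first]
    ev = ws.is_event
    return float(
        np.sum(np.log(ws.w[ev]) + lp[ev] - np.log(s0[ws.inv[ev]]))
    )


def _check_design(data: SurvivalData) -> None:
    sd = np.sqrt(np.average(
        (data.covariates - np.average(data.covariates, axis=0, weights=data.weights)) ** 2,
        axis=0, weights=data.weights,
    ))
    bad = [data.names[j] for j in np.nonzero(sd < 1e-12)[0]]
    if bad:
        raise CoxEstimationError(
            f"constant covariate column(s) {bad}: coefficient not identifiable"
        )


def fit_coxph(
    data: SurvivalData,
    ties_method: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
    max_halvings: int = 10,
    initial: np.ndarray | None = None,
) -> CoxFit:
    """Maximize the weighted Cox partial likelihood by Newton-Raphson.

    Convergence requires the maximum absolute score component below ``tol``.
    Accepted steps never decrease the log-likelihood (step-halving up to
    ``max_halvings``).  Non-convergence is flagged on the returned
    :class:`CoxFit`, not raised; a singular information matrix raises
    :class:`CoxEstimationError`.
    """
    _check_design(data)
    ws = _Workspace(data)
    quantities = {"breslow": _breslow_quantities, "efron": _efron_quantities}[ties_method]
    p = data.p
    coef = np.zeros(p) if initial is None else np.asarray(initial, dtype=float).copy()
    loglik, score, info, *_ = quantities(ws, coef)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise CoxEstimationError(
                "singular information matrix: covariates "
                f"{data.names} may be collinear"
            ) from exc
        new = coef + step
        ll_new, sc_new, info_new, *_ = quantities(ws, new)
        h = 0
        while (not np.isfinite(ll_new) or ll_new < loglik) and h < max_halvings:
            step *= 0.5
            new = coef + step
            ll_new, sc_new, info_new, *_ = quantities(ws, new)
            h += 1
        coef, loglik, score, info = new, ll_new, sc_new, info_new
    else:
        it = max_iter
    if converged is False and np.max(np.abs(score)) < tol:
        converged = True

    try:
        vcov_model = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxEstimationError(
            f"singular information at optimum; columns {data.names}"
        ) from exc
    vcov_model = 0.5 * (vcov_model + vcov_model.T)
    fit = CoxFit(
        coef=coef,
        vcov_model=vcov_model,
        vcov_robust=np.full((p, p), np.nan),
        loglik=loglik,
        converged=converged,
        n_iterations=it,
        names=list(data.names),
        n=data.n,
        n_events=int(data.event.sum()),
    )
    fit.vcov_robust = robust_vcov(fit, data, _ws=ws)
    return fit


def _score_residuals(ws: _Workspace, coef: np.ndarray) -> np.ndarray:
    """Per-subject score residuals r_i of the weighted partial likelihood.

    ``r_i = d_i (x_i - xbar(T_i)) - e^{lp_i} [x_i H(T_i) - G(T_i)]`` with
    ``H`` the weighted Breslow cumulative hazard and ``G`` its
    xbar-weighted companion; both cumulative over event times <= T_i.
    """
    _, _, _, lp, rexp, s0, xbar = _breslow_quantities(ws, coef)
    hu = np.where(ws.has_event, ws.dw / s0, 0.0)
    H = np.cumsum(hu)
    G = np.cumsum(hu[:, None] * xbar, axis=0)
    Hi = H[ws.inv]
    Gi = G[ws.inv]
    r = ws.d[:, None] * (ws.Xc - xbar[ws.inv]) - np.exp(lp)[:, None] * (
        ws.Xc * Hi[:, None] - Gi
    )
    return r


def robust_vcov(
    fit: CoxFit, data: SurvivalData, _ws: _Workspace | None = None
) -> np.ndarray:
    """Sandwich covariance ``A^{-1} B A^{-1}``.

    ``A`` is the observed information of the weighted partial likelihood
    and ``B = sum_i (w_i r_i)(w_i r_i)'`` the cross-product of weighted
    score residuals (the dfbeta form used by ``coxph(robust=TRUE)``).
    Weights are treated as fixed: no correction for weight estimation.
    """
    ws = _ws if _ws is not None else _Workspace(data)
    r = _score_residuals(ws, fit.coef)
    wr = ws.w[:, None] * r
    B = wr.T @ wr
    V = fit.vcov_model @ B @ fit.vcov_model
    return 0.5 * (V + V.T)


def wald_test(fit: CoxFit, index: int, null_value: float = 0.0) -> dict:
    """Robust-SE Wald test and 95% CI for one coefficient."""
    se = fit.se_robust[index]
    z = (fit.coef[index] - null_value) / se
    return {
        "z": float(z),
        "p_value": float(2 * stats.norm.sf(abs(z))),
        "ci_95": (
            float(fit.coef[index] - 1.959963984540054 * se),
            float(fit.coef[index] + 1.959963984540054 * se),
        ),
    }


def breslow_baseline(fit: CoxFit, data: SurvivalData):
    """Weighted Breslow baseline cumulative hazard.

    Returns ``(jump_times, cumhaz)`` where
    ``Lambda_0(t) = sum_{t_u <= t} dw(t_u) / S0(t_u)`` with sums on the
    original (uncentered) covariate scale.
    """
    ws = _Workspace(data)
    _, _, _, lp, rexp, s0, _ = _breslow_quantities(ws, fit.coef)
    # _Workspace centers covariates; rescale S0 back to the raw scale
    scale = np.exp(float(ws.xmean @ fit.coef))
    he = ws.has_event
    jumps = ws.dw[he] / (s0[he] * scale)
    return ws.ut[he], np.cumsum(jumps)


def export_fit(fit: CoxFit, path) -> None:
    """Write the fit as a flat table (term, coef, se_model, se_robust, z, p)."""
    fit.summary().to_csv(path, index=False)
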