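"""From-first-principles survival and regression primitives.

This module implements the four statistical workhorses of the pipeline without
delegating to an external modelling library:

* weighted logistic regression by iteratively reweighted least squares (IRLS)
  with a cluster-robust sandwich covariance,
* Cox proportional hazards with Breslow tie handling and a robust (score
  residual) covariance,
* the Kaplan-Meier product-limit estimator,
* the k-group log-rank test.

Established GLM/survival libraries are used only as independent cross-checks
in the test suite.  All functions accept plain numpy arrays; patient/cluster
identifiers may be any hashable dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

from .errors import (
    ConvergenceError,
    EstimationError,
    RankDeficiencyError,
    SeparationError,
    ZeroEventsError,
)

__all__ = [
    "LogisticFit",
    "CoxFit",
    "KMCurve",
    "LogRankResult",
    "fit_logistic",
    "fit_cox",
    "km_estimate",
    "logrank_test",
]

#: IRLS stops when the largest absolute coefficient update falls below this.
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
#: Any |coefficient| beyond this is read as separation (log-odds of ~1e21).
SEPARATION_BOUND = 50.0

COX_TOL = 1e-10
COX_MAX_ITER = 100


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _check_full_rank(X: np.ndarray, names=None) -> None:
    """Raise RankDeficiencyError naming (approximately) dependent columns."""
    if X.shape[0] < X.shape[1]:
        raise RankDeficiencyError(
            f"design has {X.shape[1]} columns but only {X.shape[0]} rows"
        )
    # QR with column pivoting is not exposed by numpy; scan R's diagonal after
    # a plain QR, which is enough to localise the first dependent column.
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    bad = np.flatnonzero(diag <= 1e-10 * max(scale, 1.0))
    if bad.size:
        if names is not None:
            labels = [str(names[j]) for j in bad]
        else:
            labels = [f"column {j}" for j in bad]
        raise RankDeficiencyError(
            "design matrix is rank deficient; dependent columns: "
            + ", ".join(labels),
            columns=labels,
        )


def _cluster_sum(rows: np.ndarray, cluster_ids: np.ndarray) -> np.ndarray:
    """Sum rows of a (n, p) array within clusters; returns (g, p)."""
    _, inverse = np.unique(cluster_ids, return_inverse=True)
    g = inverse.max() + 1
    out = np.zeros((g, rows.shape[1]))
    np.add.at(out, inverse, rows)
    return out


@dataclass
class LogisticFit:
    """Result of a weighted logistic regression.

    ``covariance_model`` is the inverse of the weighted Fisher information;
    ``covariance_robust`` is the cluster sandwich (equal to the
    heteroskedasticity-robust sandwich when each observation is its own
    cluster).
    """

    coefficients: np.ndarray
    covariance_model: np.ndarray
    covariance_robust: np.ndarray
    n_obs: int
    n_clusters: int
    converged: bool
    iterations: int
    column_names: list = field(default_factory=list)

    @property
    def bse_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance_model))

    @property
    def bse_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance_robust))

    def predict(self, X) -> np.ndarray:
        return expit(_as_2d(X) @ self.coefficients)


def fit_logistic(y, X, weights=None, cluster_ids=None, column_names=None,
                 tol: float = IRLS_TOL, max_iter: int = IRLS_MAX_ITER) -> LogisticFit:
    """Maximise the weighted Bernoulli log-likelihood by IRLS.

    Parameters
    ----------
    y : (n,) binary response.
    X : (n, p) design matrix (include the intercept column yourself).
    weights : (n,) non-negative observation weights; None means all ones.
        Multiplying all weights by a positive constant leaves the
        coefficients unchanged.
    cluster_ids : (n,) identifiers for the sandwich "meat"; rows sharing an
        id have their scores summed before the outer product.  None treats
        every row as its own cluster.
    """
    y = np.asarray(y, dtype=float)
    X = _as_2d(X)
    n, p = X.shape
    if y.shape[0] != n:
        raise EstimationError(f"y has {y.shape[0]} rows, X has {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise EstimationError("negative observation weights")
    if cluster_ids is None:
        cluster_ids = np.arange(n)
    else:
        cluster_ids = np.asarray(cluster_ids)

    support = w > 0
    _check_full_rank(X[support] * np.sqrt(w[support, None]), column_names)

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        # Fisher scoring: W = w * mu(1-mu), solve (X'WX) d = X' w (y - mu)
        wls = w * mu * (1.0 - mu)
        info = X.T @ (X * wls[:, None])
        score = X.T @ (w * (y - mu))
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # perfectly flat likelihood
            raise RankDeficiencyError(
                f"singular information matrix at iteration {it}"
            ) from exc
        beta = beta + delta
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                "detected separation: |coefficient| exceeded "
                f"{SEPARATION_BOUND} at iteration {it}"
            )
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations",
            last_params=beta, iterations=it,
        )

    mu = expit(X @ beta)
    wls = w * mu * (1.0 - mu)
    info = X.T @ (X * wls[:, None])
    cov_model = np.linalg.inv(info)
    scores = X * (w * (y - mu))[:, None]
    grouped = _cluster_sum(scores, cluster_ids)
    meat = grouped.T @ grouped
    cov_robust = cov_model @ meat @ cov_model
    cov_robust = 0.5 * (cov_robust + cov_robust.T)

    return LogisticFit(
        coefficients=beta,
        covariance_model=cov_model,
        covariance_robust=cov_robust,
        n_obs=n,
        n_clusters=len(np.unique(cluster_ids)),
        converged=converged,
        iterations=it,
        column_names=list(column_names) if column_names is not None else [],
    )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Breslow ties, robust covariance)."""

    coefficients: np.ndarray
    covariance_model: np.ndarray
    covariance_robust: np.ndarray
    n_obs: int
    n_events: int
    converged: bool
    iterations: int
    ties_method: str = "breslow"
    column_names: list = field(default_factory=list)

    @property
    def bse_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance_robust))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)


def _cox_sums(order, time, event, X, beta):
    """Risk-set sums S0, S1, S2 evaluated at each row's own time.

    Rows must be pre-sorted by descending time (``order``); with ties, every
    row with t_j >= t_i belongs to the risk set of t_i (Breslow).
    Returns per-event-time quantities aligned with the ascending-time view.
    """
    ts = time[order]
    Xs = X[order]
    r = np.exp(Xs @ beta)
    S0 = np.cumsum(r)
    S1 = np.cumsum(Xs * r[:, None], axis=0)
    p = X.shape[1]
    S2 = np.cumsum(r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    # index of the last row sharing each time (= full risk set under ties)
    last = np.empty(len(ts), dtype=int)
    idx = 0
    while idx < len(ts):
        j = idx
        while j + 1 < len(ts) and ts[j + 1] == ts[idx]:
            j += 1
        last[idx:j + 1] = j
        idx = j + 1
    return ts, Xs, r, S0[last], S1[last], S2[last]


def fit_cox(time, event, X, cluster_ids=None, column_names=None,
            tol: float = COX_TOL, max_iter: int = COX_MAX_ITER) -> CoxFit:
    """Newton-Raphson on the Breslow partial likelihood.

    The robust covariance is the sandwich built from score residuals summed
    within cluster (each subject its own cluster when ``cluster_ids`` is
    None), the grouped-jackknife form standard for survival data.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    X = _as_2d(X)
    n, p = X.shape
    if np.any(time <= 0):
        raise EstimationError("non-positive survival times")
    n_events = int(event.sum())
    if n_events == 0:
        raise ZeroEventsError("no events: Cox model is not estimable")
    # centre columns for numerical stability (does not change coefficients)
    centre = X.mean(axis=0)
    Xc = X - centre
    _check_full_rank(Xc, column_names)

    order = np.argsort(-time, kind="stable")
    ev_s = event[order]
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ts, Xs, r, S0, S1, S2 = _cox_sums(order, time, event, Xc, beta)
        is_ev = ev_s == 1
        xbar = S1[is_ev] / S0[is_ev, None]
        score = (Xs[is_ev] - xbar).sum(axis=0)
        info = (S2[is_ev] / S0[is_ev, None, None]
                - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(
                "singular information matrix in Cox fit (constant or "
                "collinear covariates on the risk sets)"
            ) from exc
        beta = beta + delta
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                "monotone partial likelihood: no finite maximiser"
            )
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Cox Newton-Raphson did not converge in {max_iter} iterations",
            last_params=beta, iterations=it,
        )

    ts, Xs, r, S0, S1, S2 = _cox_sums(order, time, event, Xc, beta)
    is_ev = ev_s == 1
    xbar = S1[is_ev] / S0[is_ev, None]
    info = (S2[is_ev] / S0[is_ev, None, None]
            - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    cov_model = np.linalg.inv(info)

    # Score residuals (Lin-Wei): r_i = d_i (x_i - xbar(t_i))
    #   - e^{x_i b} [x_i A(t_i) - B(t_i)],
    # with A(t) = sum_{t_k <= t} d_k / S0(t_k), B(t) likewise with xbar.
    ev_times = ts[is_ev]
    a_terms = 1.0 / S0[is_ev]
    b_terms = xbar * a_terms[:, None]
    # cumulate over event times ascending; ts is descending
    asc = np.argsort(ev_times, kind="stable")
    et_asc = ev_times[asc]
    A_cum = np.cumsum(a_terms[asc])
    B_cum = np.cumsum(b_terms[asc], axis=0)
    # for each subject, number of event times <= its own time
    pos = np.searchsorted(et_asc, ts, side="right")
    A_i = np.where(pos > 0, A_cum[np.maximum(pos - 1, 0)], 0.0)
    B_i = np.where(pos[:, None] > 0, B_cum[np.maximum(pos - 1, 0)], 0.0)
    resid = -r[:, None] * (Xs * A_i[:, None] - B_i)
    own_xbar = np.zeros_like(Xs)
    own_xbar[is_ev] = xbar
    resid += np.where(is_ev[:, None], Xs - own_xbar, 0.0)

    if cluster_ids is None:
        grouped = resid
    else:
        grouped = _cluster_sum(resid, np.asarray(cluster_ids)[order])
    meat = grouped.T @ grouped
    cov_robust = cov_model @ meat @ cov_model
    cov_robust = 0.5 * (cov_robust + cov_robust.T)

    return CoxFit(
        coefficients=beta,
        covariance_model=cov_model,
        covariance_robust=cov_robust,
        n_obs=n,
        n_events=n_events,
        converged=converged,
        iterations=it,
        column_names=list(column_names) if column_names is not None else [],
    )


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve over the observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(time, event) -> KMCurve:
    """Product-limit estimator.

    Subjects censored at t stay in the risk set for events at t (the standard
    convention: censoring is read as happening just after the event time).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise EstimationError("empty sample")
    if np.any(time < 0):
        raise EstimationError("negative survival times")
    ev_times = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in ev_times], dtype=int)
    d = np.array([((time == t) & (event == 1)).sum() for t in ev_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(event_times=ev_times, survival=surv, at_risk=at_risk, events=d)


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    groups: list


def logrank_test(time, event, group) -> LogRankResult:
    """k-group log-rank test from hypergeometric moments at each event time.

    The statistic is (O-E)' V^{-1} (O-E) over the first k-1 groups, with V the
    hypergeometric covariance summed over distinct event times; chi-square on
    k-1 degrees of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels, g_idx = np.unique(group, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise EstimationError("log-rank test needs at least 2 groups")
    if event.sum() == 0:
        raise ZeroEventsError("log-rank test needs at least one event")

    ev_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in ev_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = ((time == t) & (event == 1)).sum()
        n_g = np.bincount(g_idx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(g_idx[(time == t) & (event == 1)], minlength=k).astype(float)
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            V += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    chi = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi = max(chi, 0.0)
    df = k - 1
    p = float(chi2_dist.sf(chi, df))
    return LogRankResult(
        chi_square=chi, df=df, p_value=p, observed=O, expected=E,
        groups=list(labels),
    )
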