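"""Decomposable local scores localscore(v, S) for a node given a parent set.

Two score families are provided — BIC (Gaussian for continuous nodes,
multinomial for categorical nodes, plus logistic / Cox variants for a
designated outcome) and BGe (Bayesian Gaussian equivalent marginal
likelihood).  All scores are on the log scale with larger = better, and the
BIC convention is maximized log-likelihood minus (k/2)·ln(n), so that
−2·score is the classical BIC.  Degenerate fits (exact collinearity, perfect
residual fit, non-positive-definite posteriors, single-class or zero-event
outcomes) return a minus-infinity sentinel rather than raising.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import multigammaln

from .data import CATEGORICAL, CONTINUOUS, DataMatrix

NEG_INF = float("-inf")

#: Residual variances below this are treated as exact fits (degenerate).
RESIDUAL_VAR_FLOOR = 1e-12

#: Ridge penalty stabilizing logistic fits under separation.
LOGISTIC_RIDGE = 1e-6


@dataclass(frozen=True)
class LocalScore:
    """Score of ``node`` with parent set ``parents`` (log scale)."""

    node: str
    parents: frozenset
    value: float


def _design(data: DataMatrix, parents) -> np.ndarray | None:
    """Regression design matrix (with intercept) for a set of parents.

    Categorical parents enter as full dummy encodings (first level dropped).
    Returns None if the design is empty of parents (intercept only).
    """
    cols = []
    for pa in sorted(parents):
        if data.kind_of(pa) == CATEGORICAL:
            d = pd.get_dummies(data.frame[pa], drop_first=True)
            cols.append(d.to_numpy(dtype=float))
        else:
            cols.append(data.column(pa).astype(float)[:, None])
    if not cols:
        return None
    return np.hstack(cols)


def _gaussian_loglik(y: np.ndarray, X: np.ndarray | None) -> tuple[float, int] | None:
    """Maximized Gaussian log-likelihood of y ~ X (ML variance, divisor N).

    Returns (loglik, n_regression_params) or None for a degenerate fit.
    """
    n = y.shape[0]
    if X is None:
        Z = np.ones((n, 1))
    else:
        Z = np.column_stack([np.ones(n), X])
    if Z.shape[1] >= n:
        return None
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        return None
    resid = y - Z @ beta
    s2 = float(resid @ resid) / n
    if s2 < RESIDUAL_VAR_FLOOR:
        return None
    ll = -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)
    return ll, Z.shape[1]


def score_gaussian_bic(node: str, parents, data: DataMatrix) -> LocalScore:
    """Gaussian BIC local score: max log-likelihood − (k/2)·ln N.

    k counts the regression coefficients (intercept included) plus the
    residual variance, i.e. k = |parents| + 2 for all-continuous parents.
    """
    parents = frozenset(parents)
    y = data.column(node).astype(float)
    n = data.n_samples
    fit = _gaussian_loglik(y, _design(data, parents))
    if fit is None:
        warnings.warn(
            f"degenerate Gaussian fit for {node} | {sorted(parents)}; "
            "score set to -inf",
            stacklevel=2,
        )
        return LocalScore(node, parents, NEG_INF)
    ll, n_params = fit
    k = n_params + 1  # + residual variance
    return LocalScore(node, parents, ll - 0.5 * k * math.log(n))


def score_discrete_bic(node: str, parents, data: DataMatrix) -> LocalScore:
    """Multinomial BIC local score for a categorical child.

    Log-likelihood is sum over parent configurations j and child levels k of
    n_jk·ln(n_jk / n_j·), with 0·ln 0 := 0; the parameter count is
    (r − 1)·prod_j q_j for r child levels and q_j levels of parent j.
    """
    parents = frozenset(parents)
    for pa in parents:
        if data.kind_of(pa) != CATEGORICAL:
            raise ValueError(
                f"continuous parent {pa!r} of categorical child {node!r} "
                "is not supported"
            )
    n = data.n_samples
    child = data.frame[node]
    r = child.nunique()
    if parents:
        q = 1
        for pa in sorted(parents):
            q *= data.frame[pa].nunique()
        if q > n:
            warnings.warn(
                f"parent configuration space for {node} ({q}) exceeds "
                f"sample size {n}: sparse tables",
                stacklevel=2,
            )
        counts = (
            data.frame.groupby(sorted(parents), observed=True)[node]
            .value_counts()
            .rename("n_jk")
            .reset_index()
        )
        njk = counts["n_jk"].to_numpy(dtype=float)
        nj = (
            counts.groupby(sorted(parents), observed=True)["n_jk"]
            .transform("sum")
            .to_numpy(dtype=float)
        )
        ll = float(np.sum(njk * np.log(njk / nj)))
        k = (r - 1) * q
    else:
        njk = child.value_counts().to_numpy(dtype=float)
        ll = float(np.sum(njk * np.log(njk / n)))
        k = r - 1
    return LocalScore(node, parents, ll - 0.5 * k * math.log(n))


# ---------------------------------------------------------------------------
# BGe: Bayesian Gaussian equivalent score
# ---------------------------------------------------------------------------


class BGeContext:
    """Precomputed sufficient statistics for BGe local scores on one dataset.

    Hyperparameters follow the common default parameterization: alpha_mu = 1,
    alpha_w = p + 2, prior mean = sample mean (so the mean-shift term in the
    posterior scale matrix vanishes), prior scale matrix T = t·I with
    t = alpha_mu·(alpha_w − p − 1)/(alpha_mu + 1).
    """

    def __init__(self, data: DataMatrix, alpha_mu: float = 1.0, alpha_w: float | None = None):
        cont = [v for v in data.variables if data.kind_of(v) == CONTINUOUS]
        self.names = cont
        self.index = {v: i for i, v in enumerate(cont)}
        X = np.column_stack([data.column(v).astype(float) for v in cont])
        self.N = X.shape[0]
        self.p = X.shape[1]
        self.alpha_mu = alpha_mu
        self.alpha_w = alpha_w if alpha_w is not None else self.p + 2
        self.t = alpha_mu * (self.alpha_w - self.p - 1) / (alpha_mu + 1)
        Xc = X - X.mean(axis=0)
        self.R = self.t * np.eye(self.p) + Xc.T @ Xc

    def log_marginal(self, subset: tuple[int, ...]) -> float:
        """log p(d_Y) for the variable subset Y (empty subset → 0)."""
        l = len(subset)
        if l == 0:
            return 0.0
        N, aw, p = self.N, self.alpha_w, self.p
        df_prior = aw - p + l
        idx = np.asarray(subset)
        R = self.R[np.ix_(idx, idx)]
        sign, logdet_R = np.linalg.slogdet(R)
        if sign <= 0:
            return NEG_INF
        logdet_T = l * math.log(self.t)
        return (
            -0.5 * l * N * math.log(math.pi)
            + 0.5 * l * math.log(self.alpha_mu / (N + self.alpha_mu))
            + multigammaln(0.5 * (N + df_prior), l)
            - multigammaln(0.5 * df_prior, l)
            + 0.5 * df_prior * logdet_T
            - 0.5 * (N + df_prior) * logdet_R
        )

    def score(self, node: str, parents) -> float:
        pa = tuple(sorted(self.index[u] for u in parents))
        fam = tuple(sorted(pa + (self.index[node],)))
        num = self.log_marginal(fam)
        den = self.log_marginal(pa)
        if not (math.isfinite(num) and math.isfinite(den)):
            return NEG_INF
        return num - den


def score_bge(node: str, parents, data: DataMatrix, context: BGeContext | None = None) -> LocalScore:
    """BGe local score: log marginal likelihood of ``node`` given ``parents``
    under the Gaussian–inverse-Wishart family, as the standard ratio of
    subset marginal terms (decomposable and score-equivalent)."""
    parents = frozenset(parents)
    if context is None:
        context = BGeContext(data)
    return LocalScore(node, parents, context.score(node, parents))


# ---------------------------------------------------------------------------
# Outcome scores
# ---------------------------------------------------------------------------


def _logistic_loglik(y: np.ndarray, X: np.ndarray | None) -> float | None:
    """Maximized (ridge-stabilized) logistic log-likelihood."""
    n = y.shape[0]
    Z = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    if len(np.unique(y)) < 2:
        return None

    def negll(beta):
        eta = Z @ beta
        # log(1 + exp(eta)) − y·eta, numerically stable
        val = np.logaddexp(0.0, eta).sum() - float(y @ eta)
        return val + 0.5 * LOGISTIC_RIDGE * float(beta @ beta)

    def grad(beta):
        mu = 1.0 / (1.0 + np.exp(-(Z @ beta)))
        return Z.T @ (mu - y) + LOGISTIC_RIDGE * beta

    res = optimize.minimize(negll, np.zeros(Z.shape[1]), jac=grad, method="L-BFGS-B")
    beta = res.x
    eta = Z @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _cox_null_loglik(time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of the null Cox model: −Σ_j d_j ln|R_j|."""
    t, e = time, event
    ll = 0.0
    for ut in np.unique(t[e == 1]):
        d = int(((t == ut) & (e == 1)).sum())
        at_risk = int((t >= ut).sum())
        ll -= d * math.log(at_risk)
    return ll


def _cox_loglik(data: DataMatrix, parents) -> tuple[float, int] | None:
    """Maximized Cox partial log-likelihood (Breslow ties) and event count."""
    time, event = data.survival_arrays()
    n_events = int(event.sum())
    if n_events == 0:
        return None
    if not parents:
        return _cox_null_loglik(time, event), n_events
    from lifelines import CoxPHFitter

    X = _design(data, parents)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter(penalizer=0.0)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception:
        # stabilize near-separated fits
        cph = CoxPHFitter(penalizer=1e-6)
        cph.fit(df, duration_col="time", event_col="event")
    return float(cph.log_likelihood_), n_events


def score_outcome(parents, data: DataMatrix) -> LocalScore:
    """Local score of the designated outcome given ``parents``.

    continuous → Gaussian BIC; binary → logistic log-likelihood −
    (k/2)·ln N with k = |parents| + 1; survival → Cox partial
    log-likelihood (Breslow ties) − (k/2)·ln(events) with k = |parents|.
    """
    out = data.outcome
    if out is None:
        raise ValueError("no outcome designated")
    parents = frozenset(parents)
    if out.kind == "continuous":
        return score_gaussian_bic(out.name, parents, data)
    if out.kind == "binary":
        y = data.column(out.name).astype(float)
        ll = _logistic_loglik(y, _design(data, parents))
        if ll is None:
            warnings.warn("single-class binary outcome; score -inf", stacklevel=2)
            return LocalScore(out.name, parents, NEG_INF)
        k = len(parents) + 1
        return LocalScore(out.name, parents, ll - 0.5 * k * math.log(data.n_samples))
    if out.kind == "survival":
        fit = _cox_loglik(data, parents)
        if fit is None:
            warnings.warn("zero events in survival outcome; score -inf", stacklevel=2)
            return LocalScore(out.name, parents, NEG_INF)
        ll, n_events = fit
        k = len(parents)
        pen = 0.5 * k * math.log(n_events) if k else 0.0
        return LocalScore(out.name, parents, ll - pen)
    raise ValueError(f"unknown outcome kind {out.kind!r}")


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------


def make_scorer(data: DataMatrix, method: str = "bic"):
    """Return score_fn(node, parents) -> float for the given data and method.

    Dispatches the designated outcome to its outcome-specific score,
    categorical children to the multinomial BIC, and continuous children to
    the Gaussian BIC or BGe.  BGe sufficient statistics are precomputed once.
    """
    if method not in ("bic", "bge"):
        raise ValueError(f"unknown score method {method!r}")
    bge_ctx = BGeContext(data) if method == "bge" else None
    out_name = data.outcome_name

    def score_fn(node: str, parents) -> float:
        if node == out_name:
            return score_outcome(parents, data).value
        kind = data.kind_of(node)
        if kind == CATEGORICAL:
            return score_discrete_bic(node, parents, data).value
        if method == "bge":
            return score_bge(node, parents, data, context=bge_ctx).value
        return score_gaussian_bic(node, parents, data).value

    return score_fn
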