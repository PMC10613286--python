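"""Linear mixed models with crossed random effects.

The models needed here have a specific shape that general-purpose Python
fitters do not cover: several *crossed* iid random-intercept/slope
components (one variance each) plus, optionally, one grouping factor whose
random intercept and random slope carry an unstructured 2x2 covariance.
This module fits exactly that family by profiled (restricted) maximum
likelihood:

    y = X beta + Z u + e,   u ~ N(0, sigma^2 Gamma(theta)),  e ~ N(0, sigma^2 I)

``Gamma`` is block diagonal; ``sigma^2`` and ``beta`` are profiled out, and
the optimizer works on the relative covariance parameters ``theta``
(log-Cholesky scale).  All linear algebra goes through the q-dimensional
Woodbury identity, so cost scales with the number of random-effect columns
rather than the number of observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize


def indicator_matrix(labels) -> tuple[np.ndarray, list]:
    """Dense 0/1 design for a categorical factor; returns (Z, level order)."""
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    idx = {lv: j for j, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels.tolist()):
        Z[i, idx[lab]] = 1.0
    return Z, levels


@dataclass
class IIDComponent:
    """One crossed random component with a single variance (intercepts, or
    slopes when ``Z`` columns carry the regressor)."""

    name: str
    Z: np.ndarray
    levels: list = field(default_factory=list)


@dataclass
class PairedComponent:
    """Random intercept + random slope for one factor, unstructured 2x2
    covariance between them."""

    name: str
    Z_intercept: np.ndarray
    Z_slope: np.ndarray
    levels: list = field(default_factory=list)


@dataclass
class MixedLMResult:
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    converged: bool
    method: str
    theta: np.ndarray
    varcomps: dict
    blups: dict
    n_params: int

    def coef(self, j: int = -1) -> tuple[float, float]:
        return float(self.beta[j]), float(self.se[j])


class _Profile:
    """Profiled -2 log-likelihood over theta with cached design products."""

    def __init__(self, y, X, iid, pair, method):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.iid = iid
        self.pair = pair
        self.method = method
        blocks = [c.Z for c in iid]
        if pair is not None:
            blocks += [pair.Z_intercept, pair.Z_slope]
        self.Z = np.hstack(blocks) if blocks else np.zeros((self.n, 0))
        self.q = self.Z.shape[1]
        self.n_theta = len(iid) + (3 if pair is not None else 0)

    def _lam(self, theta) -> np.ndarray:
        """Block lower-triangular square root of Gamma (q x q)."""
        L = np.zeros((self.q, self.q))
        off = 0
        for i, c in enumerate(self.iid):
            k = c.Z.shape[1]
            L[off : off + k, off : off + k] = np.exp(theta[i]) * np.eye(k)
            off += k
        if self.pair is not None:
            qp = self.pair.Z_intercept.shape[1]
            l11 = np.exp(theta[-3])
            l21 = theta[-2]
            l22 = np.exp(theta[-1])
            L[off : off + qp, off : off + qp] = l11 * np.eye(qp)
            L[off + qp : off + 2 * qp, off : off + qp] = l21 * np.eye(qp)
            L[off + qp : off + 2 * qp, off + qp : off + 2 * qp] = l22 * np.eye(qp)
        return L

    def _solve(self, theta):
        """Return (beta, rss, logdetM, XtMiX) at the given theta."""
        y, X, Z = self.y, self.X, self.Z
        if self.q == 0:
            beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            self.rank_deficient = rank < self.p
            r = y - X @ beta
            return beta, float(r @ r), 0.0, X.T @ X
        L = self._lam(theta)
        Zt = Z @ L  # n x q
        A = np.eye(self.q) + Zt.T @ Zt
        cA = np.linalg.cholesky(A)
        logdetM = 2.0 * np.log(np.diag(cA)).sum()

        def Minv_mul(B):
            ZtB = Zt.T @ B
            w = np.linalg.solve(cA.T, np.linalg.solve(cA, ZtB))
            return B - Zt @ w

        MiX = Minv_mul(X)
        Miy = Minv_mul(y)
        XtMiX = X.T @ MiX
        # lstsq tolerates rank-deficient designs; the fit is then flagged
        # non-converged through the singular standard errors
        beta, _, rank, _ = np.linalg.lstsq(XtMiX, X.T @ Miy, rcond=None)
        self.rank_deficient = rank < self.p
        r = y - X @ beta
        rss = float(r @ Minv_mul(r))
        return beta, rss, logdetM, XtMiX

    def neg2ll(self, theta) -> float:
        n, p = self.n, self.p
        try:
            _, rss, logdetM, XtMiX = self._solve(theta)
        except np.linalg.LinAlgError:
            return 1e12
        if rss <= 0 or not np.isfinite(rss):
            return 1e12
        if self.method == "reml":
            df = n - p
            sigma2 = rss / df
            sign, logdetX = np.linalg.slogdet(XtMiX)
            if sign <= 0:
                return 1e12
            return df * np.log(2 * np.pi * sigma2) + logdetM + logdetX + df
        sigma2 = rss / n
        return n * np.log(2 * np.pi * sigma2) + logdetM + n


def fit_mixed_model(
    y,
    X,
    iid_components: list[IIDComponent] | None = None,
    paired_component: PairedComponent | None = None,
    method: str = "ml",
    maxiter: int = 100,
) -> MixedLMResult:
    """Fit the mixed model; never raises on non-convergence (flag instead).

    ``method`` is ``"ml"`` (for AIC-based model comparison of fixed-effect
    structures) or ``"reml"`` (for random-slope/BLUP estimation, avoiding
    downward-biased variance estimates).  ``maxiter`` caps optimizer
    iterations; any solution reached by then is accepted, with
    ``converged`` reporting the optimizer's own verdict.
    """
    iid_components = iid_components or []
    prof = _Profile(y, X, iid_components, paired_component, method)
    n, p = prof.n, prof.p
    if prof.n_theta == 0:
        beta, rss, _, XtMiX = prof._solve(np.empty(0))
        sigma2 = rss / (n - p) if method == "reml" else rss / n
        neg2 = prof.neg2ll(np.empty(0))
        theta = np.empty(0)
        success = True
    else:
        theta0 = np.full(prof.n_theta, np.log(0.5))
        if paired_component is not None:
            theta0[-2] = 0.0
        res = minimize(
            prof.neg2ll,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 50 * maxiter},
        )
        theta = res.x
        success = bool(res.success) and np.isfinite(res.fun)
        beta, rss, _, XtMiX = prof._solve(theta)
        sigma2 = rss / (n - p) if method == "reml" else rss / n
        neg2 = prof.neg2ll(theta)
    try:
        cov_beta = sigma2 * np.linalg.pinv(XtMiX)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov_beta))
        ok_se = np.all(np.isfinite(se)) and not getattr(prof, "rank_deficient", False)
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        ok_se = False
    loglik = -0.5 * neg2
    n_params = p + prof.n_theta + 1
    aic = 2 * n_params - 2 * loglik
    varcomps = _varcomps(prof, theta, sigma2)
    blups = _blups(prof, theta, beta)
    return MixedLMResult(
        beta=beta,
        se=se,
        sigma2=float(sigma2),
        loglik=float(loglik),
        aic=float(aic),
        converged=bool(success and ok_se and np.isfinite(aic)),
        method=method,
        theta=np.asarray(theta),
        varcomps=varcomps,
        blups=blups,
        n_params=n_params,
    )


def _varcomps(prof: _Profile, theta, sigma2) -> dict:
    out = {"residual": float(sigma2)}
    for i, c in enumerate(prof.iid):
        out[c.name] = float(sigma2 * np.exp(2 * theta[i]))
    if prof.pair is not None:
        l11, l21, l22 = np.exp(theta[-3]), theta[-2], np.exp(theta[-1])
        S = np.array([[l11, 0.0], [l21, l22]])
        out[prof.pair.name] = sigma2 * (S @ S.T)
    return out


def _blups(prof: _Profile, theta, beta) -> dict:
    """Empirical Bayes predictions u_hat = Gamma Z' M^{-1} (y - X beta)."""
    out: dict = {}
    if prof.q == 0:
        return out
    L = prof._lam(theta)
    Zt = prof.Z @ L
    A = np.eye(prof.q) + Zt.T @ Zt
    r = prof.y - prof.X @ beta
    Mir = r - Zt @ np.linalg.solve(A, Zt.T @ r)
    u = (L @ L.T) @ (prof.Z.T @ Mir)
    off = 0
    for c in prof.iid:
        k = c.Z.shape[1]
        out[c.name] = u[off : off + k]
        off += k
    if prof.pair is not None:
        qp = prof.pair.Z_intercept.shape[1]
        out[prof.pair.name + "_intercept"] = u[off : off + qp]
        out[prof.pair.name + "_slope"] = u[off + qp : off + 2 * qp]
    return out
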