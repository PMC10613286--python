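"""Association inference between learning difficulty and population size.

Four inference families, all with learning difficulty (``b`` or ``mu``) as
the outcome and the natural log of speaker population size as the exposure:

* multi-model LMER — every covariate subset of a crossed random-effect
  grammar is fitted by ML, compared by AIC against its population-free
  reduced counterpart, and combined by frequentist model averaging (FMA)
  with weights proportional to ``exp(-AIC/2)``;
* double-selection lasso — controls chosen by two cross-validated lassos
  (exposure on candidates, outcome on candidates), final OLS with
  cluster-robust errors, significance by Freedman-Lane permutation;
* phylogenetic GLS — Brownian-motion covariance from a language tree;
* SAR error models — two spatially lagged error terms specified by
  inverse-distance weight matrices (geographic + lexical), estimated by
  quadratic-moment matching plus feasible GLS, significance by permuting
  the exposure and refitting.

Permutation p-values use ``max(count, 1) / n_perm`` so the reported value
stays in (0, 1]; the smallest achievable p is ``1/n_perm``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from glottolearn.lmm import IIDComponent, MixedLMResult, fit_mixed_model, indicator_matrix

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

STUDY1_GROUPS = ("corpus", "family", "macro_area", "country", "script")
STUDY1_FIXED_OPTIONS = ((), ("h",), ("L",), ("h", "L"), ("h", "L", "h:L"))
STUDY2_GROUPS = ("script", "macro_area", "country", "family", "subfamily", "sub_branch")


# ---------------------------------------------------------------------------
# model-space enumeration


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification in the subset grammar."""

    study: int
    fixed: tuple[str, ...] = ()
    include_population: bool = True
    intercepts: tuple[str, ...] = ()
    slopes: tuple[str, ...] = ()

    def reduced(self) -> "ModelSpec":
        """Population fixed effect and all random slopes removed."""
        return ModelSpec(
            study=self.study,
            fixed=self.fixed,
            include_population=False,
            intercepts=self.intercepts,
            slopes=(),
        )


def enumerate_model_subsets(study: int) -> list[tuple[ModelSpec, ModelSpec]]:
    """All (full, reduced) spec pairs of the study's covariate grammar.

    Study 1: 5 fixed-part options x language intercept in/out x five
    grouping factors each absent / intercept / intercept+slope = 2430 full
    specs (4860 fits counting reduced pairs).  Study 2: six grouping
    factors in the same three states, all-absent excluded = 728 full specs
    (1456 fits).
    """
    pairs: list[tuple[ModelSpec, ModelSpec]] = []
    if study == 1:
        for fixed in STUDY1_FIXED_OPTIONS:
            for lang_in in (False, True):
                for states in itertools.product(range(3), repeat=len(STUDY1_GROUPS)):
                    intercepts = tuple(
                        g for g, s in zip(STUDY1_GROUPS, states) if s >= 1
                    )
                    if lang_in:
                        intercepts = intercepts + ("language",)
                    slopes = tuple(g for g, s in zip(STUDY1_GROUPS, states) if s == 2)
                    full = ModelSpec(1, fixed, True, intercepts, slopes)
                    pairs.append((full, full.reduced()))
    elif study == 2:
        for states in itertools.product(range(3), repeat=len(STUDY2_GROUPS)):
            if all(s == 0 for s in states):
                continue
            intercepts = tuple(g for g, s in zip(STUDY2_GROUPS, states) if s >= 1)
            slopes = tuple(g for g, s in zip(STUDY2_GROUPS, states) if s == 2)
            full = ModelSpec(2, (), True, intercepts, slopes)
            pairs.append((full, full.reduced()))
    else:
        raise ValueError("study must be 1 or 2")
    return pairs


# ---------------------------------------------------------------------------
# association LMERs, delta-AIC, FMA


@dataclass
class AssocFit:
    """Coefficient of log population from one mixed-model fit."""

    spec: ModelSpec
    beta: float
    se: float
    aic: float
    converged: bool
    result: MixedLMResult | None = None


def standardize_per_corpus(df: pd.DataFrame, cols: list[str], corpus_col: str = "corpus") -> pd.DataFrame:
    """Z-score the given columns within each corpus (outcome and controls)."""
    out = df.copy()
    for col in cols:
        grp = out.groupby(corpus_col)[col]
        sd = grp.transform("std").replace(0, np.nan)
        out[col] = (out[col] - grp.transform("mean")) / sd
        out[col] = out[col].fillna(0.0)
    return out


def fit_association_lmer(
    data: pd.DataFrame,
    spec: ModelSpec,
    outcome: str,
    maxiter: int | None = None,
) -> AssocFit:
    """Fit one spec by ML; singular/failed designs yield ``converged=False``.

    ``data`` must carry the outcome, ``log_population``, the grouping
    columns the spec references, and (Study 1) ``h`` and ``L`` standardized per
    corpus beforehand.  Population enters as the last fixed-effect column.
    """
    if maxiter is None:
        maxiter = 20 if spec.study == 1 else 100
    y = data[outcome].to_numpy(dtype=float)
    cols = [np.ones(len(data))]
    for term in spec.fixed:
        if term == "h:L":
            cols.append(data["h"].to_numpy() * data["L"].to_numpy())
        else:
            cols.append(data[term].to_numpy(dtype=float))
    if spec.include_population:
        cols.append(data["log_population"].to_numpy(dtype=float))
    X = np.column_stack(cols)
    logpop = data["log_population"].to_numpy(dtype=float)
    comps = []
    for g in spec.intercepts:
        Z, levels = indicator_matrix(data[g])
        comps.append(IIDComponent(name=f"{g}_intercept", Z=Z, levels=levels))
    for g in spec.slopes:
        Z, levels = indicator_matrix(data[g])
        comps.append(IIDComponent(name=f"{g}_slope", Z=Z * logpop[:, None], levels=levels))
    try:
        res = fit_mixed_model(y, X, comps, None, method="ml", maxiter=maxiter)
    except (np.linalg.LinAlgError, ValueError):
        return AssocFit(spec=spec, beta=np.nan, se=np.nan, aic=np.nan, converged=False)
    beta = float(res.beta[-1]) if spec.include_population else np.nan
    se = float(res.se[-1]) if spec.include_population else np.nan
    return AssocFit(spec=spec, beta=beta, se=se, aic=res.aic, converged=res.converged, result=res)


@dataclass
class DeltaAIC:
    delta: float
    full_apt: bool | None  # None when both fits failed


def delta_aic_compare(full: AssocFit, reduced: AssocFit) -> DeltaAIC:
    """AIC_reduced - AIC_full; the full model wins ties only via the
    reduced model failing (equal AICs favor the reduced model)."""
    if not full.converged and not reduced.converged:
        return DeltaAIC(delta=np.nan, full_apt=None)
    if not reduced.converged:
        return DeltaAIC(delta=np.nan, full_apt=True)
    if not full.converged:
        return DeltaAIC(delta=np.nan, full_apt=False)
    delta = reduced.aic - full.aic
    return DeltaAIC(delta=float(delta), full_apt=bool(delta > 0))


@dataclass
class FMAResult:
    beta_fma: float
    weights: np.ndarray
    converged: np.ndarray


def fma_estimate(fits: list[AssocFit]) -> FMAResult:
    """AIC-exponential frequentist model average of the population betas.

    Weights ``w_j = c_j exp(-AIC_j/2) / sum_i c_i exp(-AIC_i/2)`` with the
    binary convergence indicator ``c_j``; AICs are shifted by their minimum
    before exponentiation (the weights are shift invariant).
    """
    c = np.array([1.0 if f.converged and np.isfinite(f.aic) else 0.0 for f in fits])
    if c.sum() == 0:
        raise ValueError("no converged fit to average")
    aic = np.array([f.aic if ci else np.inf for f, ci in zip(fits, c)])
    omega = np.exp(-(aic - aic[np.isfinite(aic)].min()) / 2.0) * c
    omega = omega / omega.sum()
    beta = np.array([f.beta for f in fits])
    return FMAResult(
        beta_fma=float(np.nansum(omega * np.where(omega > 0, beta, 0.0))),
        weights=omega,
        converged=c.astype(bool),
    )


# ---------------------------------------------------------------------------
# candidate sets + double selection + Freedman-Lane


def _bspline_basis(x: np.ndarray, name: str) -> pd.DataFrame:
    """Cubic B-spline basis with interior knots at the 25/50/75 percentiles
    (7 columns)."""
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        raise ValueError(f"degenerate coordinate column {name!r}")
    interior = np.percentile(x, [25, 50, 75])
    t = np.r_[[lo] * 4, interior, [hi] * 4]
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, 3, extrapolate=False).toarray()
    return pd.DataFrame(B, columns=[f"{name}_bs{i + 1}" for i in range(B.shape[1])])


def build_candidate_set(metadata: pd.DataFrame, tier: str = "small") -> pd.DataFrame:
    """Control-variable candidates for double selection.

    small  = level indicators (corpus/family/script/macro area/EGIDS, those
             present) + cubic B-spline bases for latitude and longitude +
             continuous covariates (logged where positive-valued);
    medium = small + pairwise products of the two coordinate bases;
    big    = medium + pairwise products of the level indicators.
    Constant columns are dropped with a warning.
    """
    if tier not in {"small", "medium", "big"}:
        raise ValueError(f"unknown tier {tier!r}")
    n = len(metadata)
    indicator_blocks: list[pd.DataFrame] = []
    for factor in ("corpus", "family", "script", "macro_area", "egids"):
        if factor not in metadata.columns:
            continue
        dummies = pd.get_dummies(metadata[factor].astype(str), prefix=factor, dtype=float)
        indicator_blocks.append(dummies.reset_index(drop=True))
    def _basis_or_empty(col: str, name: str) -> pd.DataFrame:
        try:
            return _bspline_basis(metadata[col].to_numpy(dtype=float), name)
        except ValueError:
            logger.warning("degenerate %s basis dropped (constant coordinates)", name)
            return pd.DataFrame(index=range(n))

    lat = _basis_or_empty("latitude", "lat")
    lon = _basis_or_empty("longitude", "lon")
    continuous = {}
    for col in ("h", "L", "range_size", "distance_to_water", "altitude", "n_countries"):
        if col in metadata.columns:
            continuous[f"log_{col}"] = np.log(metadata[col].to_numpy(dtype=float))
    for col in ("climate_pc1", "climate_pc2"):
        if col in metadata.columns:
            continuous[col] = metadata[col].to_numpy(dtype=float)
    blocks = indicator_blocks + [lat, lon, pd.DataFrame(continuous).reset_index(drop=True)]
    if tier in {"medium", "big"}:
        prod = {
            f"{a}_x_{b}": lat[a].to_numpy() * lon[b].to_numpy()
            for a in lat.columns
            for b in lon.columns
        }
        blocks.append(pd.DataFrame(prod))
    if tier == "big":
        inter = {}
        for i, bi in enumerate(indicator_blocks):
            for bj in indicator_blocks[i + 1 :]:
                for a in bi.columns:
                    for b in bj.columns:
                        inter[f"{a}_x_{b}"] = bi[a].to_numpy() * bj[b].to_numpy()
        blocks.append(pd.DataFrame(inter))
    out = pd.concat([b.set_index(metadata.index) for b in blocks], axis=1)
    constant = out.columns[out.std(axis=0) == 0]
    if len(constant):
        logger.warning("dropping %d constant candidate columns", len(constant))
        out = out.drop(columns=constant)
    return out


@dataclass
class DSFit:
    beta_ds: float
    se: float
    selected: list[str]
    tier: str
    n_candidates: int


def double_selection(
    outcome: np.ndarray,
    exposure: np.ndarray,
    candidates: pd.DataFrame,
    cluster_ids=None,
    tier: str = "",
    seed: int = 0,
    cv_folds: int = 10,
) -> DSFit:
    """Post-double-selection estimate of the exposure coefficient.

    Two lassos (penalty by ``cv_folds``-fold cross-validation, seeded fold
    split) select controls for the exposure and the outcome; the final OLS
    regresses the outcome on the exposure plus the union of selections,
    with standard errors clustered on ``cluster_ids`` when given.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(exposure, float)
    if len(y) == 0:
        raise ValueError("empty data")
    names = list(candidates.columns)
    selected: list[str] = []
    if names:
        C = candidates.to_numpy(dtype=float)
        C = (C - C.mean(0)) / np.where(C.std(0) > 0, C.std(0), 1.0)
        cv = KFold(n_splits=min(cv_folds, len(y)), shuffle=True, random_state=seed)
        union: set[str] = set()
        for target in (x, y):
            lasso = LassoCV(cv=cv, random_state=seed, alphas=50, max_iter=5000)
            lasso.fit(C, target)
            union.update(np.array(names)[np.abs(lasso.coef_) > 1e-10].tolist())
        selected = sorted(union)
    X = sm.add_constant(
        np.column_stack([x] + [candidates[c].to_numpy(dtype=float) for c in selected])
        if selected
        else x
    )
    model = sm.OLS(y, X)
    groups = np.asarray(cluster_ids) if cluster_ids is not None else None
    if groups is not None and len(np.unique(groups)) < len(groups):
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    else:
        # all-singleton clusters degenerate; heteroskedasticity-robust instead
        fit = model.fit(cov_type="HC1")
    return DSFit(
        beta_ds=float(fit.params[1]),
        se=float(fit.bse[1]),
        selected=selected,
        tier=tier,
        n_candidates=len(names),
    )


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p: float
    n_perm: int


def freedman_lane_test(
    outcome: np.ndarray,
    exposure: np.ndarray,
    controls: pd.DataFrame | np.ndarray | None,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the exposure coefficient, residuals permuted
    under the reduced (controls-only) model.

    Steps: t of the exposure in the full regression; fitted values and
    residuals of the reduced regression; per permutation the outcome is
    rebuilt as fitted + permuted residuals, the full model refitted and the
    t recorded; p compares |t*| with |t_obs|.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is very small for a permutation test", n_perm)
    y = np.asarray(outcome, float)
    x = np.asarray(exposure, float)
    n = len(y)
    Cmat = None
    if controls is not None:
        Cmat = np.asarray(controls, float)
        if Cmat.ndim == 1:
            Cmat = Cmat[:, None]
        if Cmat.shape[1] == 0:
            Cmat = None
    X_full = np.column_stack([np.ones(n), x] + ([Cmat] if Cmat is not None else []))
    X_red = np.column_stack([np.ones(n)] + ([Cmat] if Cmat is not None else []))
    p_full = X_full.shape[1]

    XtX_inv = np.linalg.pinv(X_full.T @ X_full)
    H = XtX_inv @ X_full.T
    beta_obs = H @ y
    resid_obs = y - X_full @ beta_obs
    dof = n - p_full
    sigma2 = resid_obs @ resid_obs / dof
    t_obs = beta_obs[1] / np.sqrt(sigma2 * XtX_inv[1, 1])

    beta_red, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    fitted = X_red @ beta_red
    resid = y - fitted

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
    Ystar = fitted[:, None] + resid[perms]  # n x n_perm
    B = H @ Ystar  # p x n_perm
    R = Ystar - X_full @ B
    rss = np.clip(np.einsum("ij,ij->j", R, R), 0.0, None)
    se = np.sqrt(rss / dof * max(XtX_inv[1, 1], 0.0))
    tstar = B[1] / se
    count = int(np.sum(np.abs(tstar) >= np.abs(t_obs)))
    return PermutationResult(
        observed=float(t_obs),
        permuted=tstar,
        p=max(count, 1) / n_perm,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# PGLS


@dataclass
class PGLSFit:
    beta_pgls: float
    se: float
    loglik: float
    aic: float
    delta_aic: float
    r2: float


def _gls(y: np.ndarray, X: np.ndarray, L: np.ndarray):
    """GLS via the Cholesky factor L of the (unit-rate) covariance."""
    yt = np.linalg.solve(L, y)
    Xt = np.linalg.solve(L, X)
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n  # ML scale
    logdet = 2.0 * np.log(np.diag(L)).sum()
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    cov = sigma2 * n / (n - X.shape[1]) * np.linalg.inv(Xt.T @ Xt)
    return beta, cov, loglik, sigma2


def fit_pgls(
    difficulty: pd.Series, log_population: pd.Series, tree: dendropy.Tree
) -> PGLSFit:
    """GLS with Brownian-motion covariance from the language phylogeny.

    The covariance between two languages is the shared branch length from
    the root to their most recent common ancestor; on a star phylogeny this
    is diagonal and the estimate equals OLS.  AIC is compared against the
    intercept-only refit; R^2 is the squared Pearson correlation between
    observed and predicted difficulty.
    """
    from glottolearn.synthetic_world import brownian_covariance

    languages = list(difficulty.index)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(languages) - tips)
    if missing:
        raise ValueError(f"languages missing from tree: {missing}")
    C = brownian_covariance(tree).loc[languages, languages].to_numpy()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(languages)))
    y = difficulty.to_numpy(dtype=float)
    x = log_population.loc[languages].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), x])
    beta, cov, loglik, _ = _gls(y, X, L)
    aic = 2 * (X.shape[1] + 1) - 2 * loglik
    X0 = np.ones((len(y), 1))
    _, _, loglik0, _ = _gls(y, X0, L)
    aic0 = 2 * 2 - 2 * loglik0
    pred = X @ beta
    r = np.corrcoef(y, pred)[0, 1] if np.std(pred) > 0 else 0.0
    return PGLSFit(
        beta_pgls=float(beta[1]),
        se=float(np.sqrt(cov[1, 1])),
        loglik=float(loglik),
        aic=float(aic),
        delta_aic=float(aic0 - aic),
        r2=float(r**2),
    )


# ---------------------------------------------------------------------------
# geography + SAR


def haversine_matrix(
    latitude: np.ndarray, longitude: np.ndarray, labels: list[str] | None = None
) -> pd.DataFrame:
    """Great-circle distance matrix in kilometres (Earth radius 6371 km)."""
    lat = np.asarray(latitude, float)
    lon = np.asarray(longitude, float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    if labels is None:
        labels = [str(i) for i in range(len(lat))]
    return pd.DataFrame(d, index=labels, columns=labels)


def inverse_distance_weights(distance: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Row-standardized elementwise inverse-distance weights.

    Zero off-diagonal distances (co-located languages) are replaced by the
    smallest positive distance before inversion; the diagonal stays zero.
    """
    d = np.asarray(distance, float).copy()
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    pos = d[off][d[off] > 0]
    if pos.size == 0:
        raise ValueError("all off-diagonal distances are zero")
    d[off & (d == 0)] = pos.min()
    W = np.zeros_like(d)
    W[off] = 1.0 / d[off]
    W = W / W.sum(axis=1, keepdims=True)
    return W


@dataclass
class SARFit:
    beta_sar: float
    se: float
    z: float
    lambda1: float
    lambda2: float
    r2: float


class _KPMoments:
    """Quadratic-moment machinery for the two-matrix SAR error model.

    With OLS residuals ``u`` and ``e(lam) = u - lam1 W1 u - lam2 W2 u``,
    each moment quadratic ``e' Q e`` is a bivariate quadratic in
    ``(lam1, lam2)`` whose six coefficients are precomputed from ``u``, so
    the grid search costs only polynomial evaluations.  Vectorized over
    columns of ``u`` (one column per permutation draw).
    """

    def __init__(self, W1: np.ndarray, W2: np.ndarray):
        self.W1, self.W2 = W1, W2
        self.Qs = [np.eye(W1.shape[0]), W1.T @ W1, W1, W2.T @ W2, W2, W1.T @ W2]
        self.traces = np.array([np.trace(Q) for Q in self.Qs])

    def coefficients(self, U: np.ndarray) -> np.ndarray:
        """(6 moments, 6 poly coefs, m columns) coefficient tensor."""
        A = self.W1 @ U
        B = self.W2 @ U
        coefs = np.empty((len(self.Qs), 6, U.shape[1]))
        for m, Q in enumerate(self.Qs):
            QU, QA, QB = Q @ U, Q @ A, Q @ B
            dot = lambda P, R: np.einsum("ij,ij->j", P, R)
            coefs[m, 0] = dot(U, QU)
            coefs[m, 1] = -(dot(U, QA) + dot(A, QU))
            coefs[m, 2] = -(dot(U, QB) + dot(B, QU))
            coefs[m, 3] = dot(A, QA)
            coefs[m, 4] = dot(A, QB) + dot(B, QA)
            coefs[m, 5] = dot(B, QB)
        return coefs

    def estimate(self, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid-zoom minimizer of the moment objective; (lam1, lam2) per column."""
        coefs = self.coefficients(U)
        t = self.traces
        tt = float(t @ t)
        c1 = np.full(U.shape[1], 0.0)
        c2 = np.full(U.shape[1], 0.0)
        half = 0.95
        for _ in range(3):
            g = np.linspace(-half, half, 21)
            l1 = np.clip(c1[None, :] + g[:, None], -0.98, 0.98)  # 21 x m
            l2 = np.clip(c2[None, :] + g[:, None], -0.98, 0.98)
            # evaluate on the 21x21 grid: shape (21, 21, m)
            L1 = l1[:, None, :]
            L2 = l2[None, :, :]
            q = (
                coefs[:, 0, None, None, :]
                + coefs[:, 1, None, None, :] * L1
                + coefs[:, 2, None, None, :] * L2
                + coefs[:, 3, None, None, :] * L1**2
                + coefs[:, 4, None, None, :] * L1 * L2
                + coefs[:, 5, None, None, :] * L2**2
            )  # (6, 21, 21, m)
            sigma2 = np.einsum("m,mabc->abc", t, q) / tt
            obj = ((q - t[:, None, None, None] * sigma2[None]) ** 2).sum(axis=0)
            flat = obj.reshape(-1, obj.shape[-1])
            best = np.argmin(flat, axis=0)
            i1, i2 = np.unravel_index(best, obj.shape[:2])
            cols = np.arange(obj.shape[-1])
            c1 = l1[i1, cols]
            c2 = l2[i2, cols]
            half = half / 10.0
        return c1, c2


def _fgls(y: np.ndarray, X: np.ndarray, A: np.ndarray):
    """Feasible GLS given the whitening matrix A = I - lam1 W1 - lam2 W2."""
    yt = A @ y
    Xt = A @ X
    XtX = Xt.T @ Xt
    beta = np.linalg.solve(XtX, Xt.T @ yt)
    resid = yt - Xt @ beta
    n, p = X.shape
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(XtX)
    return beta, cov


def fit_sar(
    difficulty: np.ndarray,
    log_population: np.ndarray,
    W_geo: np.ndarray,
    W_phylo: np.ndarray,
    n_fgls_iter: int = 2,
) -> SARFit:
    """SAR error model ``u = lam1 W1 u + lam2 W2 u + eps``.

    The two dependence parameters are estimated by quadratic-moment
    matching on residuals; the regression coefficient by feasible GLS on
    the whitened system, iterated ``n_fgls_iter`` times.  R^2 is the
    squared correlation of observed and (trend-)predicted difficulty.
    """
    y = np.asarray(difficulty, float)
    x = np.asarray(log_population, float)
    W1 = np.asarray(W_geo, float)
    W2 = np.asarray(W_phylo, float)
    if W1.shape != (len(y), len(y)) or W2.shape != (len(y), len(y)):
        raise ValueError("weight matrices not aligned with the language set")
    X = np.column_stack([np.ones(len(y)), x])
    kp = _KPMoments(W1, W2)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    l1 = l2 = 0.0
    for _ in range(n_fgls_iter):
        u = (y - X @ beta)[:, None]
        l1a, l2a = kp.estimate(u)
        l1, l2 = float(l1a[0]), float(l2a[0])
        A = np.eye(len(y)) - l1 * W1 - l2 * W2
        beta, cov = _fgls(y, X, A)
    pred = X @ beta
    r = np.corrcoef(y, pred)[0, 1] if np.std(pred) > 0 else 0.0
    se = float(np.sqrt(cov[1, 1]))
    return SARFit(
        beta_sar=float(beta[1]),
        se=se,
        z=float(beta[1] / se),
        lambda1=l1,
        lambda2=l2,
        r2=float(r**2),
    )


def sar_permutation_test(
    difficulty: np.ndarray,
    log_population: np.ndarray,
    W_geo: np.ndarray,
    W_phylo: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Permute the exposure, refit the SAR model, compare |z*| with |z_obs|.

    Permutation refits are batched: one OLS, one moment estimation and one
    feasible GLS per draw, all vectorized over draws.
    """
    y = np.asarray(difficulty, float)
    x = np.asarray(log_population, float)
    n = len(y)
    W1 = np.asarray(W_geo, float)
    W2 = np.asarray(W_phylo, float)
    obs = fit_sar(y, x, W1, W2)
    rng = np.random.default_rng(seed)
    Xp = np.stack([x[rng.permutation(n)] for _ in range(n_perm)], axis=1)  # n x m

    # batched OLS residuals of y on [1, x_perm]
    xc = Xp - Xp.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    slope = (xc * yc[:, None]).sum(0) / (xc * xc).sum(0)
    U = yc[:, None] - xc * slope[None, :]

    kp = _KPMoments(W1, W2)
    l1, l2 = kp.estimate(U)
    zstar = np.empty(n_perm)
    I = np.eye(n)
    for j in range(n_perm):
        A = I - l1[j] * W1 - l2[j] * W2
        Xj = np.column_stack([np.ones(n), Xp[:, j]])
        beta, cov = _fgls(y, Xj, A)
        zstar[j] = beta[1] / np.sqrt(cov[1, 1])
    count = int(np.sum(np.abs(zstar) >= np.abs(obs.z)))
    return PermutationResult(
        observed=float(obs.z), permuted=zstar, p=max(count, 1) / n_perm, n_perm=n_perm
    )
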