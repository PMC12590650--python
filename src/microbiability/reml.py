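"""Restricted maximum likelihood for kernel-defined variance components.

Fits linear mixed models of the form

    y = X beta + sum_k u_k + e,    u_k ~ N(0, sigma2_k K_k),  e ~ N(0, sigma2_e I)

where each ``K_k`` is an n x n relationship kernel (genomic G or
microbiome M/M1/M2).  The variance ratios are reported as heritability
h2 = sigma2_A / sigma2_total when the kernel is genomic, and
microbiability m2 = sigma2_b / sigma2_total when it is microbial.

Algorithm: average-information (AI) REML with three expectation-
maximization warm-up steps, step-halving whenever an AI step would
decrease the restricted likelihood or push a component negative, and
clamping of components at a small positive floor (constrained REML).
Standard errors come from the inverse AI matrix; ratio standard errors
use the delta method.  Single-kernel models are solved in the kernel's
eigenbasis, where the covariance matrix is diagonal and every iteration
costs O(n p^2) instead of O(n^3); the two code paths maximize the same
restricted likelihood and agree to numerical precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import (
    AlignmentError,
    DegenerateFitError,
    DesignError,
    NonIdentifiableError,
    ParameterError,
)
from .kernels import Kernel

logger = logging.getLogger(__name__)

_MICROBIAL_KINDS = ("M", "M1", "M2")


@dataclass
class ModelSpec:
    """A phenotype, a fixed-effect design and 0-2 kernels, ready to fit."""

    y: np.ndarray
    fixed: np.ndarray
    kernels: list
    trait_name: str = ""
    fixed_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        n = self.y.shape[0]
        if self.fixed.shape[0] != n:
            raise AlignmentError("fixed design rows do not match phenotype length")
        if np.isnan(self.y).any() or np.isnan(self.fixed).any():
            raise ParameterError("missing values must be removed before fitting")
        for k in self.kernels:
            if k.n != n:
                raise AlignmentError("kernel size does not match phenotype length")
        sv = np.linalg.svd(self.fixed, compute_uv=False)
        if sv[-1] < 1e-10 * sv[0]:
            raise DesignError("fixed-effect design matrix is singular")
        if n <= self.fixed.shape[1] + len(self.kernels):
            raise ParameterError("too few observations for the model dimension")


@dataclass
class VCFit:
    """Result of one REML fit.

    ``variance_components`` holds one sigma^2 per kernel followed by the
    residual sigma^2_e (trait units squared).  ``ratios`` are each kernel's
    share of the total variance; their complement to 1 is the residual
    share.
    """

    variance_components: np.ndarray
    kernel_kinds: list
    ratios: np.ndarray
    se_components: np.ndarray
    se_ratios: np.ndarray
    loglik_restricted: float
    converged: bool
    n_iter: int
    boundary_flags: np.ndarray
    n_used: int
    n_fixed: int
    trait_name: str = ""
    loglik_path: list = field(default_factory=list)

    @property
    def n_kernels(self) -> int:
        return len(self.kernel_kinds)

    def _ratio_for(self, kinds) -> float | None:
        for i, kind in enumerate(self.kernel_kinds):
            if kind in kinds:
                return i
        return None

    @property
    def h2(self) -> float | None:
        i = self._ratio_for(("G",))
        return None if i is None else float(self.ratios[i])

    @property
    def m2(self) -> float | None:
        i = self._ratio_for(_MICROBIAL_KINDS)
        return None if i is None else float(self.ratios[i])

    @property
    def se_h2(self) -> float | None:
        i = self._ratio_for(("G",))
        return None if i is None else float(self.se_ratios[i])

    @property
    def se_m2(self) -> float | None:
        i = self._ratio_for(_MICROBIAL_KINDS)
        return None if i is None else float(self.se_ratios[i])


# ---------------------------------------------------------------------------
# likelihood cores


class _DenseCore:
    """Restricted likelihood, score and AI matrix with explicit n x n algebra."""

    def __init__(self, y, X, Ks):
        self.y = y
        self.X = X
        self.Ks = Ks
        self.n, self.p = X.shape
        self._eye = np.eye(self.n)

    def evaluate(self, theta):
        n = self.n
        V = theta[-1] * self._eye
        for th, K in zip(theta[:-1], self.Ks):
            V = V + th * K
        try:
            cf = sla.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            V = V + (1e-10 * np.mean(np.diag(V))) * self._eye
            cf = sla.cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vi = sla.cho_solve(cf, self._eye, check_finite=False)
        ViX = Vi @ self.X
        XtViX = self.X.T @ ViX
        cf2 = sla.cho_factor(XtViX, lower=True, check_finite=False)
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cf2[0]))))
        W = sla.cho_solve(cf2, ViX.T, check_finite=False)
        P = Vi - ViX @ W
        Py = P @ self.y
        yPy = float(self.y @ Py)
        ll = -0.5 * (logdet_v + logdet_x + yPy)

        n_comp = len(theta)
        score = np.empty(n_comp)
        T = np.empty((n, n_comp))
        for i, K in enumerate(self.Ks):
            tr = float(np.sum(P * K))  # tr(P K), both symmetric
            t = K @ Py
            score[i] = -0.5 * (tr - float(Py @ t))
            T[:, i] = t
        tr_e = float(np.trace(P))
        score[-1] = -0.5 * (tr_e - float(Py @ Py))
        T[:, -1] = Py
        PT = P @ T
        AI = 0.5 * (T.T @ PT)
        return ll, score, AI


class _DiagCore:
    """Single-kernel core in the kernel eigenbasis (diagonal covariance)."""

    def __init__(self, y_rot, X_rot, eigvals):
        self.d = np.maximum(eigvals, 0.0)
        self.y = y_rot
        self.X = X_rot
        self.n, self.p = self.X.shape

    def _p_dot(self, z):
        return self._vi * z - self._ViX @ sla.cho_solve(
            self._cf2, self._ViX.T @ z, check_finite=False
        )

    def evaluate(self, theta):
        v = theta[0] * self.d + theta[1]
        self._vi = 1.0 / v
        logdet_v = float(np.sum(np.log(v)))
        self._ViX = self.X * self._vi[:, None]
        XtViX = self.X.T @ self._ViX
        self._cf2 = sla.cho_factor(XtViX, lower=True, check_finite=False)
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(self._cf2[0]))))
        Py = self._p_dot(self.y)
        yPy = float(self.y @ Py)
        ll = -0.5 * (logdet_v + logdet_x + yPy)

        score = np.empty(2)
        T = np.empty((self.n, 2))
        for i, diag in enumerate((self.d, np.ones(self.n))):
            inner = sla.cho_solve(
                self._cf2, self._ViX.T @ (diag[:, None] * self._ViX),
                check_finite=False,
            )
            tr = float(np.sum(diag * self._vi)) - float(np.trace(inner))
            t = diag * Py
            score[i] = -0.5 * (tr - float(Py @ t))
            T[:, i] = t
        PT = np.column_stack([self._p_dot(T[:, 0]), self._p_dot(T[:, 1])])
        AI = 0.5 * (T.T @ PT)
        return ll, score, AI


def _restricted_loglik_null(y, X):
    """Closed-form restricted log-likelihood with residual variance only.

    Uses the same constant conventions as the iterative cores, so log-
    likelihoods are directly comparable across nested models.
    """
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        raise DegenerateFitError("zero residual variance in the null model")
    sigma2 = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        raise DesignError("singular fixed-effect design")
    ll = -0.5 * ((n - p) * np.log(sigma2) + logdet_xx + (n - p))
    return ll, sigma2


# ---------------------------------------------------------------------------
# optimization loop

_N_EM_STEPS = 3
_MAX_HALVINGS = 20
_AI_COND_MAX = 1e10


def _reml_loop(core, spec, tol_loglik, tol_param, max_iter):
    y = spec.y
    n = y.shape[0]
    n_k = len(spec.kernels)
    n_comp = n_k + 1
    var_y = float(np.var(y, ddof=1))
    if var_y <= 0:
        raise DegenerateFitError("phenotype is constant")
    floor = 1e-8 * var_y

    beta, _, _, _ = np.linalg.lstsq(spec.fixed, y, rcond=None)
    resid = y - spec.fixed @ beta
    sigma2_ols = float(resid @ resid) / (n - spec.fixed.shape[1])
    theta = np.full(n_comp, max(sigma2_ols / n_comp, floor))

    ll, score, AI = core.evaluate(theta)
    ll_path = [ll]
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        if it <= _N_EM_STEPS:
            # EM update: theta_i += theta_i^2 * (y'PKPy - tr(PK)) / n
            new_theta = np.maximum(theta + theta**2 * (2.0 * score) / n, floor)
            new_ll, new_score, new_AI = core.evaluate(new_theta)
        else:
            pinned = (theta <= floor * 1.0001) & (score < 0)
            free = ~pinned
            if not free.any():
                converged = True
                break
            AI_ff = AI[np.ix_(free, free)]
            if np.linalg.cond(AI_ff) > _AI_COND_MAX:
                raise NonIdentifiableError(
                    "average-information matrix is singular; the variance "
                    "components are not separately identifiable"
                )
            delta = np.zeros(n_comp)
            delta[free] = np.linalg.solve(AI_ff, score[free])
            accepted = False
            for _ in range(_MAX_HALVINGS):
                cand = np.maximum(theta + delta, floor)
                cand_ll, cand_score, cand_AI = core.evaluate(cand)
                if cand_ll >= ll - 1e-12:
                    new_theta, new_ll = cand, cand_ll
                    new_score, new_AI = cand_score, cand_AI
                    accepted = True
                    break
                delta *= 0.5
            if not accepted:  # EM fallback step (monotone)
                new_theta = np.maximum(theta + theta**2 * (2.0 * score) / n, floor)
                new_ll, new_score, new_AI = core.evaluate(new_theta)

        d_ll = new_ll - ll
        d_par = float(np.max(np.abs(new_theta - theta) / (np.abs(theta) + tol_param)))
        theta, ll, score, AI = new_theta, new_ll, new_score, new_AI
        ll_path.append(ll)
        if it > _N_EM_STEPS and abs(d_ll) < tol_loglik and d_par < tol_param:
            converged = True
            break

    boundary = theta <= floor * 2.0
    # constrained-REML convention: components clamped at the floor are
    # reported as exact zeros (the "0.00" entries of variance tables)
    theta = np.where(boundary, 0.0, theta)
    # SEs from the (pseudo-)inverse AI at the optimum; boundary components
    # make AI ill-conditioned, in which case the SEs are flagged via
    # boundary_flags rather than suppressed.
    try:
        C = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        C = np.linalg.pinv(AI)
    se_comp = np.sqrt(np.maximum(np.diag(C), 0.0))

    total = float(theta.sum())
    if total == 0.0:  # all components on the boundary (no residual variance)
        total = 1.0
    ratios = theta[:-1] / total
    J = (np.eye(n_comp) * total - theta[:, None]) / total**2  # d(theta_i/s)/d theta_j
    cov_r = J @ C @ J.T
    se_r = np.sqrt(np.maximum(np.diag(cov_r), 0.0))[:-1]

    if not converged:
        logger.warning(
            "REML did not converge in %d iterations (trait %s)",
            max_iter, spec.trait_name or "<unnamed>",
        )
    return VCFit(
        variance_components=theta,
        kernel_kinds=[k.kind for k in spec.kernels],
        ratios=ratios,
        se_components=se_comp,
        se_ratios=se_r,
        loglik_restricted=float(ll),
        converged=converged,
        n_iter=n_iter,
        boundary_flags=boundary,
        n_used=n,
        n_fixed=spec.fixed.shape[1],
        trait_name=spec.trait_name,
        loglik_path=ll_path,
    )


# ---------------------------------------------------------------------------
# public fitting API


def reml_fit(
    spec: ModelSpec,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
    max_iter: int = 200,
) -> VCFit:
    """Maximize the restricted likelihood over non-negative variance components.

    With no kernels the fit is the closed-form residual-only model (used as
    the null in likelihood-ratio tests).  One kernel uses the spectral
    (eigenbasis) path; two kernels use dense matrix algebra.
    """
    if not spec.kernels:
        ll, sigma2 = _restricted_loglik_null(spec.y, spec.fixed)
        n, p = spec.fixed.shape
        se = sigma2 * np.sqrt(2.0 / (n - p))
        return VCFit(
            variance_components=np.array([sigma2]),
            kernel_kinds=[],
            ratios=np.array([]),
            se_components=np.array([se]),
            se_ratios=np.array([]),
            loglik_restricted=float(ll),
            converged=True,
            n_iter=0,
            boundary_flags=np.array([False]),
            n_used=n,
            n_fixed=p,
            trait_name=spec.trait_name,
            loglik_path=[float(ll)],
        )
    if len(spec.kernels) == 1:
        eigvals, eigvecs = np.linalg.eigh(spec.kernels[0].K)
        core = _DiagCore(eigvecs.T @ spec.y, eigvecs.T @ spec.fixed, eigvals)
    else:
        core = _DenseCore(spec.y, spec.fixed, [k.K for k in spec.kernels])
    return _reml_loop(core, spec, tol_loglik, tol_param, max_iter)


class SingleKernelREML:
    """Repeated single-kernel REML fits sharing one eigendecomposition.

    Screening hundreds of taxa against the same genomic kernel and fixed
    effects only changes the response vector, so the O(n^3)
    eigendecomposition and design rotation are done once here and each
    :meth:`fit` costs O(n p^2) per iteration.
    """

    def __init__(self, kernel: Kernel, X, tol_loglik=1e-8, tol_param=1e-6,
                 max_iter=200):
        self.kernel = kernel
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param
        self.max_iter = max_iter
        self.eigvals, self._U = np.linalg.eigh(kernel.K)
        self._X_rot = self._U.T @ self.X

    def fit(self, y, trait_name: str = "") -> VCFit:
        spec = ModelSpec(
            y=y, fixed=self.X, kernels=[self.kernel], trait_name=trait_name
        )
        core = _DiagCore(self._U.T @ spec.y, self._X_rot, self.eigvals)
        return _reml_loop(core, spec, self.tol_loglik, self.tol_param, self.max_iter)

    def fit_null(self, y, trait_name: str = "") -> VCFit:
        spec = ModelSpec(y=y, fixed=self.X, kernels=[], trait_name=trait_name)
        return reml_fit(spec)


class VarianceComponentModel(BaseEstimator):
    """Kernel variance-component mixed model (GREML), sklearn-style.

    Parameters
    ----------
    kernels : list of Kernel
        One or two relationship kernels; their sample order must match the
        rows of ``X`` and ``y`` passed to :meth:`fit`.
    tol_loglik, tol_param : float
        Convergence tolerances on the restricted log-likelihood change and
        the relative parameter change.
    max_iter : int
        Iteration cap; non-convergence is reported, not raised.

    Attributes
    ----------
    variance_components_ : ndarray, (n_kernels + 1,)
        Estimated sigma^2 per kernel plus residual.
    ratios_ : ndarray, (n_kernels,)
        Variance ratios (h2 for a genomic kernel, m2 for a microbial one).
    se_ratios_, se_components_ : ndarray
        Delta-method / inverse-AI standard errors.
    loglik_ : float
        Restricted log-likelihood at the optimum (additive constants omitted).
    converged_ : bool
    n_iter_ : int
    boundary_ : ndarray of bool
        True where a component was clamped at the zero boundary.
    fit_ : VCFit
        The full fit record.
    """

    def __init__(self, kernels=None, tol_loglik=1e-8, tol_param=1e-6, max_iter=200):
        self.kernels = kernels
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param
        self.max_iter = max_iter

    def fit(self, X, y, trait_name: str = ""):
        kernels = list(self.kernels) if self.kernels else []
        spec = ModelSpec(y=y, fixed=X, kernels=kernels, trait_name=trait_name)
        result = reml_fit(
            spec,
            tol_loglik=self.tol_loglik,
            tol_param=self.tol_param,
            max_iter=self.max_iter,
        )
        self.fit_ = result
        self.variance_components_ = result.variance_components
        self.ratios_ = result.ratios
        self.se_components_ = result.se_components
        self.se_ratios_ = result.se_ratios
        self.loglik_ = result.loglik_restricted
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.boundary_ = result.boundary_flags
        return self


# ---------------------------------------------------------------------------
# covariate plumbing and trait-level wrappers


def build_fixed_design(
    covariates: pd.DataFrame,
    breed_col: str | None = "breed",
    age_col: str | None = "age_months",
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Intercept + reference-coded breed + age (+ optional genetic PCs)."""
    n = covariates.shape[0]
    parts = [pd.Series(np.ones(n), index=covariates.index, name="intercept")]
    if breed_col is not None and breed_col in covariates:
        dummies = pd.get_dummies(
            covariates[breed_col].astype("category"), prefix=breed_col, drop_first=True
        ).astype(float)
        parts.append(dummies)
    if age_col is not None and age_col in covariates:
        parts.append(covariates[age_col].astype(float))
    design = pd.concat(parts, axis=1)
    if pcs is not None:
        design = pd.concat([design, pcs.loc[design.index]], axis=1)
    return design


def _align(y: pd.Series, covariates: pd.DataFrame, kernels: list, pcs=None):
    """Listwise-delete missing rows, align everything to the kernel ids."""
    ids = [str(s) for s in y.index]
    for k in kernels:
        missing = set(ids) - set(k.ids)
        if missing:
            raise AlignmentError(
                f"samples absent from {k.kind} kernel: {sorted(missing)[:5]}"
            )
    frame = pd.DataFrame({"y": y.astype(float)})
    frame = frame.join(covariates, how="inner")
    if pcs is not None:
        frame = frame.join(pcs, how="inner")
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        logger.info("dropped %d samples with missing phenotype/covariates", n_dropped)
    if complete.empty:
        raise AlignmentError("no complete cases after alignment")
    keep_ids = [str(s) for s in complete.index]
    aligned_kernels = [k.reorder(keep_ids) for k in kernels]
    cov_cols = [c for c in complete.columns if c != "y"]
    return complete["y"], complete[cov_cols], aligned_kernels


def fit_trait_h2_m2(
    y: pd.Series,
    covariates: pd.DataFrame,
    G: Kernel,
    M: Kernel,
    trait_name: str = "",
    **reml_kwargs,
) -> VCFit:
    """Joint G + M fit: h2 and total m2 of a trait, breed and age as fixed effects."""
    yy, cov, (Ga, Ma) = _align(y, covariates, [G, M])
    X = build_fixed_design(cov)
    spec = ModelSpec(
        y=yy.to_numpy(), fixed=X.to_numpy(), kernels=[Ga, Ma],
        trait_name=trait_name or str(y.name or ""),
        fixed_names=list(X.columns),
    )
    return reml_fit(spec, **reml_kwargs)


def fit_microbiota_only_m2(
    y: pd.Series,
    covariates: pd.DataFrame,
    M: Kernel,
    trait_name: str = "",
    **reml_kwargs,
) -> VCFit:
    """Single microbial-kernel fit: m2 of a trait with breed and age fixed effects.

    Partitioned microbiability fits (M1 for heritable taxa, M2 for
    non-heritable taxa) are run separately through this function, never as
    a joint three-component model.
    """
    yy, cov, (Ma,) = _align(y, covariates, [M])
    X = build_fixed_design(cov)
    spec = ModelSpec(
        y=yy.to_numpy(), fixed=X.to_numpy(), kernels=[Ma],
        trait_name=trait_name or str(y.name or ""),
        fixed_names=list(X.columns),
    )
    return reml_fit(spec, **reml_kwargs)


def lrt_pvalue(full: VCFit, null: VCFit) -> float:
    """Boundary-corrected likelihood-ratio p-value for one variance component.

    The null distribution is the 50:50 mixture of a point mass at zero and
    chi-square with 1 df, because the tested component sits on the boundary
    of the parameter space: p = 0.5 * Pr(chi2_1 >= LR).
    """
    if full.n_kernels != null.n_kernels + 1:
        raise ParameterError("null model must drop exactly one kernel")
    if full.n_used != null.n_used or full.n_fixed != null.n_fixed:
        raise ParameterError("full and null fits use different data")
    lr = max(0.0, 2.0 * (full.loglik_restricted - null.loglik_restricted))
    return float(0.5 * stats.chi2.sf(lr, df=1))
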