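"""Linear-model causal mediation with nonparametric bootstrap.

For each genus-SCFA-trait triplet the exposure x (CLR genus abundance,
standardized to unit variance so effects are per-SD), mediator m and
outcome y enter two least-squares models, both adjusted for age:

    mediator model:  m = alpha0 + a x + alpha_age age + error
    outcome model:   y = beta0 + c' x + b m + beta_age age + error

Point estimates follow the product-of-coefficients identity for linear
models: ACME = a*b (average causal mediation effect), ADE = c' (average
direct effect), total = a*b + c'.  Uncertainty comes from a
nonparametric bootstrap (resampling rows with replacement, refitting
both models), with percentile 95% confidence intervals and two-sided
bootstrap p-values 2*min(#{boot <= 0}, #{boot >= 0})/n_boot floored at
2/n_boot.

Candidate genera are pre-filtered by Spearman correlation against the
traits (retained iff P < alpha for at least one trait), and triplets are
the full genus x mediator x trait Cartesian product.  No multiple-
testing correction is applied across triplets (raw P < alpha).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import (
    AlignmentError,
    ConfigurationError,
    DegenerateFitError,
    ParameterError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TripletSpec:
    """One exposure-mediator-outcome combination."""

    genus_id: str
    mediator_id: str
    trait_id: str


@dataclass
class MediationResult:
    """ACME/ADE decomposition for one triplet with bootstrap uncertainty."""

    triplet: TripletSpec
    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci_acme: tuple
    ci_ade: tuple
    ci_total: tuple
    p_acme: float
    p_ade: float
    n_boot: int
    n_used: int
    seed: int | None
    a_path: float
    b_path: float


def spearman_prefilter(
    genus_clr: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Retain genera Spearman-associated with at least one trait (P < alpha).

    Returns (retained genus ids, rho matrix, p matrix), both matrices
    genera x traits.  Constant genus or trait vectors yield undefined
    correlations which count as non-significant.
    """
    if genus_clr.shape[0] != traits.shape[0]:
        raise AlignmentError("genus and trait tables have different sample counts")
    if not (genus_clr.index == traits.index).all():
        raise AlignmentError("genus and trait tables are not sample-aligned")
    n = genus_clr.shape[0]
    if n < 4:
        raise ParameterError("need at least 4 samples for the Spearman prefilter")

    gr = np.apply_along_axis(stats.rankdata, 0, genus_clr.to_numpy(dtype=float))
    tr = np.apply_along_axis(stats.rankdata, 0, traits.to_numpy(dtype=float))

    def _standardize(R):
        R = R - R.mean(axis=0)
        sd = R.std(axis=0, ddof=0)
        ok = sd > 0
        R[:, ok] = R[:, ok] / sd[ok]
        return R, ok

    gz, g_ok = _standardize(gr)
    tz, t_ok = _standardize(tr)
    rho = (gz.T @ tz) / n
    rho = np.clip(rho, -1.0, 1.0)
    defined = np.outer(g_ok, t_ok)
    if not defined.all():
        logger.warning(
            "%d genus/trait pairs have constant vectors; treated as "
            "non-significant", int((~defined).sum()),
        )
    # two-sided p from the t approximation, as in the standard Spearman test
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    pvals = 2.0 * stats.t.sf(np.abs(t_stat), df=n - 2)
    pvals[np.abs(rho) >= 1.0] = 0.0
    pvals[~defined] = np.nan

    rho_df = pd.DataFrame(rho, index=genus_clr.columns, columns=traits.columns)
    p_df = pd.DataFrame(pvals, index=genus_clr.columns, columns=traits.columns)
    min_p = p_df.min(axis=1, skipna=True)
    retained = [str(g) for g in p_df.index[min_p < alpha]]
    return retained, rho_df, p_df


def enumerate_triplets(genera, mediators, traits) -> list[TripletSpec]:
    """Full Cartesian product in deterministic genus-major order."""
    for name, ids in (("genus", genera), ("mediator", mediators), ("trait", traits)):
        ids = list(ids)
        if not ids:
            raise ParameterError(f"empty {name} id list")
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate {name} ids")
    return [
        TripletSpec(str(g), str(m), str(t))
        for g, m, t in itertools.product(genera, mediators, traits)
    ]


def _ols_paths(Xm, m, Xy, y):
    """Coefficient paths (a, c', b) from the two least-squares fits."""
    am, _, _, _ = np.linalg.lstsq(Xm, m, rcond=None)
    ay, _, _, _ = np.linalg.lstsq(Xy, y, rcond=None)
    return am[1], ay[1], ay[2]  # a (x in mediator model), c' (x), b (m)


def _boot_paths(Xm, m, Xy, y, idx):
    """Vectorized bootstrap refits via batched normal equations."""
    Xmb, mb = Xm[idx], m[idx]
    Xyb, yb = Xy[idx], y[idx]
    Gm = np.einsum("bnp,bnq->bpq", Xmb, Xmb)
    rm = np.einsum("bnp,bn->bp", Xmb, mb)
    Gy = np.einsum("bnp,bnq->bpq", Xyb, Xyb)
    ry = np.einsum("bnp,bn->bp", Xyb, yb)
    cm = np.linalg.solve(Gm, rm[..., None])[..., 0]
    cy = np.linalg.solve(Gy, ry[..., None])[..., 0]
    return cm[:, 1], cy[:, 1], cy[:, 2]  # a, c', b per resample


def _boot_pvalue(samples: np.ndarray) -> float:
    n_boot = samples.size
    p = 2.0 * min((samples <= 0).sum(), (samples >= 0).sum()) / n_boot
    return float(min(1.0, max(p, 2.0 / n_boot)))


class LinearMediation(BaseEstimator):
    """Linear-model mediation estimator with bootstrap inference.

    Parameters
    ----------
    n_boot : int
        Number of nonparametric bootstrap resamples.
    random_state : int, optional
        Seed for the bootstrap resampling.

    Attributes (after :meth:`fit`)
    ------------------------------
    acme_, ade_, total_ : float
        Point estimates (ACME = a*b, ADE = c', total = ACME + ADE).
    prop_mediated_ : float
        acme_/total_, NaN when |total| < 1e-12.
    ci_acme_, ci_ade_, ci_total_ : (lo, hi) percentile 95% intervals.
    p_acme_, p_ade_ : two-sided bootstrap p-values.
    a_path_, b_path_ : the two OLS path coefficients.
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, x, mediator, y, covariates=None):
        x = np.asarray(x, dtype=float).ravel()
        m = np.asarray(mediator, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        n = x.size
        if m.size != n or y.size != n:
            raise AlignmentError("x, mediator and y must have equal length")
        if n < 10:
            raise ParameterError("need at least 10 complete cases for mediation")
        if covariates is None:
            cov = np.empty((n, 0))
        else:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != n:
                cov = cov.T
        if x.std() == 0 or m.std() == 0:
            raise DegenerateFitError("constant exposure or mediator")
        r_xm = np.corrcoef(x, m)[0, 1]
        if abs(r_xm) > 1 - 1e-10:
            raise DegenerateFitError("exposure and mediator are collinear")

        ones = np.ones((n, 1))
        Xm = np.hstack([ones, x[:, None], cov])
        Xy = np.hstack([ones, x[:, None], m[:, None], cov])
        a, c_prime, b = _ols_paths(Xm, m, Xy, y)
        self.a_path_ = float(a)
        self.b_path_ = float(b)
        self.acme_ = float(a * b)
        self.ade_ = float(c_prime)
        self.total_ = float(a * b + c_prime)
        self.prop_mediated_ = (
            float(self.acme_ / self.total_) if abs(self.total_) >= 1e-12
            else float("nan")
        )

        rng = np.random.default_rng(self.random_state)
        idx = rng.integers(0, n, size=(self.n_boot, n))
        ab, cb, bb = _boot_paths(Xm, m, Xy, y, idx)
        acme_b = ab * bb
        ade_b = cb
        total_b = acme_b + ade_b
        self.boot_acme_ = acme_b
        self.boot_ade_ = ade_b
        self.ci_acme_ = tuple(np.percentile(acme_b, [2.5, 97.5]))
        self.ci_ade_ = tuple(np.percentile(ade_b, [2.5, 97.5]))
        self.ci_total_ = tuple(np.percentile(total_b, [2.5, 97.5]))
        self.p_acme_ = _boot_pvalue(acme_b)
        self.p_ade_ = _boot_pvalue(ade_b)
        self.n_used_ = n
        return self


def mediate(
    triplet: TripletSpec,
    genus_clr: pd.DataFrame,
    mediators: pd.DataFrame,
    traits: pd.DataFrame,
    age: pd.Series,
    n_boot: int = 1000,
    seed: int | None = None,
    standardize_exposure: bool = True,
) -> MediationResult:
    """Run one triplet's mediation analysis on sample-aligned tables.

    The exposure is the triplet genus's CLR abundance, standardized to unit
    variance by default so ACME/ADE are in trait units per SD of exposure.
    Rows with a missing value in any of the four variables are dropped.
    """
    for frame, attr, name in (
        (genus_clr, triplet.genus_id, "genus"),
        (mediators, triplet.mediator_id, "mediator"),
        (traits, triplet.trait_id, "trait"),
    ):
        if attr not in frame.columns:
            raise ConfigurationError(f"{name} id {attr!r} not found in its table")
    data = pd.DataFrame(
        {
            "x": genus_clr[triplet.genus_id].astype(float),
            "m": mediators[triplet.mediator_id].astype(float),
            "y": traits[triplet.trait_id].astype(float),
            "age": age.astype(float),
        }
    ).dropna()
    n_dropped = len(genus_clr) - len(data)
    if n_dropped:
        logger.info("triplet %s: dropped %d incomplete rows", triplet, n_dropped)
    x = data["x"].to_numpy()
    if standardize_exposure:
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateFitError(f"genus {triplet.genus_id!r} is constant")
        x = (x - x.mean()) / sd
    est = LinearMediation(n_boot=n_boot, random_state=seed).fit(
        x, data["m"], data["y"], covariates=data["age"]
    )
    return MediationResult(
        triplet=triplet,
        acme=est.acme_,
        ade=est.ade_,
        total=est.total_,
        prop_mediated=est.prop_mediated_,
        ci_acme=est.ci_acme_,
        ci_ade=est.ci_ade_,
        ci_total=est.ci_total_,
        p_acme=est.p_acme_,
        p_ade=est.p_ade_,
        n_boot=n_boot,
        n_used=est.n_used_,
        seed=seed,
        a_path=est.a_path_,
        b_path=est.b_path_,
    )


def significant_links(
    results: list[MediationResult], alpha: float = 0.05
) -> list[MediationResult]:
    """Triplets with ACME bootstrap P strictly below alpha."""
    if not results:
        raise ParameterError("no mediation results to filter")
    return [r for r in results if r.p_acme < alpha]


def link_direction(result: MediationResult) -> str:
    """Whether the exposure increases or decreases the mediator (a-path sign)."""
    return "mediator-increasing" if result.a_path > 0 else "mediator-decreasing"


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Flat results table, one row per triplet."""
    return pd.DataFrame(
        {
            "genus": [r.triplet.genus_id for r in results],
            "scfa": [r.triplet.mediator_id for r in results],
            "trait": [r.triplet.trait_id for r in results],
            "acme": [r.acme for r in results],
            "acme_lo": [r.ci_acme[0] for r in results],
            "acme_hi": [r.ci_acme[1] for r in results],
            "p_acme": [r.p_acme for r in results],
            "ade": [r.ade for r in results],
            "ade_lo": [r.ci_ade[0] for r in results],
            "ade_hi": [r.ci_ade[1] for r in results],
            "p_ade": [r.p_ade for r in results],
            "total": [r.total for r in results],
            "prop_mediated": [r.prop_mediated for r in results],
            "n": [r.n_used for r in results],
            "seed": [r.seed for r in results],
        }
    )


def run_mediation_panel(
    genus_clr: pd.DataFrame,
    mediators: pd.DataFrame,
    traits: pd.DataFrame,
    age: pd.Series,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[MediationResult]:
    """Mediate every genus x mediator x trait triplet with per-triplet seeds.

    Per-triplet seeds derive deterministically from the panel seed so the
    full panel is reproducible and order-independent.
    """
    triplets = enumerate_triplets(
        list(genus_clr.columns), list(mediators.columns), list(traits.columns)
    )
    seeds = np.random.SeedSequence(seed).generate_state(len(triplets)) % (2**31)
    return [
        mediate(t, genus_clr, mediators, traits, age, n_boot=n_boot, seed=int(s))
        for t, s in zip(triplets, seeds)
    ]
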