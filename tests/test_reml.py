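"""REML engine: agreement with independent oracles (exhaustive grid search
of the restricted likelihood; closed-form balanced-ANOVA estimators),
boundary handling, identifiability, and the LRT boundary mixture."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microbiability as mb
from microbiability._exceptions import (
    AlignmentError,
    NonIdentifiableError,
    ParameterError,
)
from microbiability.reml import _DenseCore, _reml_loop, reml_fit


def grid_search_reml(y, X, K, lo=0.0, hi=3.0, step=0.01):
    """Independent maximizer of the restricted likelihood on a 2-D grid.

    Evaluates -0.5*(log|V| + log|X'V^-1 X| + y'Py) for every
    (sigma2_k, sigma2_e) pair on the grid, using only eigendecomposition
    and direct linear algebra (no iterative scheme).
    """
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yr = U.T @ y
    Xr = U.T @ X
    g = np.arange(lo, hi + step / 2, step)
    sg = g[:, None, None]
    se = g[None, :, None]
    v = sg * d[None, None, :] + se  # (G, G, n)
    valid = (v > 0).all(axis=2)
    v = np.where(v > 0, v, 1.0)
    vi = 1.0 / v
    logdet_v = np.log(np.where(valid[:, :, None], v, 1.0)).sum(axis=2)
    XtViX = np.einsum("np,abn,nq->abpq", Xr, vi, Xr)
    XtViy = np.einsum("np,abn,n->abp", Xr, vi, yr)
    sign, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, XtViy[..., None])[..., 0]
    yViy = np.einsum("abn,n->ab", vi, yr**2)
    yPy = yViy - np.einsum("abp,abp->ab", XtViy, beta)
    ll = -0.5 * (logdet_v + logdet_x + yPy)
    ll[~valid | (sign <= 0)] = -np.inf
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return np.array([g[i], g[j]]), ll[i, j]


def _random_fixture(seed, n, p=1, sigma_g=1.0, sigma_e=1.0):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, max(2, n // 2)))
    K = Z @ Z.T / Z.shape[1]
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n)
                                        for _ in range(p - 1)])
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    y = (X.sum(axis=1) + np.sqrt(sigma_g) * (L @ rng.standard_normal(n))
         + np.sqrt(sigma_e) * rng.standard_normal(n))
    kern = mb.Kernel([f"s{i}" for i in range(n)], K, kind="custom",
                     n_features=Z.shape[1])
    return y, X, kern


class TestGridOracle:
    @pytest.mark.parametrize(
        "seed,n,p",
        [(8, 6, 1), (2, 8, 1), (3, 10, 2), (4, 7, 1), (5, 9, 2), (6, 10, 1)],
    )
    def test_ai_reml_matches_grid_search(self, seed, n, p):
        y, X, kern = _random_fixture(seed, n, p)
        spec = mb.ModelSpec(y=y, fixed=X, kernels=[kern])
        fit = reml_fit(spec)
        grid_theta, grid_ll = grid_search_reml(y, X, kern.K)
        # clamp comparison into the grid's box: the grid cannot see optima
        # outside [0, 3]
        est = np.minimum(fit.variance_components, 3.0)
        assert np.abs(est - grid_theta).max() <= 0.02
        assert fit.loglik_restricted >= grid_ll - 1e-6

    def test_dense_path_matches_grid_search(self):
        # the dense-algebra core maximizes the same restricted likelihood
        y, X, kern = _random_fixture(7, 9)
        spec = mb.ModelSpec(y=y, fixed=X, kernels=[kern])
        fit = _reml_loop(_DenseCore(spec.y, spec.fixed, [kern.K]),
                         spec, 1e-8, 1e-6, 200)
        grid_theta, _ = grid_search_reml(y, X, kern.K)
        assert np.abs(np.minimum(fit.variance_components, 3.0)
                      - grid_theta).max() <= 0.02

    def test_dense_and_spectral_paths_agree(self):
        y, X, kern = _random_fixture(11, 60)
        spec = mb.ModelSpec(y=y, fixed=X, kernels=[kern])
        spectral = reml_fit(spec)
        dense = _reml_loop(_DenseCore(spec.y, spec.fixed, [kern.K]),
                           spec, 1e-8, 1e-6, 200)
        np.testing.assert_allclose(
            spectral.variance_components, dense.variance_components,
            rtol=1e-5, atol=1e-8,
        )
        assert abs(spectral.loglik_restricted - dense.loglik_restricted) < 1e-6


class TestAnovaOracle:
    def test_balanced_one_way_matches_closed_form(self):
        # 10 groups x 10 reps with a block-of-ones kernel is the classic
        # random-intercept model: REML equals the ANOVA estimators
        # sigma2_e = MSW, sigma2_b = (MSB - MSW) / r
        g, r = 10, 10
        n = g * r
        rng = np.random.default_rng(42)
        groups = np.repeat(np.arange(g), r)
        b = np.sqrt(2.0) * rng.standard_normal(g)
        y = b[groups] + rng.standard_normal(n)
        K = (groups[:, None] == groups[None, :]).astype(float)
        kern = mb.Kernel([f"s{i}" for i in range(n)], K, kind="custom",
                         n_features=g)
        X = np.ones((n, 1))
        fit = reml_fit(mb.ModelSpec(y=y, fixed=X, kernels=[kern]),
                       tol_loglik=1e-12, tol_param=1e-10)
        group_means = np.array([y[groups == i].mean() for i in range(g)])
        msb = r * ((group_means - y.mean()) ** 2).sum() / (g - 1)
        msw = sum(((y[groups == i] - group_means[i]) ** 2).sum()
                  for i in range(g)) / (g * (r - 1))
        np.testing.assert_allclose(fit.variance_components[-1], msw, atol=1e-6)
        np.testing.assert_allclose(
            fit.variance_components[0], (msb - msw) / r, atol=1e-6
        )


class TestEngineBehavior:
    def test_identity_kernel_non_identifiable(self):
        n = 40
        rng = np.random.default_rng(0)
        kern = mb.Kernel([f"s{i}" for i in range(n)], np.eye(n),
                         kind="custom", n_features=n)
        spec = mb.ModelSpec(y=rng.standard_normal(n), fixed=np.ones((n, 1)),
                            kernels=[kern])
        with pytest.raises(NonIdentifiableError):
            reml_fit(spec)

    def test_em_warmup_is_monotone(self):
        y, X, kern = _random_fixture(13, 50)
        fit = reml_fit(mb.ModelSpec(y=y, fixed=X, kernels=[kern]))
        em_path = fit.loglik_path[:4]  # initial value + 3 EM steps
        assert all(b >= a - 1e-9 for a, b in zip(em_path, em_path[1:]))

    def test_ratios_and_residual_sum_to_one(self):
        y, X, kern = _random_fixture(17, 50)
        fit = reml_fit(mb.ModelSpec(y=y, fixed=X, kernels=[kern]))
        total = fit.variance_components.sum()
        resid_share = fit.variance_components[-1] / total
        assert abs(fit.ratios.sum() + resid_share - 1.0) < 1e-10

    def test_permutation_invariance(self):
        y, X, kern = _random_fixture(19, 50)
        fit = reml_fit(mb.ModelSpec(y=y, fixed=X, kernels=[kern]))
        perm = np.random.default_rng(5).permutation(50)
        kperm = mb.Kernel([kern.ids[i] for i in perm],
                          kern.K[np.ix_(perm, perm)], kind="custom",
                          n_features=kern.n_features)
        fit_p = reml_fit(mb.ModelSpec(y=y[perm], fixed=X[perm],
                                      kernels=[kperm]))
        np.testing.assert_allclose(
            fit.variance_components, fit_p.variance_components, atol=1e-6
        )

    def test_deterministic_refit(self, small_dataset, small_grm):
        M = mb.build_microbiome_kernel(
            mb.standardize_abundance(small_dataset.abundance)
        )
        args = (small_dataset.traits["semen_volume"], small_dataset.covariates,
                small_grm, M)
        f1 = mb.fit_trait_h2_m2(*args)
        f2 = mb.fit_trait_h2_m2(*args)
        np.testing.assert_array_equal(f1.variance_components,
                                      f2.variance_components)
        assert f1.loglik_restricted == f2.loglik_restricted

    def test_id_mismatch_raises_alignment_error(self, small_dataset, small_grm):
        y = small_dataset.traits["semen_volume"].copy()
        y.index = ["x" + str(i) for i in range(len(y))]
        covs = small_dataset.covariates.copy()
        covs.index = y.index
        M = mb.build_microbiome_kernel(
            mb.standardize_abundance(small_dataset.abundance)
        )
        with pytest.raises(AlignmentError):
            mb.fit_trait_h2_m2(y, covs, small_grm, M)

    def test_fixed_effect_only_signal_hits_boundary(self, small_dataset):
        # trait that is a deterministic function of age: both variance
        # components collapse to the boundary
        M = mb.build_microbiome_kernel(
            mb.standardize_abundance(small_dataset.abundance)
        )
        y = 2.0 * small_dataset.age_months.astype(float)
        fit = mb.fit_microbiota_only_m2(y, small_dataset.covariates, M)
        assert fit.boundary_flags.all()
        assert fit.m2 < 1e-6

    def test_microbiota_only_recovery(self):
        # truth m2 = 0.5 with no genetic term; single-seed sanity check
        spec = mb.SimSpec(
            n_individuals=400, n_snps=300, n_taxa=100,
            taxon_h2=np.zeros(100), taxon_prevalence=np.full(100, 0.9),
            trait_config=[mb.TraitConfig(h2_true=0.0, m2_true=0.5)],
            seed=23,
        )
        ds = mb.simulate_dataset(spec)
        M = mb.build_microbiome_kernel(mb.standardize_abundance(ds.abundance))
        fit = mb.fit_microbiota_only_m2(ds.traits["trait1"], ds.covariates, M)
        assert abs(fit.m2 - 0.5) < 0.15


class TestLrt:
    def _pair(self, seed=29, n=60):
        y, X, kern = _random_fixture(seed, n)
        full = reml_fit(mb.ModelSpec(y=y, fixed=X, kernels=[kern]))
        null = reml_fit(mb.ModelSpec(y=y, fixed=X, kernels=[]))
        return full, null

    def test_boundary_mass_at_zero_lr(self):
        full, null = self._pair()
        # force LR = 0 by comparing the null with itself
        assert mb.lrt_pvalue(null_with_fake_kernel(full, null), null) == 0.5

    def test_quantile_value(self):
        # LR = 2.706 is the chi2_1 0.10 upper quantile; halved mixture
        # p-value is ~0.05
        assert abs(0.5 * stats.chi2.sf(2.706, 1) - 0.05) < 5e-4

    def test_model_pair_validation(self):
        full, null = self._pair()
        with pytest.raises(ParameterError):
            mb.lrt_pvalue(null, full)  # reversed nesting
        other_null = reml_fit(
            mb.ModelSpec(y=np.random.default_rng(0).standard_normal(30),
                         fixed=np.ones((30, 1)), kernels=[])
        )
        with pytest.raises(ParameterError):
            mb.lrt_pvalue(full, other_null)

    def test_pvalue_from_real_pair_in_unit_interval(self):
        full, null = self._pair()
        p = mb.lrt_pvalue(full, null)
        assert 0 < p <= 0.5 or (0 < p < 1)


def null_with_fake_kernel(full: mb.VCFit, null: mb.VCFit) -> mb.VCFit:
    """A copy of the null fit dressed as a one-kernel fit with equal logL,
    so the likelihood ratio is exactly zero."""
    import dataclasses

    return dataclasses.replace(
        null,
        kernel_kinds=["custom"],
        loglik_restricted=null.loglik_restricted,
    )
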