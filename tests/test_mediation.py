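"""Mediation: Spearman prefilter, triplet enumeration, the
product-of-coefficients identity, bootstrap inference and link filtering."""

import numpy as np
import pandas as pd
import pytest

import microbiability as mb
from microbiability._exceptions import (
    ConfigurationError,
    DegenerateFitError,
    ParameterError,
)
from microbiability.mediation import link_direction, mediation_table


def _mediation_data(n, a, b, c_prime, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    age = rng.uniform(8, 69, n)
    m = a * x + rng.standard_normal(n)
    y = c_prime * x + b * m + rng.standard_normal(n)
    return x, m, y, age


class TestSpearmanPrefilter:
    def test_perfect_monotone_association_retained(self):
        n = 20
        rng = np.random.default_rng(1)
        trait = rng.standard_normal(n)
        genus = pd.DataFrame({"g": np.argsort(np.argsort(trait)).astype(float)},
                             index=range(n))
        traits = pd.DataFrame({"t": trait}, index=range(n))
        retained, rho, p = mb.spearman_prefilter(genus, traits)
        assert retained == ["g"]
        assert rho.loc["g", "t"] == pytest.approx(1.0)

    def test_constant_vector_treated_as_nonsignificant(self):
        n = 30
        rng = np.random.default_rng(2)
        genus = pd.DataFrame({"flat": np.ones(n),
                              "ok": rng.standard_normal(n)}, index=range(n))
        traits = pd.DataFrame({"t": rng.standard_normal(n)}, index=range(n))
        retained, _, p = mb.spearman_prefilter(genus, traits)
        assert np.isnan(p.loc["flat", "t"])
        assert "flat" not in retained

    def test_misaligned_samples_rejected(self):
        genus = pd.DataFrame({"g": range(10)}, index=range(10))
        traits = pd.DataFrame({"t": range(10)}, index=range(1, 11))
        with pytest.raises(Exception):
            mb.spearman_prefilter(genus, traits)

    def test_small_n_rejected(self):
        frame = pd.DataFrame({"g": [1.0, 2.0, 3.0]})
        with pytest.raises(ParameterError):
            mb.spearman_prefilter(frame, frame)


class TestEnumerateTriplets:
    def test_study_scale_product(self):
        triplets = mb.enumerate_triplets(
            [f"g{i}" for i in range(27)],
            [f"s{i}" for i in range(6)],
            [f"t{i}" for i in range(4)],
        )
        assert len(triplets) == 648

    def test_single_triplet(self):
        assert len(mb.enumerate_triplets(["g"], ["m"], ["t"])) == 1

    def test_genus_major_order(self):
        triplets = mb.enumerate_triplets(["g1", "g2"], ["m1", "m2", "m3"],
                                         ["t1", "t2", "t3", "t4"])
        assert len(triplets) == 24
        assert [t.genus_id for t in triplets[:12]] == ["g1"] * 12
        assert [t.trait_id for t in triplets[:4]] == ["t1", "t2", "t3", "t4"]

    def test_duplicates_rejected(self):
        with pytest.raises(ConfigurationError):
            mb.enumerate_triplets(["g", "g"], ["m"], ["t"])

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            mb.enumerate_triplets([], ["m"], ["t"])


class TestLinearMediation:
    def test_point_acme_equals_ols_product(self):
        # closed-form oracle: refit both models with plain lstsq and
        # compare the coefficient product
        x, m, y, age = _mediation_data(300, a=0.5, b=0.4, c_prime=0.3)
        est = mb.LinearMediation(n_boot=100, random_state=0).fit(
            x, m, y, covariates=age
        )
        n = x.size
        Xm = np.column_stack([np.ones(n), x, age])
        Xy = np.column_stack([np.ones(n), x, m, age])
        a_hat = np.linalg.lstsq(Xm, m, rcond=None)[0][1]
        b_hat = np.linalg.lstsq(Xy, y, rcond=None)[0][2]
        c_hat = np.linalg.lstsq(Xy, y, rcond=None)[0][1]
        assert est.acme_ == pytest.approx(a_hat * b_hat, abs=1e-12)
        assert est.ade_ == pytest.approx(c_hat, abs=1e-12)

    def test_effect_decomposition_identity(self):
        x, m, y, age = _mediation_data(200, a=0.7, b=0.2, c_prime=-0.4, seed=3)
        est = mb.LinearMediation(n_boot=50, random_state=1).fit(
            x, m, y, covariates=age
        )
        assert est.acme_ + est.ade_ == pytest.approx(est.total_, abs=1e-8)

    def test_recovery_within_bootstrap_ci(self):
        x, m, y, age = _mediation_data(2000, a=0.5, b=0.4, c_prime=0.3, seed=7)
        est = mb.LinearMediation(n_boot=1000, random_state=5).fit(
            x, m, y, covariates=age
        )
        assert est.ci_acme_[0] <= 0.20 <= est.ci_acme_[1]
        assert est.ci_ade_[0] <= 0.30 <= est.ci_ade_[1]
        assert abs(est.acme_ - 0.20) < 0.06

    def test_null_acme_ci_covers_zero(self):
        covered = 0
        for seed in range(12):
            x, m, y, age = _mediation_data(300, a=0.0, b=0.4, c_prime=0.3,
                                           seed=seed)
            est = mb.LinearMediation(n_boot=300, random_state=seed).fit(
                x, m, y, covariates=age
            )
            if est.ci_acme_[0] <= 0 <= est.ci_acme_[1]:
                covered += 1
            assert abs(est.acme_) < 0.1
        assert covered >= 10

    def test_bootstrap_reproducible(self):
        x, m, y, age = _mediation_data(150, a=0.5, b=0.4, c_prime=0.0, seed=9)
        e1 = mb.LinearMediation(n_boot=200, random_state=4).fit(x, m, y, age)
        e2 = mb.LinearMediation(n_boot=200, random_state=4).fit(x, m, y, age)
        assert e1.ci_acme_ == e2.ci_acme_ and e1.p_acme_ == e2.p_acme_

    def test_acme_invariant_to_mediator_affine_rescaling(self):
        x, m, y, age = _mediation_data(400, a=0.5, b=0.4, c_prime=0.3, seed=11)
        e1 = mb.LinearMediation(n_boot=10, random_state=0).fit(x, m, y, age)
        e2 = mb.LinearMediation(n_boot=10, random_state=0).fit(
            x, 3.0 * m + 7.0, y, age
        )
        assert e1.acme_ == pytest.approx(e2.acme_, abs=1e-10)

    def test_collinear_exposure_mediator_rejected(self):
        x = np.random.default_rng(0).standard_normal(100)
        with pytest.raises(DegenerateFitError):
            mb.LinearMediation(n_boot=10).fit(x, 2 * x, x + 1.0)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ParameterError):
            mb.LinearMediation().fit(np.arange(5.0), np.arange(5.0) % 2,
                                     np.arange(5.0) ** 2)


class TestTripletApi:
    def _tables(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        x = rng.standard_normal(n)
        genus = pd.DataFrame({"gA": x, "gB": rng.standard_normal(n)},
                             index=idx)
        med = pd.DataFrame({"butyrate": 0.6 * x + rng.standard_normal(n)},
                           index=idx)
        traits = pd.DataFrame(
            {"motility": 0.5 * med["butyrate"] + rng.standard_normal(n)},
            index=idx,
        )
        age = pd.Series(rng.uniform(8, 69, n), index=idx, name="age_months")
        return genus, med, traits, age

    def test_mediate_unknown_id_rejected(self):
        genus, med, traits, age = self._tables()
        with pytest.raises(ConfigurationError):
            mb.mediate(mb.TripletSpec("nope", "butyrate", "motility"),
                       genus, med, traits, age, n_boot=10, seed=0)

    def test_panel_runs_all_triplets_and_is_reproducible(self):
        genus, med, traits, age = self._tables()
        r1 = mb.run_mediation_panel(genus, med, traits, age, n_boot=100,
                                    seed=3)
        r2 = mb.run_mediation_panel(genus, med, traits, age, n_boot=100,
                                    seed=3)
        assert len(r1) == 2  # 2 genera x 1 mediator x 1 trait
        assert [r.p_acme for r in r1] == [r.p_acme for r in r2]
        frame = mediation_table(r1)
        assert list(frame["genus"]) == ["gA", "gB"]

    def test_significant_links_strict_alpha(self):
        genus, med, traits, age = self._tables()
        results = mb.run_mediation_panel(genus, med, traits, age, n_boot=100,
                                         seed=3)
        for r in results:
            r.p_acme = 0.5
        assert mb.significant_links(results) == []
        results[0].p_acme = 0.05  # exact boundary excluded
        assert mb.significant_links(results) == []
        results[0].p_acme = 0.049
        assert len(mb.significant_links(results)) == 1

    def test_link_direction_follows_a_path(self):
        genus, med, traits, age = self._tables()
        result = mb.mediate(mb.TripletSpec("gA", "butyrate", "motility"),
                            genus, med, traits, age, n_boot=50, seed=0)
        assert result.a_path > 0
        assert link_direction(result) == "mediator-increasing"

    def test_true_and_null_links_separate(self):
        # small panel: the one real pathway is detected, null genus is not
        genus, med, traits, age = self._tables(n=400, seed=5)
        results = mb.run_mediation_panel(genus, med, traits, age,
                                         n_boot=500, seed=1)
        by_genus = {r.triplet.genus_id: r for r in results}
        assert by_genus["gA"].p_acme < 0.05
        assert by_genus["gB"].p_acme > 0.05
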