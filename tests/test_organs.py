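"""Organ-compartment model: sums, shares, intercept multiplier, reductions."""
import math

import numpy as np
import pytest

from alloscale import (
    NoInteriorMaximumError,
    OrganCompartment,
    OrganModel,
    PowerLaw,
    doubling_range,
    evaluate_power_law,
    exponent_sensitivity,
    intercept_multiplier,
    linear_to_allometric,
    linearize_model,
    maximizing_exponent,
    organ_mass_parameterization,
    organ_shares,
    reduce_to_single_power,
    whole_body_ree,
)


def random_model(rng: np.random.Generator, n_organs: int = 4) -> OrganModel:
    comps = tuple(
        OrganCompartment(name=f"organ{i}", c=rng.uniform(0.01, 2.0), k=rng.uniform(0.1, 1.3))
        for i in range(n_organs)
    )
    return OrganModel(compartments=comps, mass_unit="g")


class TestWholeBodyRee:
    def test_single_compartment_equals_power_law(self):
        model = OrganModel((OrganCompartment("liver", 0.36, 0.6),), mass_unit="g")
        p = PowerLaw(c=0.36, k=0.6, mass_unit="g")
        for M in (5.0, 30.0, 80.0):
            assert whole_body_ree(model, M) == pytest.approx(evaluate_power_law(p, M))

    def test_mouse5_total_at_reference(self, mouse5):
        # fixture constrained so REE(30 g) = a + b*M0 = 1.66 + 123.73*0.03
        assert whole_body_ree(mouse5, 30.0) == pytest.approx(5.3719, abs=1e-4)

    def test_strictly_increasing(self, mouse5):
        grid = np.linspace(10.0, 60.0, 200)
        ree = whole_body_ree(mouse5, grid)
        assert np.all(np.diff(ree) > 0)

    def test_rejects_nonpositive_mass(self, mouse5):
        with pytest.raises(ValueError):
            whole_body_ree(mouse5, 0.0)


class TestLinearizeModel:
    def test_proportional_organ_has_zero_intercept(self):
        model = OrganModel((OrganCompartment("x", 2.0, 1.0),), mass_unit="g")
        lin = linearize_model(model, 12.0)
        assert lin.per_organ["x"][0] == pytest.approx(0.0, abs=1e-12)

    def test_liver_tangent_at_30g(self, mouse5):
        a, b = linearize_model(mouse5, 30.0).per_organ["liver"]
        assert a == pytest.approx(1.1083, abs=2e-4)
        assert b == pytest.approx(0.055413, rel=1e-3)  # kcal/d per g

    def test_aggregate_matches_published_mouse_values(self, mouse5):
        lin = linearize_model(mouse5, 30.0)
        assert lin.aggregate.a == pytest.approx(1.66, abs=1e-9)
        assert lin.aggregate.b * 1000 == pytest.approx(123.73, abs=1e-6)

    def test_sum_rule_on_random_models(self):
        # Linearizing the sum equals summing the per-organ linearizations.
        rng = np.random.default_rng(42)
        for _ in range(20):
            model = random_model(rng)
            M0 = rng.uniform(5.0, 100.0)
            lin = linearize_model(model, M0)
            a_sum = sum(ab[0] for ab in lin.per_organ.values())
            b_sum = sum(ab[1] for ab in lin.per_organ.values())
            assert lin.aggregate.a == pytest.approx(a_sum, rel=1e-12, abs=1e-12)
            assert lin.aggregate.b == pytest.approx(b_sum, rel=1e-12)
            # tangency of the aggregate to the organ sum
            assert lin.aggregate.predict(M0) == pytest.approx(
                whole_body_ree(model, M0), rel=1e-12
            )


class TestOrganShares:
    def test_single_organ_all_shares_unity(self):
        model = OrganModel((OrganCompartment("only", 1.3, 0.6),), mass_unit="g")
        sh = organ_shares(model, 10.0)
        assert sh.ree["only"] == pytest.approx(1.0)
        assert sh.intercept["only"] == pytest.approx(1.0)
        assert sh.slope["only"] == pytest.approx(1.0)

    def test_liver_dominates_mouse_ree_and_intercept(self, mouse5):
        sh = organ_shares(mouse5, 30.0)
        assert sh.ree["liver"] == pytest.approx(0.516, abs=5e-3)
        assert sh.intercept["liver"] == pytest.approx(0.668, abs=5e-3)

    def test_shares_sum_to_one_and_are_scale_invariant(self, mouse5):
        sh = organ_shares(mouse5, 30.0)
        for group in (sh.ree, sh.intercept, sh.slope):
            assert sum(group.values()) == pytest.approx(1.0, abs=1e-9)
        scaled = OrganModel(
            tuple(
                OrganCompartment(c.name, c.c * 4.184, c.k, f=c.f)
                for c in mouse5.compartments
            ),
            mass_unit="g",
            ee_unit="kJ/d",
        )
        sh2 = organ_shares(scaled, 30.0)
        for name in mouse5.names:
            assert sh2.ree[name] == pytest.approx(sh.ree[name], rel=1e-12)

    def test_intercept_shares_flagged_absent_when_intercept_zero(self):
        model = OrganModel(
            (OrganCompartment("x", 1.0, 1.0), OrganCompartment("y", 2.0, 1.0)),
            mass_unit="g",
        )
        assert organ_shares(model, 10.0).intercept is None


class TestOrganMassParameterization:
    def test_whole_body_organ_recovers_aggregate(self, mouse5):
        model = OrganModel((OrganCompartment("all", 0.5, 0.7),), mass_unit="g")
        betas, intercept = organ_mass_parameterization(model, {"all": 1.0}, 30.0)
        lin = linearize_model(model, 30.0)
        assert betas["all"] == pytest.approx(lin.aggregate.b, rel=1e-12)
        assert intercept == pytest.approx(lin.aggregate.a, rel=1e-12)

    def test_intercept_independent_of_fraction_choice(self, mouse5):
        rng = np.random.default_rng(7)
        names = mouse5.names
        results = []
        for _ in range(2):
            f = {n: float(rng.uniform(0.01, 0.19)) for n in names}
            results.append(organ_mass_parameterization(mouse5, f, 30.0)[1])
        assert results[0] == pytest.approx(results[1], rel=1e-12)
        assert results[0] == pytest.approx(1.66, abs=1e-9)

    def test_liver_slope_per_gram_of_liver(self, mouse5):
        betas, _ = organ_mass_parameterization(mouse5, None, 30.0)
        b_liver = linearize_model(mouse5, 30.0).per_organ["liver"][1]
        assert betas["liver"] == pytest.approx(b_liver / 0.05, rel=1e-9)
        assert betas["liver"] == pytest.approx(1.108, abs=2e-3)

    def test_invalid_fractions_rejected(self, mouse5):
        with pytest.raises(ValueError):
            organ_mass_parameterization(mouse5, {n: 0.0 for n in mouse5.names}, 30.0)
        with pytest.raises(ValueError):
            organ_mass_parameterization(mouse5, {n: 0.5 for n in mouse5.names}, 30.0)


class TestInterceptMultiplier:
    def test_boundary_values(self):
        assert intercept_multiplier(1.0, 30.0) == 0.0
        assert intercept_multiplier(1.0, 7.0) == 0.0
        assert intercept_multiplier(0.0, 30.0) == 1.0

    def test_value_at_maximizer_for_mouse(self):
        k_star = maximizing_exponent(30.0)
        assert intercept_multiplier(k_star, 30.0) == pytest.approx(3.245, abs=2e-3)

    def test_organ_intercept_is_coefficient_times_multiplier(self, mouse5):
        lin = linearize_model(mouse5, 30.0)
        for comp in mouse5.compartments:
            assert lin.per_organ[comp.name][0] == pytest.approx(
                comp.c * intercept_multiplier(comp.k, 30.0), rel=1e-12
            )


class TestMaximizingExponent:
    def test_mouse_reference_mass(self):
        assert maximizing_exponent(30.0) == pytest.approx(0.706, abs=5e-4)

    def test_boundary_at_e(self):
        assert maximizing_exponent(math.e) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_grid_search_at_30g(self):
        ks = np.arange(0.01, 0.99, 1e-4)
        g = (1 - ks) * 30.0**ks
        assert maximizing_exponent(30.0) == pytest.approx(ks[np.argmax(g)], abs=1e-4)

    def test_agrees_with_grid_search_for_random_masses(self):
        rng = np.random.default_rng(11)
        ks = np.linspace(1e-4, 1 - 1e-4, 20001)
        for M0 in rng.uniform(math.e + 0.05, 5000.0, size=50):
            g = (1 - ks) * M0**ks
            assert maximizing_exponent(M0) == pytest.approx(
                ks[np.argmax(g)], abs=1e-4
            )

    def test_too_small_reference_mass_is_flagged(self):
        with pytest.raises(NoInteriorMaximumError):
            maximizing_exponent(0.5)


class TestDoublingRange:
    def test_mouse_interval_against_grid_oracle(self):
        lo, hi = doubling_range(30.0)
        ks = np.linspace(1e-6, 1 - 1e-6, 400001)
        above = ks[(1 - ks) * 30.0**ks >= 2.0]
        assert lo == pytest.approx(above[0], abs=1e-4)
        assert hi == pytest.approx(above[-1], abs=1e-4)
        assert lo < maximizing_exponent(30.0) < hi

    def test_empty_when_multiplier_never_doubles(self):
        lo, hi = doubling_range(math.e)
        assert math.isnan(lo) and math.isnan(hi)


class TestExponentSensitivity:
    def test_no_change_for_identical_exponent(self, mouse5):
        rep = exponent_sensitivity(mouse5, "liver", 0.6, 30.0)
        assert rep.organ_ree_pct_change == pytest.approx(0.0, abs=1e-12)
        assert rep.whole_body_ree_pct_change == pytest.approx(0.0, abs=1e-12)

    def test_liver_exponent_shift_published_magnitudes(self, mouse5):
        rep = exponent_sensitivity(mouse5, "liver", 0.65, 30.0)
        # organ change is 100*(30^0.05 - 1) regardless of the fixture
        assert rep.organ_ree_pct_change == pytest.approx(
            100 * (30.0**0.05 - 1), rel=1e-12
        )
        assert rep.organ_ree_pct_change == pytest.approx(18.54, abs=0.01)
        assert rep.whole_body_ree_pct_change == pytest.approx(9.5, abs=0.1)

    def test_unknown_organ_raises(self, mouse5):
        with pytest.raises(KeyError):
            exponent_sensitivity(mouse5, "spleen", 0.7, 30.0)


class TestReduceToSinglePower:
    @pytest.mark.parametrize("method", ["taylor_sum", "loglog", "nls"])
    def test_single_organ_exact_recovery(self, method):
        model = OrganModel((OrganCompartment("only", 0.36, 0.6),), mass_unit="g")
        res = reduce_to_single_power(model, 20.0, 40.0, method=method)
        assert res.power_law.c == pytest.approx(0.36, rel=1e-6)
        assert res.power_law.k == pytest.approx(0.6, rel=1e-6)
        assert res.rss == pytest.approx(0.0, abs=1e-12)

    def test_mouse5_taylor_sum_recovers_published_whole_body_law(self, mouse5):
        res = reduce_to_single_power(mouse5, 20.0, 40.0, method="taylor_sum")
        p_kg = res.power_law.to_unit("kg")
        assert p_kg.c == pytest.approx(60.6, rel=0.01)
        assert p_kg.k == pytest.approx(0.691, rel=0.01)
        assert res.M0 == 30.0

    def test_nls_never_worse_than_its_taylor_initializer(self, mouse5):
        rng = np.random.default_rng(3)
        models = [mouse5] + [random_model(rng) for _ in range(5)]
        for model in models:
            r_t = reduce_to_single_power(model, 20.0, 40.0, "taylor_sum")
            r_n = reduce_to_single_power(model, 20.0, 40.0, "nls")
            assert r_n.rss <= r_t.rss + 1e-15

    def test_unknown_method_and_bad_range(self, mouse5):
        with pytest.raises(ValueError):
            reduce_to_single_power(mouse5, 20.0, 40.0, method="prony")
        with pytest.raises(ValueError):
            reduce_to_single_power(mouse5, 40.0, 20.0)


class TestModelInvariants:
    def test_weighted_exponent_identity(self):
        # Inverting the aggregate tangent yields the REE-share-weighted mean
        # of the organ exponents.
        rng = np.random.default_rng(21)
        for _ in range(20):
            model = random_model(rng, n_organs=5)
            M0 = rng.uniform(5.0, 200.0)
            lin = linearize_model(model, M0)
            k_agg = linear_to_allometric(lin.aggregate).k
            sh = organ_shares(model, M0)
            k_weighted = sum(
                sh.ree[c.name] * c.k for c in model.compartments
            )
            assert k_agg == pytest.approx(k_weighted, rel=1e-10)

    def test_intercept_decomposition(self, mouse5):
        lin = linearize_model(mouse5, 30.0)
        k_agg = linear_to_allometric(lin.aggregate).k
        assert lin.aggregate.a == pytest.approx(
            whole_body_ree(mouse5, 30.0) * (1 - k_agg), rel=1e-10
        )

    def test_sublinear_organs_force_positive_aggregate_intercept(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            comps = tuple(
                OrganCompartment(f"o{i}", rng.uniform(0.01, 2.0), rng.uniform(0.05, 0.999))
                for i in range(4)
            )
            model = OrganModel(comps, mass_unit="g")
            assert linearize_model(model, rng.uniform(2.0, 300.0)).aggregate.a > 0

    def test_lumped_exponent_consistency_enforced(self):
        OrganCompartment("ok", 1.0, 0.9, p=-0.1, q=1.0)
        with pytest.raises(ValueError):
            OrganCompartment("bad", 1.0, 0.9, p=0.2, q=0.9)
        with pytest.raises(ValueError):
            OrganModel(
                (OrganCompartment("a", 1.0, 0.5), OrganCompartment("a", 2.0, 0.6)),
                mass_unit="g",
            )
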