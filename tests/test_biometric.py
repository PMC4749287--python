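"""Biometric ACE/ADE machinery: covariance algebra, likelihood, fitting, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twindelta.biometric import (
    NESTED_MODELS,
    SelectionResult,
    TwinModelFit,
    VarianceComponents,
    aic,
    bootstrap_components_ci,
    choose_full_model_aic,
    choose_full_model_icc,
    expected_cov,
    falconer_start,
    fit_twin_model,
    lrt,
    negloglik,
    select_best_model,
    _pair_data,
)

from conftest import delta_frame, simulated_deltas


class TestExpectedCov:
    @pytest.mark.parametrize(
        "model, comps, zyg, off",
        [
            ("ACE", dict(a2=0.4, c2=0.2, e2=0.4), "MZ", 0.6),
            ("ADE", dict(a2=0.4, d2=0.2, e2=0.4), "DZ", 0.25),
            ("E", dict(e2=1.0), "MZ", 0.0),
            ("E", dict(e2=1.0), "DZ", 0.0),
            ("AE", dict(a2=0.5, e2=0.5), "DZ", 0.25),
        ],
    )
    def test_known_covariances(self, model, comps, zyg, off):
        v = expected_cov(model, VarianceComponents(**comps), 1.0, zyg)
        assert v[0, 1] == pytest.approx(off)
        assert v[0, 0] == pytest.approx(1.0)

    def test_component_outside_model_raises(self):
        with pytest.raises(ValueError, match="d2"):
            expected_cov("ACE", VarianceComponents(a2=0.5, d2=0.2, e2=0.3), 1.0, "MZ")


class TestNegloglik:
    def test_single_standard_pair_closed_form(self):
        deltas = delta_frame({"MZ": [(0.0, 0.0)]})
        data = _pair_data(deltas, covariates=False)
        v = negloglik("E", VarianceComponents(e2=1.0), 1.0, data, beta=np.array([0.0]))
        assert v == pytest.approx(np.log(2 * np.pi), abs=1e-12)

    def test_duplicating_pairs_doubles_value(self):
        pairs = [(0.3, -0.2), (1.1, 0.4), (-0.5, 0.6)]
        one = _pair_data(delta_frame({"MZ": pairs}), covariates=False)
        two = _pair_data(delta_frame({"MZ": pairs * 2}), covariates=False)
        comps = VarianceComponents(a2=0.5, e2=0.5)
        v1 = negloglik("AE", comps, 1.3, one, beta=np.array([0.1]))
        v2 = negloglik("AE", comps, 1.3, two, beta=np.array([0.1]))
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_agrees_with_scipy_density_oracle(self):
        rng = np.random.default_rng(3)
        pairs = [tuple(r) for r in rng.standard_normal((10, 2))]
        deltas = delta_frame({"MZ": pairs[:5], "DZ": pairs[5:]})
        data = _pair_data(deltas, covariates=False)
        comps = VarianceComponents(a2=0.35, c2=0.15, e2=0.5)
        total = 0.8
        mu = 0.23
        ours = negloglik("ACE", comps, total, data, beta=np.array([mu]))
        oracle = 0.0
        for zyg, rho in (("MZ", 0.5), ("DZ", 0.325)):
            cov = total * np.array([[1.0, rho], [rho, 1.0]])
            mvn = stats.multivariate_normal(mean=[mu, mu], cov=cov)
            y = data[zyg][0]
            oracle -= mvn.logpdf(y).sum()
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_non_positive_definite_returns_inf(self):
        deltas = delta_frame({"MZ": [(0.0, 1.0)] * 3})
        data = _pair_data(deltas, covariates=False)
        v = negloglik("AE", VarianceComponents(a2=1.0 - 1e-12, e2=1e-12), 0.0, data)
        assert v == np.inf


class TestFalconerStart:
    @pytest.mark.parametrize(
        "rmz, rdz, expect",
        [
            ((0.6), 0.3, (0.6, 0.0, 0.4)),
            (0.50, 0.18, (0.64, 0.0, 0.36)),
            (0.0, 0.0, (0.0, 0.0, 1.0)),
        ],
    )
    def test_known_values(self, rmz, rdz, expect):
        c = falconer_start(rmz, rdz)
        assert (c.a2, c.c2, c.e2) == pytest.approx(expect)
        assert c.d2 == 0.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_always_on_simplex_with_positive_e(self, rmz, rdz):
        c = falconer_start(rmz, rdz)
        assert c.a2 >= 0 and c.c2 >= 0 and c.e2 > 0
        assert c.total() == pytest.approx(1.0, abs=1e-12)


class TestFullModelRules:
    @pytest.mark.parametrize(
        "rmz, rdz, expect",
        [(0.50, 0.18, "ADE"), (0.29, 0.26, "ACE"), (0.40, 0.20, "ACE")],
    )
    def test_icc_rule(self, rmz, rdz, expect):
        assert choose_full_model_icc(rmz, rdz) == expect

    def test_aic_rule_and_tie(self):
        f = lambda a: TwinModelFit(  # noqa: E731
            model="ACE", components=VarianceComponents(e2=1.0), total_var=1.0,
            mean_coefs={}, loglik=-(a / 2 - 3), k=3, aic=a,
        )
        assert choose_full_model_aic(f(-100.0), f(-101.0)) == "ADE"
        assert choose_full_model_aic(f(-100.0), f(-100.0)) == "ACE"


def synthetic_fit(model, loglik, k):
    return TwinModelFit(
        model=model,
        components=VarianceComponents(e2=1.0),
        total_var=1.0,
        mean_coefs={},
        loglik=loglik,
        k=k,
        aic=aic(loglik, k),
    )


class TestLrtAic:
    def test_identical_logliks(self):
        full = synthetic_fit("ACE", -100.0, 7)
        nested = synthetic_fit("AE", -100.0, 6)
        x2, df, p = lrt(full, nested)
        assert (x2, df, p) == (0.0, 1, 1.0)

    def test_printed_chi_square_pair(self):
        # X2 = 1.40 on 1 df -> p ~ 0.237 (prints as 0.24)
        full = synthetic_fit("ADE", -100.0, 7)
        nested = synthetic_fit("AE", -100.7, 6)
        x2, df, p = lrt(full, nested)
        assert x2 == pytest.approx(1.40, abs=1e-9)
        assert p == pytest.approx(0.2367, abs=1e-3)
        assert round(p, 2) == 0.24

    def test_nested_better_warns(self):
        full = synthetic_fit("ACE", -101.0, 7)
        nested = synthetic_fit("AE", -100.0, 6)
        with pytest.warns(UserWarning, match="refitting"):
            lrt(full, nested)

    def test_aic_values_and_identity(self):
        assert aic(-100.0, 3) == 206.0
        assert aic(0.0, 0) == 0.0
        full = synthetic_fit("ACE", -393.25, 7)
        nested = synthetic_fit("AE", -393.95, 6)
        x2, df, _ = lrt(full, nested)
        assert nested.aic == pytest.approx(full.aic + x2 - 2 * df, abs=1e-9)


class TestSelectBestModel:
    def test_parsimony_selects_nested_on_nonsignificant_lrt(self):
        # ADE full with AE at X2 = 1.40 (p = 0.24): AE wins
        full = synthetic_fit("ADE", -100.0, 7)
        nested = {"AE": synthetic_fit("AE", -100.7, 6), "E": synthetic_fit("E", -110.0, 5)}
        sel = select_best_model(full, nested)
        assert sel.best_model == "AE"

    def test_equal_k_tie_broken_by_aic(self):
        full = synthetic_fit("ACE", -100.0, 7)
        nested = {
            "AE": synthetic_fit("AE", -100.5, 6),
            "CE": synthetic_fit("CE", -100.2, 6),
            "E": synthetic_fit("E", -110.0, 5),
        }
        sel = select_best_model(full, nested)
        assert sel.best_model == "CE"

    def test_parsimony_overrides_aic_against_full(self):
        # nested AIC exceeds the full model's, yet p > alpha keeps the nested model
        full = synthetic_fit("ADE", -100.0, 7)
        nested = {"AE": synthetic_fit("AE", -101.5, 6), "E": synthetic_fit("E", -120.0, 5)}
        sel = select_best_model(full, nested)
        assert nested["AE"].aic > full.aic
        assert sel.best_model == "AE"

    def test_all_significant_returns_full(self):
        full = synthetic_fit("ACE", -100.0, 7)
        nested = {
            "AE": synthetic_fit("AE", -110.0, 6),
            "CE": synthetic_fit("CE", -112.0, 6),
            "E": synthetic_fit("E", -130.0, 5),
        }
        assert select_best_model(full, nested).best_model == "ACE"

    def test_smallest_model_preferred_when_it_passes(self):
        full = synthetic_fit("ACE", -100.0, 7)
        nested = {
            "AE": synthetic_fit("AE", -100.1, 6),
            "CE": synthetic_fit("CE", -100.2, 6),
            "E": synthetic_fit("E", -100.6, 5),
        }
        assert select_best_model(full, nested).best_model == "E"

    def test_wrong_nested_set_raises(self):
        full = synthetic_fit("ADE", -100.0, 7)
        with pytest.raises(ValueError, match="nested set"):
            select_best_model(full, {"CE": synthetic_fit("CE", -101.0, 6)})


class TestFitTwinModel:
    def test_null_heritability_recovery(self):
        deltas = simulated_deltas(2000, (0.0, 0.0, 0.0, 1.0), seed=41)
        fit = fit_twin_model(deltas, "AE", covariates=False)
        assert fit.components.a2 <= 0.05
        assert fit.components.e2 >= 0.95

    def test_components_sum_to_one_and_excluded_zero(self):
        deltas = simulated_deltas(300, (0.5, 0.2, 0.0, 0.3), seed=42)
        for model in ("ACE", "ADE", "AE", "CE", "E"):
            fit = fit_twin_model(deltas, model)
            assert fit.components.total() == pytest.approx(1.0, abs=1e-8)
            for comp in ("a", "c", "d", "e"):
                if comp not in model.lower():
                    assert fit.components.as_dict()[f"{comp}2"] == 0.0

    def test_full_loglik_dominates_nested(self):
        deltas = simulated_deltas(400, (0.4, 0.2, 0.0, 0.4), seed=43)
        full = fit_twin_model(deltas, "ACE")
        for name in NESTED_MODELS["ACE"]:
            nested = fit_twin_model(deltas, name)
            assert full.loglik >= nested.loglik - 1e-6

    def test_few_pairs_warns(self):
        deltas = simulated_deltas(8, (0.5, 0.0, 0.0, 0.5), seed=44)
        with pytest.warns(UserWarning, match="unstable"):
            fit_twin_model(deltas, "AE")

    def test_unknown_model_raises(self):
        deltas = simulated_deltas(20, (0.5, 0.0, 0.0, 0.5), seed=45)
        with pytest.raises(ValueError, match="unknown model"):
            fit_twin_model(deltas, "DE")


class TestBootstrapComponents:
    def test_seed_determinism_and_unit_interval(self):
        deltas = simulated_deltas(60, (0.5, 0.0, 0.0, 0.5), seed=51)
        a = bootstrap_components_ci(deltas, "AE", reps=100, seed=5)
        b = bootstrap_components_ci(deltas, "AE", reps=100, seed=5)
        assert a == b
        for lo, hi in a.values():
            assert 0.0 <= lo <= hi <= 1.0

    def test_reps_minimum(self):
        deltas = simulated_deltas(60, (0.5, 0.0, 0.0, 0.5), seed=51)
        with pytest.raises(ValueError):
            bootstrap_components_ci(deltas, "AE", reps=10)
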