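import numpy as np
import pandas as pd
import pytest

from cellalloc.division_size import (
    division_allocation,
    enumerate_pairwise_fits,
    fit_size_law,
    predict_c_plus_d,
    predict_division_size,
    steady_state_with_division,
)
from cellalloc.model_core import GrowthModulation
from cellalloc.steady_state import solve_regulated
from cellalloc.synthetic_fixtures import (
    make_modulation_grid,
    make_sizelaw_table,
)


@pytest.fixture(scope="module")
def mixed_grid(params):
    """Nutrient + chloramphenicol + useless conditions (both regressors vary)."""
    return (
        list(make_modulation_grid("nutrient", 8, params))
        + list(make_modulation_grid("chloramphenicol", 6, params))
        + list(make_modulation_grid("useless", 5, params))
    )


class TestDivisionAllocation:
    def test_fully_active_ribosomes(self, params, ref_mod):
        ss = solve_regulated(params, ref_mod)
        assert ss.active_fraction == 1.0
        assert division_allocation(ss, params) == pytest.approx(
            params.f_X_scale * ss.e, rel=1e-12
        )

    def test_linear_in_metabolic_concentration(self, params):
        # doubling e (at fixed active fraction) doubles f_X
        ss1 = solve_regulated(params, GrowthModulation(k=1.0))
        f1 = division_allocation(ss1, params)
        f2 = division_allocation(ss1, params.with_(f_X_scale=2 * params.f_X_scale))
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_inactivation_raises_allocation(self, params):
        # (r_a/r)^(-2/3): halving the active fraction multiplies f_X by 2^(2/3)
        ss_free = solve_regulated(params, GrowthModulation(k=3.5088))
        fX_free = division_allocation(ss_free, params)
        scaled = fX_free * 0.5 ** (-2.0 / 3.0)
        assert scaled == pytest.approx(fX_free * 1.5874, rel=1e-4)


class TestSizePrediction:
    def test_low_precursor_form(self, params, ref_mod):
        ss = solve_regulated(params, ref_mod)
        pred = predict_division_size(ss, params, approx=True)
        assert pred.V_div == pytest.approx(params.X_div / pred.f_X, rel=1e-12)
        full = predict_division_size(ss, params)
        assert full.V_div == pytest.approx(pred.V_div / (1 - ss.a), rel=1e-12)

    def test_size_law_ratios(self, params):
        # V ~ e^-1 (r_a/r)^(2/3): condition pairs obey the predicted ratios
        ss_a = solve_regulated(params, GrowthModulation(k=1.0))
        ss_b = solve_regulated(params, GrowthModulation(k=8.0))
        Va = predict_division_size(ss_a, params, approx=True).V_div
        Vb = predict_division_size(ss_b, params, approx=True).V_div
        assert Vb / Va == pytest.approx(
            (ss_a.e / ss_b.e)
            * (ss_b.active_fraction / ss_a.active_fraction) ** (2.0 / 3.0),
            rel=1e-10,
        )

    def test_attached_division_sector_is_self_consistent(self, params, ref_mod):
        att = steady_state_with_division(params, ref_mod)
        assert att["f_Q_eff"] + att["f_X"] == pytest.approx(params.f_Q, abs=1e-15)
        assert att["V_div"] == pytest.approx(params.X_div / att["x"], rel=1e-12)


class TestCPlusD:
    def test_initiation_size_gives_zero_duration(self):
        assert predict_c_plus_d(0.28, 1.0, 0.28) == 0.0

    def test_worked_value(self):
        # V_div/S0 = 4 at alpha = 1/hr: C+D = ln 4
        assert predict_c_plus_d(1.12, 1.0, 0.28) == pytest.approx(np.log(4), rel=1e-12)

    def test_inverse_in_growth_rate(self):
        assert predict_c_plus_d(1.12, 2.0, 0.28) == pytest.approx(
            predict_c_plus_d(1.12, 1.0, 0.28) / 2, rel=1e-12
        )

    def test_sub_initiation_size_flags_negative(self):
        assert predict_c_plus_d(0.14, 1.0, 0.28) < 0

    def test_round_trip_with_exponential_size_law(self):
        # V_div = S0*exp(alpha*(C+D)) inverts exactly
        cpd = predict_c_plus_d(2.3, 0.9, 0.28)
        assert 0.28 * np.exp(0.9 * cpd) == pytest.approx(2.3, rel=1e-12)


class TestSizeLawFit:
    def test_noise_free_recovery(self, params, mixed_grid):
        table = make_sizelaw_table(mixed_grid, params, noise_sd=0.0)
        fit = fit_size_law(table, ("e", "active_fraction"))
        assert fit.exponents[0] == pytest.approx(-1.0, abs=1e-10)
        assert fit.exponents[1] == pytest.approx(2.0 / 3.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_prediction_fit_round_trip(self, params, mixed_grid):
        # predictions from the structural model, refit: exponents come back
        rows = []
        for mod in mixed_grid:
            ss = solve_regulated(params, mod)
            pred = predict_division_size(ss, params, approx=True)
            rows.append(
                {"V_div": pred.V_div, "e": ss.e, "active_fraction": ss.active_fraction}
            )
        fit = fit_size_law(pd.DataFrame(rows), ("e", "active_fraction"))
        assert fit.exponents[0] == pytest.approx(-params.beta_e, abs=1e-8)
        assert fit.exponents[1] == pytest.approx(-params.beta_ar, abs=1e-8)

    def test_ci_coverage_under_lognormal_noise(self, params, mixed_grid):
        """95% CIs cover the true exponents in >=90% of noisy replicates."""
        conds = (
            list(make_modulation_grid("nutrient", 20, params))
            + [
                GrowthModulation(k=3.5088, kon_cm=kon, label=f"c{i}")
                for i, kon in enumerate(np.linspace(0.5, 8, 12))
            ]
            + [
                GrowthModulation(k=3.5088, f_U=fu, label=f"u{i}")
                for i, fu in enumerate(np.linspace(0.02, 0.3, 8))
            ]
        )
        hits = 0
        for seed in range(200):
            table = make_sizelaw_table(conds, params, noise_sd=0.05, seed=seed)
            fit = fit_size_law(table, ("e", "active_fraction"))
            (lo1, hi1), (lo2, hi2) = fit.ci95
            hits += lo1 <= -1.0 <= hi1 and lo2 <= 2.0 / 3.0 <= hi2
        assert hits / 200 >= 0.90

    def test_single_regressor_suffices_without_drug(self, params):
        """Nutrient+useless conditions: e alone explains size (active frac = 1).

        Adding chloramphenicol conditions degrades the single-regressor fit
        relative to the two-regressor one.
        """
        drug_free = list(make_modulation_grid("nutrient", 8, params)) + list(
            make_modulation_grid("useless", 5, params)
        )
        t0 = make_sizelaw_table(drug_free, params, noise_sd=0.0)
        fit_e = fit_size_law(t0, ("e",))
        assert fit_e.exponents[0] == pytest.approx(-1.0, abs=1e-10)
        assert fit_e.r_squared == pytest.approx(1.0, abs=1e-12)
        with_drug = drug_free + list(make_modulation_grid("chloramphenicol", 6, params))
        t1 = make_sizelaw_table(with_drug, params, noise_sd=0.0)
        r2_single = fit_size_law(t1, ("e",)).r_squared
        r2_pair = fit_size_law(t1, ("e", "active_fraction")).r_squared
        assert r2_pair > r2_single

    def test_constant_regressor_rejected(self, params):
        drug_free = list(make_modulation_grid("nutrient", 6, params))
        table = make_sizelaw_table(drug_free, params, noise_sd=0.0)
        with pytest.raises(ValueError, match="constant"):
            fit_size_law(table, ("active_fraction",))


class TestEnumerateFits:
    def test_true_pair_ranks_first(self, params, mixed_grid):
        table = make_sizelaw_table(mixed_grid, params, noise_sd=0.0)
        fits = enumerate_pairwise_fits(table)
        assert fits[0].quantity_names == ("e", "active_fraction")
        assert fits[0].r_squared == pytest.approx(1.0, abs=1e-12)

    def test_generator_matching_single_regressor_model(self, params):
        # data built from f_X ~ e alone: the single-e fit is already perfect
        drug_free = list(make_modulation_grid("nutrient", 8, params)) + list(
            make_modulation_grid("useless", 5, params)
        )
        table = make_sizelaw_table(drug_free, params, noise_sd=0.0)
        fits = enumerate_pairwise_fits(table)
        best_single_e = [f for f in fits if f.quantity_names == ("e",)][0]
        assert best_single_e.r_squared == pytest.approx(fits[0].r_squared, abs=1e-10)

    def test_degenerate_regressors_skipped(self, params):
        drug_free = list(make_modulation_grid("nutrient", 6, params))
        table = make_sizelaw_table(drug_free, params, noise_sd=0.0)
        fits = enumerate_pairwise_fits(table)
        for f in fits:
            assert "active_fraction" not in f.quantity_names
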