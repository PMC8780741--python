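"""Ampholyte solubility-pH engine: branches, titration sweep, refinement."""

import math

import numpy as np
import pytest
from scipy.optimize import bisect

from preformkit.speciation import (SolubilityPoint, SpeciationModel,
                                   calculated_solubility_table, davies_gamma,
                                   hh_solubility_ampholyte, ph_max,
                                   refine_model, salt_branch_solubility,
                                   simulate_titration, solubility_at)
from preformkit.synthetic import gen_solubility


@pytest.fixture
def model():
    return SpeciationModel(s0=12.0, pka1=5.54, pka2=10.33)


@pytest.fixture
def salt_model():
    return SpeciationModel(s0=12.0, pka1=5.54, pka2=10.33, pksp=8.0)


class TestHendersonHasselbalch:
    def test_neutral_plateau_equals_s0(self, model):
        ph = 0.5 * (model.pka1 + model.pka2)  # > 2 units from both pKa
        assert hh_solubility_ampholyte(ph, model) == pytest.approx(
            model.s0, rel=0.02)

    def test_half_protonated_at_pka1(self, model):
        assert hh_solubility_ampholyte(model.pka1, model) == pytest.approx(
            2.0 * model.s0, rel=0.01)

    def test_direct_evaluation_at_ph_7_4(self, model):
        # 12.0 * (1 + 10**-1.86 + 10**-2.93) = 12.1797
        assert hh_solubility_ampholyte(7.4, model) == pytest.approx(
            12.1797, abs=5e-4)


class TestDaviesGamma:
    def test_unit_activity_at_zero_ionic_strength(self):
        assert davies_gamma(0.0, 1) == 1.0

    def test_reference_value(self):
        assert davies_gamma(0.1, 1) == pytest.approx(0.782, abs=5e-4)

    @pytest.mark.parametrize("ionic", [0.01, 0.05, 0.1, 0.3])
    def test_charge_square_scaling(self, ionic):
        assert davies_gamma(ionic, 2) == pytest.approx(
            davies_gamma(ionic, 1) ** 4, rel=1e-12)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            davies_gamma(-0.1, 1)


class TestSaltBranch:
    def test_doubling_chloride_halves_solubility_at_low_ph(self, salt_model):
        s1 = salt_branch_solubility(2.0, salt_model, chloride=0.05)
        s2 = salt_branch_solubility(2.0, salt_model, chloride=0.10)
        assert s1 == pytest.approx(2.0 * s2, rel=1e-9)

    def test_ksp_limit_far_below_pka1(self, salt_model):
        cl = 0.05
        s = salt_branch_solubility(1.0, salt_model, chloride=cl)
        expected = (salt_model.ksp / cl) * salt_model.molecular_weight * 1e3
        assert s == pytest.approx(expected, rel=2e-4)

    def test_nonpositive_chloride_rejected(self, salt_model):
        with pytest.raises(ValueError):
            salt_branch_solubility(2.0, salt_model, chloride=0.0)

    def test_ph_max_matches_independent_bisection(self, salt_model):
        cl = 0.02
        f = lambda p: (salt_branch_solubility(p, salt_model, cl)
                       - hh_solubility_ampholyte(p, salt_model))
        oracle = bisect(f, 1.0, 9.0, xtol=1e-12)
        assert ph_max(salt_model, cl) == pytest.approx(oracle, abs=1e-8)


class TestTitrationSimulation:
    def test_reduces_to_hh_without_salt(self, model):
        points = simulate_titration(model, 0.0, 13.0, 0.2, use_activity=False)
        for p in points:
            hh = hh_solubility_ampholyte(p.ph, model)
            assert abs(p.s_calc - hh) / hh < 1e-9
            assert p.saturating_phase == "neutral"

    def test_equals_two_branch_minimum_with_fixed_chloride(self, salt_model):
        cl = 0.05
        points = simulate_titration(salt_model, 0.2, 13.0, 0.2,
                                    fixed_chloride=cl, use_activity=False)
        for p in points:
            oracle = min(hh_solubility_ampholyte(p.ph, salt_model),
                         salt_branch_solubility(p.ph, salt_model, cl))
            assert abs(p.s_calc - oracle) / oracle < 1e-6

    def test_phase_switches_at_ph_max(self, salt_model):
        cl = 0.05
        switch = ph_max(salt_model, cl)
        points = simulate_titration(salt_model, 0.2, 13.0, 0.2,
                                    fixed_chloride=cl, use_activity=False)
        for p in points:
            expected = "salt" if p.ph < switch else "neutral"
            assert p.saturating_phase == expected

    def test_common_ion_effect_below_ph_2(self, salt_model):
        # with HCl titrant supplying chloride, solubility falls as pH falls
        points = [p for p in simulate_titration(salt_model, 0.4, 2.0, 0.2)
                  if p.saturating_phase == "salt"]
        s = [p.s_calc for p in points]
        assert all(a < b for a, b in zip(s, s[1:]))

    def test_u_shape_single_interior_minimum(self, salt_model):
        points = simulate_titration(salt_model, 0.4, 13.0, 0.2)
        logs = np.log10([p.s_calc for p in points])
        interior_minima = sum(
            1 for i in range(1, len(logs) - 1)
            if logs[i] < logs[i - 1] and logs[i] <= logs[i + 1])
        assert interior_minima == 1

    def test_ionic_strength_reported_nonnegative(self, salt_model):
        points = simulate_titration(salt_model, 0.4, 13.0, 0.2)
        assert all(p.ionic_strength >= 0 for p in points)


class TestCalculatedTable:
    def test_grid_ph_returned_exactly(self, model):
        [(_, s)] = calculated_solubility_table(model, [7.4],
                                               use_activity=False)
        point = [p for p in simulate_titration(model, 0.0, 13.0, 0.2,
                                               use_activity=False)
                 if abs(p.ph - 7.4) < 1e-9]
        assert s == pytest.approx(point[0].s_calc, rel=1e-12)

    def test_neutral_region_equals_closed_form(self, model):
        [(_, s)] = calculated_solubility_table(model, [8.0],
                                               use_activity=False)
        assert s == pytest.approx(hh_solubility_ampholyte(8.0, model),
                                  rel=1e-9)

    def test_interpolation_against_half_step_simulation(self, model):
        [(_, interpolated)] = calculated_solubility_table(
            model, [7.5], step=0.2, use_activity=False)
        [(_, direct)] = calculated_solubility_table(
            model, [7.5], step=0.1, use_activity=False)
        assert interpolated == pytest.approx(direct, rel=1e-3)

    def test_out_of_range_ph_rejected(self, model):
        with pytest.raises(ValueError):
            calculated_solubility_table(model, [13.8])


class TestRefinement:
    def test_exact_data_recovers_parameters(self, salt_model):
        ph_list = [1.5, 2.5, 3.5, 4.0, 4.5, 5.0, 6.0, 7.0, 8.0, 9.0]
        points = [SolubilityPoint(ph=p, solubility=solubility_at(salt_model, p))
                  for p in ph_list]
        start = SpeciationModel(s0=30.0, pka1=5.54, pka2=10.33, pksp=7.2)
        result = refine_model(points, start, ("s0", "pksp"))
        assert result.converged
        assert result.weighted_sse <= 1e-12
        assert math.log10(result.model.s0) == pytest.approx(
            math.log10(salt_model.s0), abs=1e-6)
        assert result.model.pksp == pytest.approx(salt_model.pksp, abs=1e-6)

    def test_noisy_recovery_and_bias(self, salt_model):
        # 12 pH points, 0.05 log-unit lognormal noise, many seeds
        ph_list = np.round(np.arange(2.0, 7.51, 0.5), 2)
        errors = []
        for seed in range(100):
            points, _ = gen_solubility(salt_model, ph_list,
                                       noise_sd_log=0.05, seed=seed)
            start = SpeciationModel(s0=25.0, pka1=5.54, pka2=10.33, pksp=7.5)
            result = refine_model(points, start, ("s0", "pksp"))
            errors.append(math.log10(result.model.s0 / salt_model.s0))
        errors = np.asarray(errors)
        assert np.median(np.abs(10.0 ** errors - 1.0)) < 0.10
        assert abs(errors.mean()) < 0.02  # bias of log10 s0

    def test_too_few_points_rejected(self, salt_model):
        points = [SolubilityPoint(ph=7.0, solubility=12.0),
                  SolubilityPoint(ph=8.0, solubility=12.0)]
        with pytest.raises(ValueError):
            refine_model(points, salt_model, ("s0",))

    def test_excluded_point_residual_still_reported(self, salt_model):
        ph_list = [2.0, 3.0, 4.0, 5.0, 6.8, 7.4]
        points = [SolubilityPoint(ph=p, solubility=solubility_at(salt_model, p))
                  for p in ph_list]
        result = refine_model(points, salt_model, ("s0",), exclude_ph=[2.0])
        assert result.excluded == (2.0,)
        assert result.residuals.shape == (6,)

    def test_unknown_free_parameter_rejected(self, salt_model):
        points = [SolubilityPoint(ph=p, solubility=12.0) for p in (6.0, 7.0, 8.0)]
        with pytest.raises(ValueError):
            refine_model(points, salt_model, ("s0", "ksp_typo"))


class TestModelValidation:
    def test_pka_ordering_enforced(self):
        with pytest.raises(ValueError):
            SpeciationModel(s0=10.0, pka1=10.0, pka2=5.0)

    def test_positive_s0_enforced(self):
        with pytest.raises(ValueError):
            SpeciationModel(s0=-1.0, pka1=5.0, pka2=10.0)
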