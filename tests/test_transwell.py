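"""Non-sink transwell forward model, Papp fitting and reference comparison."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from preformkit.synthetic import gen_transwell
from preformkit.transwell import (PappResult, TranswellAssay, compare_groups,
                                  compare_to_reference, dilution_factor,
                                  efflux_ratio, fit_papp,
                                  forward_receiver_series)


def make_assay(papp=None, vr=2.0, vd=2.0, times=(0.0, 15.0, 30.0, 60.0, 90.0),
               c_donor=100.0, sample_volume=0.2, area=4.2):
    assay = TranswellAssay(
        direction="A-B", v_receiver=vr, v_donor=vd,
        receiver_concentrations=np.zeros(len(times)),
        sample_times=np.array(times), membrane_area=area,
        sample_volume=sample_volume, donor_concentrations=(c_donor, c_donor))
    if papp is None:
        return assay
    predicted = forward_receiver_series(assay, papp)
    return TranswellAssay(
        direction="A-B", v_receiver=vr, v_donor=vd,
        receiver_concentrations=predicted, sample_times=np.array(times),
        membrane_area=area, sample_volume=sample_volume,
        donor_concentrations=(c_donor, c_donor))


class TestDilutionFactor:
    def test_no_sampling_gives_unity(self):
        assert dilution_factor(2.0, 0.0) == 1.0

    def test_fixture_volumes(self):
        assert dilution_factor(2.0, 0.2) == pytest.approx(0.9)

    def test_scale_invariance(self):
        assert dilution_factor(20.0, 2.0) == dilution_factor(2.0, 0.2)

    def test_sample_exceeding_receiver_rejected(self):
        with pytest.raises(ValueError):
            dilution_factor(2.0, 2.0)


class TestForwardModel:
    def test_zero_papp_constant_concentration(self):
        assay = make_assay(sample_volume=0.0)
        predicted = forward_receiver_series(assay, 0.0)
        assert np.all(predicted == predicted[0])

    def test_large_papp_reaches_equilibrium(self):
        assay = make_assay(sample_volume=0.0)
        predicted = forward_receiver_series(assay, 1e-2)
        c_eq = assay.total_amount() / (assay.v_receiver + assay.v_donor)
        assert predicted[1:] == pytest.approx(c_eq, rel=1e-6)

    def test_matches_independent_ode_integration(self):
        # oracle: stiff-solver integration of the two-compartment system with
        # instantaneous sampling events
        papp = 3.83e-5
        assay = make_assay()
        predicted = forward_receiver_series(assay, papp)

        vr, vd, area = assay.v_receiver, assay.v_donor, assay.membrane_area
        q = assay.total_amount()
        m_r = 0.0
        oracle = [0.0]
        times = assay.sample_times
        q -= oracle[0] * assay.sample_volume  # t=0 sampling event
        m_r -= oracle[0] * assay.sample_volume
        for t0, t1 in zip(times, times[1:]):
            def rhs(_t, y):
                c_r, c_d = y[0] / vr, (q - y[0]) / vd
                return [papp * area * (c_d - c_r) * 60.0]  # per minute
            sol = solve_ivp(rhs, (t0, t1), [m_r], rtol=1e-10, atol=1e-12)
            m_r = sol.y[0, -1]
            c = m_r / vr
            oracle.append(c)
            removed = c * assay.sample_volume
            q -= removed
            m_r -= removed
        assert predicted[1:] == pytest.approx(np.array(oracle)[1:], rel=5e-3)

    def test_mass_conservation(self):
        papp = 5e-5
        assay = make_assay()
        predicted, sampled = forward_receiver_series(assay, papp,
                                                     return_masses=True)
        q0 = assay.total_amount()
        # in-system mass after the final sampling event
        f = dilution_factor(assay.v_receiver, assay.sample_volume)
        receiver_mass = predicted[-1] * f * assay.v_receiver
        # donor mass from closure of the recursion's own bookkeeping
        q_in_system = q0 - sampled.sum()
        donor_mass = q_in_system - receiver_mass
        assert receiver_mass + donor_mass + sampled.sum() == pytest.approx(
            q0, rel=1e-12)
        assert donor_mass > 0

    @pytest.mark.parametrize("papp_pair", [(1e-6, 2e-6), (1e-5, 5e-5),
                                           (5e-5, 2e-4)])
    def test_monotone_in_papp(self, papp_pair):
        assay = make_assay()
        low = forward_receiver_series(assay, papp_pair[0])
        high = forward_receiver_series(assay, papp_pair[1])
        assert np.all(high[1:] >= low[1:])


class TestFitPapp:
    @pytest.mark.parametrize("papp", [3.83e-5, 8.5e-6, 2.46e-5])
    def test_inverse_of_forward_is_identity(self, papp):
        result = fit_papp(make_assay(papp))
        assert result.papp == pytest.approx(papp, rel=1e-6)

    @pytest.mark.parametrize("vr,vd,times", [
        (2.0, 2.0, (0.0, 15.0, 30.0, 60.0, 90.0)),
        (1.5, 2.5, (0.0, 10.0, 20.0, 40.0, 80.0)),
        (3.0, 1.0, (0.0, 5.0, 30.0, 45.0, 120.0)),
    ])
    def test_identity_across_geometries(self, vr, vd, times):
        papp = 2.2e-5
        result = fit_papp(make_assay(papp, vr=vr, vd=vd, times=times))
        assert result.papp == pytest.approx(papp, rel=1e-6)

    def test_noisy_recovery(self):
        recovered = []
        for seed in range(100):
            ab, _, _ = gen_transwell(3.83e-5, noise_sd=0.02, seed=seed)
            recovered.append(fit_papp(ab).papp)
        median = float(np.median(recovered))
        assert abs(median - 3.83e-5) / 3.83e-5 < 0.05

    def test_all_zero_receiver_gives_zero_with_warning(self):
        result = fit_papp(make_assay())
        assert result.papp == 0.0
        assert result.warning is not None

    def test_concentration_scale_invariance(self):
        # expressing concentrations in nM instead of uM leaves papp unchanged
        papp = 2.2e-5
        assay = make_assay(papp)
        scaled = TranswellAssay(
            direction="A-B", v_receiver=assay.v_receiver,
            v_donor=assay.v_donor,
            receiver_concentrations=assay.receiver_concentrations * 1e3,
            sample_times=assay.sample_times,
            membrane_area=assay.membrane_area,
            sample_volume=assay.sample_volume,
            donor_concentrations=(1e5, 1e5))
        assert fit_papp(scaled).papp == pytest.approx(fit_papp(assay).papp,
                                                      rel=1e-9)


class TestEffluxAndReference:
    def test_equal_permeabilities_unity(self):
        assert efflux_ratio(1e-5, 1e-5) == pytest.approx(1.0)

    def test_published_style_ratios(self):
        assert efflux_ratio(0.85e-5, 3.83e-5) == pytest.approx(0.22, abs=0.005)
        assert efflux_ratio(0.28e-5, 2.46e-5) == pytest.approx(0.11, abs=0.005)

    def test_zero_absorptive_papp_rejected(self):
        with pytest.raises(ValueError):
            efflux_ratio(1e-5, 0.0)

    def test_boundary_is_high(self):
        assert compare_to_reference(2e-5, 2e-5) == ("high", 1.0)

    def test_zero_is_low(self):
        cls, ratio = compare_to_reference(0.0, 2e-5)
        assert cls == "low" and ratio == 0.0

    def test_double_reference_high(self):
        assert compare_to_reference(4e-5, 2e-5) == ("high", 2.0)

    def test_welch_comparison_detects_separation(self):
        a = [3.8, 3.9, 3.7, 3.85]
        b = [0.8, 0.9, 0.85, 0.88]
        _, p, significant = compare_groups(a, b)
        assert significant and p < 1e-4


class TestAssayValidation:
    def test_requires_total_amount_source(self):
        with pytest.raises(ValueError):
            TranswellAssay(direction="A-B", v_receiver=2.0, v_donor=2.0,
                           receiver_concentrations=np.zeros(5))

    def test_mass_balance_deviation_flagged(self):
        assay = make_assay(3.83e-5)
        bad = TranswellAssay(
            direction="A-B", v_receiver=2.0, v_donor=2.0,
            receiver_concentrations=assay.receiver_concentrations,
            sample_times=assay.sample_times,
            donor_concentrations=(100.0, 50.0))  # 50% loss
        result = fit_papp(bad)
        assert result.warning and "mass-balance" in result.warning
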