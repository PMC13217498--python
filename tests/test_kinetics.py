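"""Arrhenius rates, first-order inactivation, and the pectin system."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blanchsim import (
    ArrheniusRate,
    BiphasicInactivation,
    MonophasicInactivation,
    PectinParameters,
    PectinState,
    firmness,
    pectin_trajectory,
    rate_at,
    residual_activity,
)
from blanchsim import params as P
from blanchsim.errors import StepSizeError, ValidationError
from blanchsim.kinetics import GAS_CONSTANT

from oracles import arrhenius, biphasic_isothermal, monophasic_isothermal, pectin_isothermal


def const_history(temp_k, t_end=300.0, n=301):
    t = np.linspace(0.0, t_end, n)
    return t, np.full_like(t, temp_k)


class TestArrhenius:
    def test_reference_temperature_returns_k_ref(self):
        r = ArrheniusRate(0.05, 350.0, 2.5e5)
        assert rate_at(r, 350.0) == pytest.approx(0.05, rel=1e-14)

    def test_zero_energy_is_temperature_independent(self):
        r = ArrheniusRate(0.05, 350.0, 0.0)
        assert rate_at(r, 280.0) == rate_at(r, 400.0) == 0.05

    def test_pme_rate_at_90C_matches_direct_evaluation(self):
        r = P.pme_monophasic().rate
        expected = arrhenius(0.091, r.t_ref, 315e3, 363.15)
        assert rate_at(r, 363.15) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_temperature_rejected(self):
        r = ArrheniusRate(0.05, 350.0, 1e5)
        with pytest.raises(ValidationError):
            r.at(0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        ea=st.floats(1e4, 5e5),
        dT=st.floats(0.1, 60.0),
    )
    def test_rate_increases_with_temperature_for_positive_energy(self, ea, dT):
        r = ArrheniusRate(1e-3, 340.0, ea)
        assert r.at(340.0 + dT) > r.at(340.0)


class TestResidualActivity:
    def test_starts_at_one(self):
        t, temps = const_history(363.15)
        a = residual_activity(P.pme_monophasic(), t, temps)
        assert a[0] == 1.0

    def test_monophasic_constant_temperature_closed_form(self):
        model = P.pme_monophasic()
        t, temps = const_history(348.15, t_end=600.0)
        k = model.rate.at(348.15)
        assert np.allclose(
            residual_activity(model, t, temps), monophasic_isothermal(k, t), atol=1e-12
        )

    def test_biphasic_with_full_labile_fraction_degenerates_to_monophasic(self):
        lox = P.lox_biphasic()
        mono = MonophasicInactivation(lox.rate_labile)
        bi = BiphasicInactivation(1.0, lox.rate_labile, lox.rate_stable)
        t, temps = const_history(338.15, t_end=900.0)
        assert np.allclose(
            residual_activity(bi, t, temps), residual_activity(mono, t, temps), atol=1e-14
        )

    def test_biphasic_lox_at_70C_matches_two_exponential_closed_form(self):
        lox = P.lox_biphasic()
        t, temps = const_history(343.15, t_end=300.0)
        expected = biphasic_isothermal(
            lox.fraction_labile,
            arrhenius(0.36e-3, lox.rate_labile.t_ref, 282e3, 343.15),
            arrhenius(0.028, lox.rate_stable.t_ref, 96e3, 343.15),
            t,
        )
        assert np.allclose(residual_activity(lox, t, temps), expected, atol=1e-12)

    def test_non_monotone_history_rejected(self):
        with pytest.raises(ValidationError):
            residual_activity(
                P.pme_monophasic(), np.array([0.0, 10.0, 5.0]), np.full(3, 360.0)
            )

    def test_biphasic_lies_between_the_two_monophasic_decays(self, hot_field):
        lox = P.lox_biphasic()
        times = hot_field.times
        temps = hot_field.temperatures[:, 2] + 273.15
        a_bi = residual_activity(lox, times, temps)
        a_lab = residual_activity(MonophasicInactivation(lox.rate_labile), times, temps)
        a_sta = residual_activity(MonophasicInactivation(lox.rate_stable), times, temps)
        lo = np.minimum(a_lab, a_sta)
        hi = np.maximum(a_lab, a_sta)
        assert np.all(a_bi >= lo - 1e-12) and np.all(a_bi <= hi + 1e-12)

    def test_ice_bath_changes_activity_negligibly(self):
        """A 5-min hold at 2 C is kinetically inert for every packaged model.

        The high-energy POD/PME rates shut off entirely; the heat-stable LOX
        isoform (96 kJ/mol) retains a tiny residual rate, so the practical
        bound is 1 % rather than machine zero.
        """
        t, temps = const_history(275.15, t_end=300.0)
        for model in (P.pme_monophasic(), P.pod_biphasic()):
            a = residual_activity(model, t, temps)
            assert 1.0 - a[-1] < 1e-6
        a_lox = residual_activity(P.lox_biphasic(), t, temps)
        assert 1.0 - a_lox[-1] < 1e-2

    def test_higher_activation_energy_means_lower_activity_above_t_ref(self):
        t, temps = const_history(370.0, t_end=200.0)
        acts = []
        for ea in (1e5, 2e5, 3e5):
            model = MonophasicInactivation(ArrheniusRate(1e-3, 350.0, ea))
            acts.append(residual_activity(model, t, temps)[-1])
        assert acts[0] > acts[1] > acts[2]


class TestPectin:
    def test_zero_rates_freeze_the_state(self):
        pars = PectinParameters(
            ArrheniusRate(0.0, 350.0, 1e5),
            ArrheniusRate(0.0, 350.0, 1e5),
            ArrheniusRate(0.0, 350.0, 1e5),
        )
        t, temps = const_history(370.0, t_end=600.0)
        tr = pectin_trajectory(pars, t, temps)
        assert np.all(tr.pm == 0.8) and np.all(tr.pe == pytest.approx(0.2))
        assert np.all(tr.psol == 0.0) and np.all(tr.pme == 1.0)

    def test_pure_beta_elimination_closed_form(self):
        kb = ArrheniusRate(2e-4, 373.15, 200e3)
        pars = PectinParameters(
            kb, ArrheniusRate(0.0, 350.0, 0.0), ArrheniusRate(0.0, 350.0, 0.0)
        )
        t, temps = const_history(373.15, t_end=1200.0)
        tr = pectin_trajectory(pars, t, temps)
        assert np.allclose(tr.pm, 0.8 * np.exp(-2e-4 * t), atol=1e-10)
        assert np.allclose(tr.pe, 0.2, atol=1e-12)

    @pytest.mark.parametrize("method", ["splitting", "rk4"])
    def test_mass_conservation_and_monotonicity(self, method, hot_field):
        pars = P.texture_parameters()
        times = hot_field.times
        temps = hot_field.temperatures[:, 0] + 273.15
        if method == "rk4":
            # refine the grid so the fixed step respects the stiffness guard
            times = np.linspace(times[0], times[-1], 200001)
            temps = np.interp(times, hot_field.times, temps)
        tr = pectin_trajectory(pars, times, temps, method=method)
        assert np.abs(tr.pm + tr.pe + tr.psol - 1.0).max() < 1e-9
        assert np.all(np.diff(tr.pm) <= 1e-12)
        assert np.all(np.diff(tr.pme) <= 1e-12)
        assert np.all(np.diff(tr.pe) >= -1e-12)
        assert np.all(np.diff(tr.psol) >= -1e-12)

    def test_pme_pool_matches_monophasic_law(self):
        pars = P.texture_parameters()
        t, temps = const_history(358.15, t_end=120.0)
        tr = pectin_trajectory(pars, t, temps)
        _, pme_exact = pectin_isothermal(0.0, 0.0, pars.k_d.at(358.15), 0.8, t)
        assert np.allclose(tr.pme, pme_exact, atol=1e-10)

    def test_self_refinement_convergence(self):
        """10x finer fixed step changes every pool by < 1e-8 (2nd order)."""
        pars = P.texture_parameters()
        t_f = np.arange(0.0, 600.0001, 0.0005)
        t_c = t_f[::10]
        temps_f = np.full_like(t_f, 353.15)
        fine = pectin_trajectory(pars, t_f, temps_f, refine_cap=1)
        coarse = pectin_trajectory(pars, t_c, temps_f[::10], refine_cap=1)
        for pool in ("pm", "pe", "psol"):
            diff = np.abs(getattr(coarse, pool) - getattr(fine, pool)[::10]).max()
            assert diff < 1e-8, pool

    def test_splitting_agrees_with_rk4(self):
        pars = P.texture_parameters()
        t, temps = const_history(353.15, t_end=600.0, n=120001)
        a = pectin_trajectory(pars, t, temps, method="splitting")
        b = pectin_trajectory(pars, t, temps, method="rk4")
        for pool in ("pm", "pe", "psol", "pme"):
            assert np.abs(getattr(a, pool) - getattr(b, pool)).max() < 1e-8

    def test_rk4_stiffness_guard(self):
        pars = P.texture_parameters()
        t, temps = const_history(373.15, t_end=600.0, n=61)  # kd*dt >> 0.1
        with pytest.raises(StepSizeError):
            pectin_trajectory(pars, t, temps, method="rk4")

    def test_demethylation_conserves_nonsolubilized_pectin(self):
        """d(Pm+Pe)/dt = -k_beta*Pm: firmness loss is beta-elimination only."""
        pars = P.texture_parameters()
        t, temps = const_history(368.15, t_end=900.0, n=90001)
        tr = pectin_trajectory(pars, t, temps)
        kb = pars.k_beta.at(368.15)
        beta_integral = np.trapezoid(kb * tr.pm, t)
        assert 1.0 - (tr.pm[-1] + tr.pe[-1]) == pytest.approx(beta_integral, rel=1e-6)


class TestFirmness:
    def test_initial_state_gives_one(self):
        s0 = PectinState.initial(0.8)
        assert firmness(s0, s0) == 1.0

    def test_fully_solubilized_gives_zero(self):
        s0 = PectinState.initial(0.8)
        assert firmness(PectinState(0.0, 0.0, 1.0, 0.0), s0) == 0.0

    def test_half_solubilized_gives_half(self):
        s0 = PectinState.initial(0.8)
        assert firmness(PectinState(0.3, 0.2, 0.5, 0.1), s0) == pytest.approx(0.5)

    def test_zero_initial_pectin_rejected(self):
        with pytest.raises(ValidationError):
            firmness(PectinState(0, 0, 1, 0), PectinState(0.0, 0.0, 1.0, 1.0))

    def test_trajectory_firmness_starts_at_one_and_never_increases(self, hot_field):
        tr = pectin_trajectory(
            P.texture_parameters(), hot_field.times, hot_field.temperatures[:, 0] + 273.15
        )
        f = tr.firmness()
        assert f[0] == pytest.approx(1.0)
        assert np.all(np.diff(f) <= 1e-12)


class TestBiphasicConstruction:
    def test_ratio_and_fraction_parameterizations_agree(self):
        r1 = ArrheniusRate(1e-3, 340.0, 2e5)
        r2 = ArrheniusRate(1e-2, 340.0, 1e5)
        from_ratio = BiphasicInactivation.from_ratio(0.53, r1, r2)
        assert from_ratio.fraction_labile == pytest.approx(0.53 / 1.53)
        assert from_ratio.isoform_ratio == pytest.approx(0.53)
        assert from_ratio.parameterization == "ratio"

    def test_fraction_outside_unit_interval_rejected(self):
        r = ArrheniusRate(1e-3, 340.0, 2e5)
        with pytest.raises(ValidationError):
            BiphasicInactivation(1.2, r, r)
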