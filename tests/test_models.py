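"""Unit and property tests for the unfolding forward models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meltfit import (
    Baselines,
    KineticParams,
    R,
    T_STD,
    ThermoParams,
    dcp_neglect_error,
    equilibrium_fraction,
    equilibrium_signal,
    gibbs_free_energy,
    kinetic_signal,
    kinetic_xn,
    pku_std,
    t_eucl,
    t_onset,
)
from meltfit.models import unfolding_rate


class TestGibbsFreeEnergy:
    @pytest.mark.parametrize("dHm,Tm,dCp", [(1e5, 300, 0), (4e5, 330, 0), (9e5, 360, 5000)])
    def test_zero_at_midpoint(self, dHm, Tm, dCp):
        p = ThermoParams(dHm=dHm, Tm=Tm, dCp=dCp)
        assert gibbs_free_energy(p, Tm) == pytest.approx(0.0, abs=1e-9)

    def test_vant_hoff_value(self):
        # 400000 * (1 - 298.15/330) = 38606.06 J/mol
        p = ThermoParams(dHm=400_000.0, Tm=330.0)
        assert gibbs_free_energy(p, 298.15) == pytest.approx(38_606.06, abs=0.1)

    def test_heat_capacity_term(self):
        # adds dCp*(T - Tm - T ln(T/Tm)) = -7944.93 J/mol at 298.15 K
        p = ThermoParams(dHm=400_000.0, Tm=330.0, dCp=5000.0)
        assert gibbs_free_energy(p, 298.15) == pytest.approx(30_661.13, abs=1.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            gibbs_free_energy(ThermoParams(dHm=4e5, Tm=330.0), -1.0)


class TestEquilibriumSignal:
    def test_midpoint_is_baseline_average(self, thermo_params):
        b = thermo_params.baselines
        expected = 0.5 * (b.native(330.0) + b.unfolded(330.0))
        assert equilibrium_signal(thermo_params, 330.0) == pytest.approx(expected, rel=1e-12)

    def test_low_temperature_limit_is_native_baseline(self, thermo_params):
        T = 293.15
        native = thermo_params.baselines.native(T)
        assert equilibrium_signal(thermo_params, T) == pytest.approx(native, abs=1e-6)

    def test_fraction_signal_roundtrip(self, thermo_params, grid):
        # algebraic inversion: (signal - native)/(unfolded - native) == f_unf
        sig = np.asarray(equilibrium_signal(thermo_params, grid))
        b = thermo_params.baselines
        back = (sig - b.native(grid)) / b.separation(grid)
        assert np.allclose(back, equilibrium_fraction(thermo_params, grid), atol=1e-10)

    def test_overflow_safe_far_from_midpoint(self):
        p = ThermoParams(dHm=3.9e6, Tm=360.0)
        assert np.isfinite(equilibrium_signal(p, np.array([10.0, 200.0, 500.0]))).all()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        dHm=st.floats(1e5, 1e6),
        Tm=st.floats(300.0, 360.0),
    )
    def test_fraction_monotone_increasing(self, dHm, Tm):
        p = ThermoParams(dHm=dHm, Tm=Tm)
        T = np.linspace(293.15, 368.15, 151)
        f = np.asarray(equilibrium_fraction(p, T))
        assert np.all(np.diff(f) >= -1e-12)  # float rounding at saturation
        # strict away from float saturation at the extremes
        core = (f > 1e-6) & (f < 1 - 1e-6)
        assert np.all(np.diff(f[core]) > 0)


class TestKinetics:
    def test_starts_fully_folded(self, kinetic_params, grid):
        assert kinetic_xn(kinetic_params, grid)[0] == 1.0

    def test_monotone_nonincreasing_in_unit_interval(self, kinetic_params, grid):
        xn = kinetic_xn(kinetic_params, grid)
        assert np.all(np.diff(xn) <= 0)
        assert np.all((xn >= 0) & (xn <= 1))

    def test_closed_form_matches_rk4(self, kinetic_params):
        from _oracles import rk4_native_fraction

        T = np.arange(293.15, 368.15 + 0.05, 0.1)
        oracle = rk4_native_fraction(kinetic_params, T)
        assert np.max(np.abs(kinetic_xn(kinetic_params, T) - oracle)) < 1e-6

    def test_slower_scan_unfolds_more_per_kelvin(self, ratio_baselines, grid):
        p1 = KineticParams(Ea=3e5, Tf=350.0, v=1.0, baselines=ratio_baselines)
        p2 = KineticParams(Ea=3e5, Tf=350.0, v=2.0, baselines=ratio_baselines)
        assert np.all(kinetic_xn(p2, grid) >= kinetic_xn(p1, grid))

    def test_nonmonotonic_grid_rejected(self, kinetic_params):
        with pytest.raises(ValueError):
            kinetic_xn(kinetic_params, np.array([300.0, 299.0, 301.0]))

    def test_signal_is_baseline_mixture(self, ratio_baselines, grid):
        p = KineticParams(Ea=3e5, Tf=330.0, v=1.0, baselines=ratio_baselines)
        xn = kinetic_xn(p, grid)
        # fully folded region follows the native baseline
        pre = xn > 1 - 1e-9
        assert np.allclose(kinetic_signal(p, grid)[pre], ratio_baselines.native(grid)[pre])
        # with flat 0/1 baselines the signal is exactly 1 - x_N
        flat = KineticParams(Ea=3e5, Tf=330.0, v=1.0,
                             baselines=Baselines(0.0, 0.0, 0.0, 1.0))
        assert np.allclose(kinetic_signal(flat, grid), 1.0 - kinetic_xn(flat, grid))


class TestStabilityMeasureFormulas:
    def test_pku_zero_at_reference_tf(self):
        assert pku_std(KineticParams(Ea=3e5, Tf=298.15)) == pytest.approx(0.0, abs=1e-12)

    def test_pku_known_value(self):
        # -log10 exp(-Ea/R * (1/298.15 - 1/350))
        assert pku_std(KineticParams(Ea=3e5, Tf=350.0)) == pytest.approx(7.79, abs=0.01)

    def test_pku_increases_with_tf(self):
        vals = [pku_std(KineticParams(Ea=3e5, Tf=tf)) for tf in np.linspace(300, 380, 9)]
        assert np.all(np.diff(vals) > 0)

    def test_onset_at_half_fraction_is_tm(self, thermo_params):
        T, extrapolated = t_onset(thermo_params, onset_fraction=0.499999)
        assert not extrapolated
        assert T == pytest.approx(thermo_params.Tm, abs=1e-2)

    def test_onset_self_consistent(self, thermo_params):
        T, _ = t_onset(thermo_params, onset_fraction=0.01)
        assert equilibrium_fraction(thermo_params, T) == pytest.approx(0.01, abs=1e-6)

    def test_steeper_transition_has_later_onset(self):
        onsets = [
            t_onset(ThermoParams(dHm=h, Tm=330.0))[0] for h in (1e5, 3e5, 6e5, 1e6)
        ]
        assert np.all(np.diff(onsets) > 0)

    def test_onset_below_scan_start_flagged(self):
        p = ThermoParams(dHm=1e5, Tm=300.0)
        T, extrapolated = t_onset(p, t_min=299.0)
        assert extrapolated and T == 299.0

    def test_teucl_value_and_symmetry(self):
        assert t_eucl(330.0, 320.0) == pytest.approx(459.67, abs=0.01)
        assert t_eucl(320.0, 330.0) == t_eucl(330.0, 320.0)
        assert t_eucl(345.0, 0.0) == 345.0


class TestDcpNeglectError:
    def test_known_value(self):
        assert dcp_neglect_error(5000.0, 298.15, 330.0) == pytest.approx(-7944.93, abs=1.0)

    def test_always_negative_below_tm(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            Tm = rng.uniform(300.0, 380.0)
            Tref = rng.uniform(250.0, Tm - 1e-3)
            dCp = rng.uniform(100.0, 20_000.0)
            assert dcp_neglect_error(dCp, Tref, Tm) < 0

    def test_zero_dcp_gives_zero(self):
        assert dcp_neglect_error(0.0, 298.15, 330.0) == 0.0

    def test_reference_above_midpoint_rejected(self):
        with pytest.raises(ValueError):
            dcp_neglect_error(5000.0, 330.0, 298.15)
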