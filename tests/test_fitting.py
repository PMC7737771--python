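"""Tests for the nonlinear fit engine: initialization, recovery, quality
metrics and reliability filtering."""

import math

import numpy as np
import pytest

from meltfit import (
    Baselines,
    FitError,
    SimSpec,
    ThermoParams,
    bs_factor,
    fallback_tm,
    fit_curve,
    fraction_unfolded_curve,
    select_readout,
)
from meltfit.fitting import (
    FLAG_NO_POST_BASELINE,
    FLAG_NO_TRANSITION,
    FLAG_UNRELIABLE_TM_SD,
    FitResult,
)
from meltfit.models import equilibrium_fraction
from meltfit.simulate import default_grid, simulate_curve


class TestThermodynamicFit:
    def test_noiseless_recovery(self, ratio_baselines):
        spec = SimSpec(dHm=350_000.0, Tm=325.0, baselines=ratio_baselines, seed=0)
        curve, truth = simulate_curve(spec)
        fit = fit_curve(curve, "thermodynamic")
        assert fit.success
        assert fit.params.Tm == pytest.approx(325.0, abs=0.01)
        assert fit.params.dHm == pytest.approx(350_000.0, rel=1e-3)
        assert fit.S < 1e-6
        assert FLAG_UNRELIABLE_TM_SD not in fit.flags

    def test_noisy_tm_within_three_sd(self, ratio_baselines):
        hits = 0
        for seed in range(20):
            spec = SimSpec(dHm=350_000.0, Tm=325.0, baselines=ratio_baselines,
                           noise_sd=0.0015, seed=seed)
            curve, _ = simulate_curve(spec, sample_id=f"n{seed}")
            fit = fit_curve(curve, "thermodynamic")
            assert fit.success
            if abs(fit.params.Tm - 325.0) <= 3 * fit.param_sd["Tm"]:
                hits += 1
        assert hits >= 19

    def test_flat_line_not_fitted(self):
        from meltfit import MeltingCurve

        curve = MeltingCurve("flat", default_grid(), np.full(151, 0.8))
        fit = fit_curve(curve, "thermodynamic")
        assert not fit.success
        assert FLAG_NO_TRANSITION in fit.flags

    def test_z_curve_recovery(self, ratio_baselines):
        # falling signal (e.g. F330): same transition, negated orientation
        b = Baselines(k_N=-2e-4, b_N=1.0 + 2e-4 * 330, k_U=-3e-4, b_U=0.8 + 3e-4 * 330)
        spec = SimSpec(dHm=450_000.0, Tm=335.0, baselines=b, seed=0)
        curve, _ = simulate_curve(spec)
        fit = fit_curve(curve, "thermodynamic")
        assert fit.success
        assert fit.params.Tm == pytest.approx(335.0, abs=0.01)


class TestKineticFit:
    def test_noiseless_recovery(self, ratio_baselines):
        spec = SimSpec(model="kinetic", Ea=300_000.0, Tf=340.0,
                       baselines=ratio_baselines, seed=0)
        curve, _ = simulate_curve(spec)
        fit = fit_curve(curve, "kinetic")
        assert fit.success
        assert fit.params.Tf == pytest.approx(340.0, abs=0.01)
        assert fit.params.Ea == pytest.approx(300_000.0, rel=1e-3)

    def test_scan_rate_enters_fit(self, ratio_baselines):
        spec = SimSpec(model="kinetic", Ea=300_000.0, Tf=340.0, scan_rate=2.0,
                       baselines=ratio_baselines, seed=0)
        curve, _ = simulate_curve(spec)
        assert curve.scan_rate == 2.0
        fit = fit_curve(curve, "kinetic")
        assert fit.params.Tf == pytest.approx(340.0, abs=0.05)


class TestEmpiricalFit:
    def test_tm_identical_to_thermodynamic(self, noisy_curve):
        curve, _ = noisy_curve
        thermo = fit_curve(curve, "thermodynamic")
        emp = fit_curve(curve, "empirical")
        assert emp.params.Tm == thermo.params.Tm  # same underlying fit
        assert emp.empirical is not None
        assert emp.empirical.Tonset < emp.params.Tm
        assert emp.empirical.Teucl == pytest.approx(
            math.hypot(emp.params.Tm, emp.empirical.Tonset)
        )


class TestBsFactor:
    def setup_method(self):
        self.params = ThermoParams(
            dHm=4e5, Tm=330.0,
            baselines=Baselines(k_N=0.0, b_N=0.8, k_U=0.0, b_U=0.86),
        )  # separation 0.06

    def test_perfect_fit_scores_one(self):
        assert bs_factor(0.0, self.params) == 1.0

    def test_zero_at_one_sixth_separation(self):
        assert bs_factor(0.01, self.params) == pytest.approx(0.0, abs=1e-12)

    def test_half_at_known_value(self):
        assert bs_factor(0.005, self.params) == pytest.approx(0.5)

    def test_z_curve_scores_like_s_curve(self):
        flipped = ThermoParams(
            dHm=4e5, Tm=330.0,
            baselines=Baselines(k_N=0.0, b_N=0.86, k_U=0.0, b_U=0.8),
        )
        assert bs_factor(0.005, flipped) == bs_factor(0.005, self.params)

    def test_zero_separation_sentinel(self):
        degenerate = ThermoParams(
            dHm=4e5, Tm=330.0, baselines=Baselines(0.0, 0.8, 0.0, 0.8)
        )
        assert bs_factor(0.005, degenerate) == -math.inf


class TestFractionUnfolded:
    def test_inversion_identity_on_noiseless_curve(self, clean_curve):
        curve, _ = clean_curve
        fit = fit_curve(curve, "thermodynamic")
        frac = fraction_unfolded_curve(curve, fit.params)
        model = equilibrium_fraction(fit.params, curve.temperature)
        assert np.max(np.abs(frac - model)) < 1e-6

    def test_pretransition_baseline_maps_to_zero(self, ratio_baselines):
        from meltfit import MeltingCurve

        T = default_grid()
        curve = MeltingCurve("base", T, np.asarray(ratio_baselines.native(T)))
        p = ThermoParams(dHm=4e5, Tm=330.0, baselines=ratio_baselines)
        assert np.max(np.abs(fraction_unfolded_curve(curve, p))) < 1e-12

    def test_baseline_midpoint_signal_maps_to_half(self, ratio_baselines):
        from meltfit import MeltingCurve

        T = default_grid()
        mid = 0.5 * (np.asarray(ratio_baselines.native(T)) + np.asarray(ratio_baselines.unfolded(T)))
        curve = MeltingCurve("mid", T, mid)
        p = ThermoParams(dHm=4e5, Tm=330.0, baselines=ratio_baselines)
        frac = fraction_unfolded_curve(curve, p)
        assert np.allclose(frac, 0.5, atol=1e-12)

    def test_intersecting_baselines_rejected(self):
        from meltfit import MeltingCurve

        T = default_grid()
        cross = float(T[74])  # a grid point
        bad = ThermoParams(
            dHm=4e5, Tm=330.0,
            baselines=Baselines(1e-3, 0.5 - 1e-3 * cross, -1e-3, 0.5 + 1e-3 * cross),
        )
        curve = MeltingCurve("x", T, np.ones(T.size))
        with pytest.raises(FitError):
            fraction_unfolded_curve(curve, bad)


class TestFallbackTm:
    def test_truncated_curve_uses_derivative_peak(self, ratio_baselines):
        spec = SimSpec(dHm=400_000.0, Tm=355.0, baselines=ratio_baselines,
                       noise_sd=0.0015, seed=2)
        curve, truth = simulate_curve(spec, truncate_at_fraction=0.6)
        assert curve.t_max < 360.0  # post-transition baseline missing
        tm, flags = fallback_tm(curve)
        assert FLAG_NO_POST_BASELINE in flags
        # derivative peak of a truncated sigmoid sits at/below the true Tm
        assert tm == pytest.approx(truth["Tm"], abs=2.0)

    def test_flat_curve_flags_no_transition(self):
        from meltfit import MeltingCurve

        curve = MeltingCurve("flat", default_grid(), np.full(151, 0.8))
        tm, flags = fallback_tm(curve)
        assert FLAG_NO_TRANSITION in flags and math.isnan(tm)


class TestReadoutSelection:
    @staticmethod
    def result(bs):
        r = FitResult(model="thermodynamic", sample_id="s",
                      params=ThermoParams(dHm=4e5, Tm=330.0))
        r.BS = bs
        return r

    def test_good_ratio_kept(self):
        assert select_readout({"ratio": self.result(0.8), "F330": self.result(0.9)}) == "ratio"

    def test_poor_ratio_switches_to_f330(self):
        assert select_readout({"ratio": self.result(0.1), "F330": self.result(0.7)}) == "F330"

    def test_margin_not_met_keeps_ratio(self):
        assert select_readout({"ratio": self.result(0.2), "F330": self.result(0.22)}) == "ratio"

    def test_all_failed_raises(self):
        failed = FitResult(model="thermodynamic", sample_id="s")
        failed.flags.add("fit_failed")
        with pytest.raises(FitError):
            select_readout({"ratio": failed})


class TestCovarianceScaling:
    def test_tm_sd_shrinks_with_point_count(self, ratio_baselines):
        """Reported SD(T_m) scales roughly as 1/sqrt(N) at fixed noise."""
        sds = []
        for step, reps in ((1.0, 0), (0.25, 0)):
            spec = SimSpec(dHm=350_000.0, Tm=330.0, baselines=ratio_baselines,
                           noise_sd=0.0015, step=step, seed=11)
            curve, _ = simulate_curve(spec)
            fit = fit_curve(curve, "thermodynamic")
            sds.append(fit.param_sd["Tm"])
        # 4x the points -> about half the SD
        assert sds[1] / sds[0] == pytest.approx(0.5, abs=0.2)
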