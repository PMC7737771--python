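"""Bounded nonlinear least-squares fitting of unfolding models to curves.

Initialization follows the derivative/baseline estimates from
:mod:`meltfit.preprocess`; the transition enthalpy (or activation energy)
always starts at 100,000 J/mol, which is robust across typical proteins.
Bounds: the midpoint temperature is confined to the scan range, ΔH_m to
60–4,000 kJ/mol, E_a to 10–4,000 kJ/mol; baselines are unbounded.

Fit quality is summarized by the standard error of estimate
S = sqrt(Σ(F_exp − F_fit)² / (N − n)) and the baseline-separation factor
BS = 1 − 6·S/|baseline gap at T_m| (0.5–1 excellently separated, negative
unreliable).  Parameter SDs come from the covariance of the least-squares
Jacobian; a fitted T_m with SD above 0.5 K is flagged unreliable (the
record is flagged, not deleted, so screens remain auditable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

from . import models
from .curves import CurveError, MeltingCurve
from .models import Baselines, EmpiricalResult, KineticParams, ThermoParams
from .preprocess import (
    CurveShape,
    estimate_shape_and_baselines,
    looks_flat,
    savgol_derivative,
)

# flag vocabulary
FLAG_UNRELIABLE_TM_SD = "unreliable_tm_sd"
FLAG_NO_TRANSITION = "no_transition"
FLAG_ONSET_EXTRAPOLATED = "onset_extrapolated"
FLAG_NO_POST_BASELINE = "no_post_baseline"
FLAG_FIT_FAILED = "fit_failed"
FLAG_FRACTION_OUT_OF_RANGE = "fraction_out_of_range"

#: SD(T_m) above this value (kelvin) marks a fit as unreliable.
TM_SD_LIMIT = 0.5

DHM_INIT = 100_000.0  # J/mol
DHM_BOUNDS = (60_000.0, 4_000_000.0)  # J/mol
EA_INIT = 100_000.0  # J/mol, symmetric to the enthalpy choice
EA_BOUNDS = (10_000.0, 4_000_000.0)  # J/mol


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Outcome of fitting one model to one curve."""

    model: str  # thermodynamic | kinetic | empirical
    sample_id: str
    params: ThermoParams | KineticParams | None = None
    param_sd: dict[str, float] = field(default_factory=dict)
    S: float = math.nan
    BS: float = math.nan
    n_points: int = 0
    n_params: int = 0
    flags: set[str] = field(default_factory=set)
    empirical: EmpiricalResult | None = None
    t_scan_min: float = math.nan
    t_scan_max: float = math.nan

    @property
    def success(self) -> bool:
        return self.params is not None and FLAG_FIT_FAILED not in self.flags


def bs_factor(S: float, params: ThermoParams | KineticParams, Tm: float | None = None) -> float:
    """Baseline-separation factor 1 − 6·S/|k_U·T_m + b_U − k_N·T_m − b_N|.

    The absolute value in the denominator makes S- and Z-shaped curves
    score identically.  Zero separation returns −inf (no distinguishable
    transition).
    """
    if Tm is None:
        Tm = params.Tm if isinstance(params, ThermoParams) else params.Tf
    sep = abs(float(params.baselines.separation(Tm)))
    if sep == 0.0:
        return -math.inf
    return 1.0 - 6.0 * S / sep


def _thermo_predict(T, dHm, Tm, k_N, b_N, k_U, b_U, dCp=0.0):
    p = ThermoParams(dHm=dHm, Tm=Tm, dCp=dCp, baselines=Baselines(k_N, b_N, k_U, b_U))
    return models.equilibrium_signal(p, T)


def _make_kinetic_predict(v: float):
    def predict(T, Ea, Tf, k_N, b_N, k_U, b_U):
        p = KineticParams(Ea=Ea, Tf=Tf, v=v, baselines=Baselines(k_N, b_N, k_U, b_U))
        return models.kinetic_signal(p, T)

    return predict


def fit_curve(
    curve: MeltingCurve,
    model: str = "thermodynamic",
    shape: CurveShape | None = None,
    dCp: float = 0.0,
    onset_fraction: float = 0.01,
    max_nfev: int = 5000,
) -> FitResult:
    """Fit one unfolding model to a preprocessed curve.

    ``model`` is "thermodynamic", "kinetic" or "empirical" (the empirical
    result is derived from the thermodynamic fit: identical T_m, plus the
    onset temperature at ``onset_fraction`` unfolded and T_eucl).  ``dCp``
    is held fixed, not fitted.  Curves flagged as having no transition are
    not fitted.
    """
    if model not in ("thermodynamic", "kinetic", "empirical"):
        raise ValueError(f"unknown model {model!r}")
    curve.validate()
    if shape is None:
        shape = estimate_shape_and_baselines(curve)

    result = FitResult(
        model=model,
        sample_id=curve.sample_id,
        n_points=len(curve),
        t_scan_min=curve.t_min,
        t_scan_max=curve.t_max,
    )
    if shape.no_transition:
        result.flags |= {FLAG_NO_TRANSITION, FLAG_FIT_FAILED}
        return result

    T, S_exp = curve.temperature, curve.signal
    base0 = (shape.k_N, shape.b_N, shape.k_U, shape.b_U)
    unb = (-np.inf, np.inf)
    if model == "kinetic":
        predict = _make_kinetic_predict(curve.scan_rate)
        p0 = [EA_INIT, shape.tm_initial, *base0]
        lo = [EA_BOUNDS[0], curve.t_min, *[unb[0]] * 4]
        hi = [EA_BOUNDS[1], curve.t_max, *[unb[1]] * 4]
        names = ["Ea", "Tf", "k_N", "b_N", "k_U", "b_U"]
    else:
        predict = lambda T, dHm, Tm, k_N, b_N, k_U, b_U: _thermo_predict(  # noqa: E731
            T, dHm, Tm, k_N, b_N, k_U, b_U, dCp=dCp
        )
        p0 = [DHM_INIT, shape.tm_initial, *base0]
        lo = [DHM_BOUNDS[0], curve.t_min, *[unb[0]] * 4]
        hi = [DHM_BOUNDS[1], curve.t_max, *[unb[1]] * 4]
        names = ["dHm", "Tm", "k_N", "b_N", "k_U", "b_U"]

    result.n_params = len(p0)
    try:
        popt, pcov = curve_fit(
            predict, T, S_exp, p0=p0, bounds=(lo, hi), method="trf", max_nfev=max_nfev
        )
    except (RuntimeError, ValueError):
        result.flags.add(FLAG_FIT_FAILED)
        return result

    sd = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(popt)) or not np.all(np.isfinite(sd)):
        result.flags.add(FLAG_FIT_FAILED)
        return result

    baselines = Baselines(*popt[2:])
    if model == "kinetic":
        params: ThermoParams | KineticParams = KineticParams(
            Ea=float(popt[0]), Tf=float(popt[1]), v=curve.scan_rate, baselines=baselines
        )
        midpoint_name = "Tf"
    else:
        params = ThermoParams(
            dHm=float(popt[0]), Tm=float(popt[1]), dCp=dCp, baselines=baselines
        )
        midpoint_name = "Tm"

    resid = S_exp - np.asarray(predict(T, *popt))
    dof = len(curve) - len(popt)
    S = float(np.sqrt(np.sum(resid**2) / dof))

    result.params = params
    result.param_sd = dict(zip(names, sd.astype(float)))
    result.S = S
    result.BS = bs_factor(S, params)
    if result.BS == -math.inf:
        result.flags.add(FLAG_NO_TRANSITION)
    if result.param_sd[midpoint_name] > TM_SD_LIMIT:
        result.flags.add(FLAG_UNRELIABLE_TM_SD)

    if model == "empirical":
        if params.Tm <= curve.t_min:
            tonset, extrapolated = curve.t_min, True
        else:
            tonset, extrapolated = models.t_onset(
                params, onset_fraction=onset_fraction, t_min=curve.t_min
            )
        if extrapolated:
            result.flags.add(FLAG_ONSET_EXTRAPOLATED)
        result.empirical = EmpiricalResult(
            Tm=params.Tm,
            Tonset=tonset,
            onset_fraction=onset_fraction,
            Teucl=models.t_eucl(params.Tm, tonset),
            onset_extrapolated=extrapolated,
        )
    return result


def fraction_unfolded_curve(curve: MeltingCurve, params: ThermoParams) -> np.ndarray:
    """Baseline-corrected experimental fraction unfolded,
    (Signal − k_N·T − b_N)/(k_U·T + b_U − k_N·T − b_N).

    Values are deliberately not clamped to [0, 1]: small excursions expose
    noise.  A zero baseline separation anywhere in the scan is an error.
    """
    T = curve.temperature
    denom = np.asarray(params.baselines.separation(T))
    if np.min(np.abs(denom)) <= 1e-12 * max(1.0, float(np.max(np.abs(denom)))):
        raise FitError(f"{curve.sample_id}: baselines intersect within the scan range")
    return (curve.signal - np.asarray(params.baselines.native(T))) / denom


def fraction_out_of_range(frac: np.ndarray, limit: float = 1.5) -> bool:
    """True when any baseline-corrected fraction exceeds ``limit`` in
    magnitude (a sign of poor baselines or non-two-state behavior)."""
    return bool(np.any(np.abs(frac) > limit))


def fallback_tm(curve: MeltingCurve, shape: CurveShape | None = None) -> tuple[float, set[str]]:
    """Derivative-peak T_m for curves without a post-transition baseline.

    When the full fit fails (typically because the scan ends inside the
    transition), the melting temperature is estimated from the extremum of
    the Savitzky–Golay derivative and flagged ``no_post_baseline``.  No
    free-energy, kinetic or empirical measure is derived from such an
    estimate.  Flat curves yield ``no_transition``.
    """
    if shape is None:
        try:
            shape = estimate_shape_and_baselines(curve)
        except CurveError:
            shape = None
    if shape is not None and shape.no_transition:
        return math.nan, {FLAG_NO_TRANSITION}
    if shape is None and looks_flat(curve.temperature, curve.signal):
        return math.nan, {FLAG_NO_TRANSITION}

    deriv = savgol_derivative(curve)
    signed = deriv if (shape is None or shape.kind == "S") else -deriv
    tm = float(curve.temperature[int(np.argmax(signed))])
    return tm, {FLAG_NO_POST_BASELINE}


def select_readout(
    results_by_readout: Mapping[str, FitResult],
    bs_threshold: float = 0.25,
    margin: float = 0.1,
    preferred: str = "ratio",
    alternate: str = "F330",
) -> str:
    """Choose which readout's fit to report for a sample.

    The fluorescence ratio is preferred; the single-wavelength F330 fit is
    used instead only when the ratio's baseline separation is suboptimal
    (BS below ``bs_threshold``) and F330 improves on it by at least
    ``margin``.  If the preferred readout failed outright, the best
    successful fit by BS-factor wins.
    """
    ok = {k: r for k, r in results_by_readout.items() if r.success}
    if not ok:
        raise FitError("all readout fits failed")
    if preferred in ok:
        pref = ok[preferred]
        alt = ok.get(alternate)
        if (
            alt is not None
            and pref.BS < bs_threshold
            and alt.BS >= pref.BS + margin
        ):
            return alternate
        return preferred
    return max(ok, key=lambda k: ok[k].BS)
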