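"""Isothermal chemical-denaturation analysis and the ΔC_p bridge between
thermal and chemical unfolding.

Signal versus denaturant concentration at fixed temperature is fitted to
the six-parameter linear-extrapolation model (Santoro & Bolen): linear
native and unfolded baselines in concentration, and a two-state
transition with ΔG_u(c) = ΔG°′ − m·c.  ΔC_p is estimated independently as
the slope of ΔH_m versus T_m across denaturant concentrations
(Kirchhoff's relation (∂ΔH/∂T)_p = ΔC_p), which lets the ΔC_p-neglect
error of a thermal-only ΔG_u°′ be corrected and reconciled with the
chemical ΔG°′.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .models import R, T_STD, dcp_neglect_error
from .ranking import StabilityRecord

_EXP_CLAMP = 700.0


class ChemFitError(RuntimeError):
    pass


@dataclass
class DenaturationSeries:
    """Signal versus denaturant concentration at a fixed temperature."""

    conc: np.ndarray  # mol/L, increasing, starting at 0
    signal: np.ndarray
    denaturant: str = "urea"  # urea | GuHCl | other
    temperature: float = T_STD  # K

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.conc.shape != self.signal.shape:
            raise ChemFitError("conc/signal length mismatch")
        if np.any(self.conc < 0) or np.any(np.diff(self.conc) <= 0):
            raise ChemFitError("concentrations must be nonnegative and increasing")
        if self.conc[0] != 0.0:
            raise ChemFitError("series must include a zero-denaturant point")


@dataclass
class LemResult:
    """Linear-extrapolation fit: ΔG°′ at zero denaturant, the m-value,
    and linear baselines in concentration."""

    dG0: float  # J/mol
    m_value: float  # J/mol per mol/L
    a_N: float
    s_N: float
    a_U: float
    s_U: float
    temperature: float
    param_sd: dict[str, float] = field(default_factory=dict)

    @property
    def c_half(self) -> float:
        """Midpoint denaturant concentration, mol/L."""
        return self.dG0 / self.m_value


def santoro_bolen_signal(c, dG0, m, a_N, s_N, a_U, s_U, T: float = T_STD):
    """Forward model: Signal(c) = [(a_N + s_N·c) + (a_U + s_U·c)·K] / (1 + K)
    with K = exp((m·c − ΔG°′)/(R·T))."""
    c = np.asarray(c, dtype=float)
    K = np.exp(np.clip((m * c - dG0) / (R * T), -_EXP_CLAMP, _EXP_CLAMP))
    return ((a_N + s_N * c) + (a_U + s_U * c) * K) / (1.0 + K)


def fit_santoro_bolen(series: DenaturationSeries, max_nfev: int = 5000) -> LemResult:
    """Fit the six-parameter linear-extrapolation model to a series.

    Initialization: end-stretch lines (first/last three points) for the
    baselines, the steepest-change concentration for the midpoint, and an
    m-value from the normalized steepness.  Requires at least eight
    concentrations spanning the transition.
    """
    c, s = series.conc, series.signal
    if c.size < 8:
        raise ChemFitError("need at least 8 concentrations")
    if np.ptp(s) == 0.0:
        raise ChemFitError("no transition: signal is constant")

    s_N0, a_N0 = np.polyfit(c[:3], s[:3], 1)
    s_U0, a_U0 = np.polyfit(c[-3:], s[-3:], 1)
    # steepest change of the normalized signal locates the midpoint
    grad = np.gradient(s, c)
    norm = (a_U0 + s_U0 * c.mean()) - (a_N0 + s_N0 * c.mean())
    if norm == 0.0:
        raise ChemFitError("no transition: baselines coincide")
    i_mid = int(np.argmax(np.abs(grad)))
    c_half0 = float(c[i_mid])
    if c_half0 <= 0:
        raise ChemFitError("no transition within the concentration range")
    # |d f_unf/dc| at the midpoint is m/(4RT)
    m0 = max(float(abs(grad[i_mid] / norm)) * 4.0 * R * series.temperature, 500.0)
    dG00 = m0 * c_half0

    T = series.temperature

    def predict(cc, dG0, m, a_N, s_N, a_U, s_U):
        return santoro_bolen_signal(cc, dG0, m, a_N, s_N, a_U, s_U, T=T)

    p0 = [dG00, m0, a_N0, s_N0, a_U0, s_U0]
    lo = [-np.inf, 1e-9, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [np.inf] * 6
    try:
        popt, pcov = curve_fit(predict, c, s, p0=p0, bounds=(lo, hi), max_nfev=max_nfev)
    except (RuntimeError, ValueError) as exc:
        raise ChemFitError(f"fit did not converge: {exc}") from exc
    sd = np.sqrt(np.diag(pcov))
    names = ["dG0", "m_value", "a_N", "s_N", "a_U", "s_U"]
    return LemResult(
        dG0=float(popt[0]),
        m_value=float(popt[1]),
        a_N=float(popt[2]),
        s_N=float(popt[3]),
        a_U=float(popt[4]),
        s_U=float(popt[5]),
        temperature=T,
        param_sd=dict(zip(names, sd.astype(float))),
    )


def dcp_from_dhm_tm(points) -> tuple[float, float]:
    """ΔC_p from the slope of ΔH_m versus T_m (Kirchhoff).

    ``points`` is a sequence of (T_m kelvin, ΔH_m J/mol) pairs from fits
    at different denaturant concentrations.  Returns (slope, slope SD) in
    J/(mol K).  Requires at least three points with ≥2 K of T_m spread.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 3:
        raise ChemFitError("need at least 3 (Tm, dHm) points")
    tm, dhm = pts[:, 0], pts[:, 1]
    if np.ptp(tm) < 2.0:
        raise ChemFitError("insufficient Tm range (<2 K)")
    res = linregress(tm, dhm)
    return float(res.slope), float(res.stderr)


@dataclass
class ReconcileReport:
    """Comparison of thermal and chemical estimates of ΔG_u°′."""

    dG_thermal_uncorrected: float  # J/mol, ΔC_p neglected
    dG_thermal_corrected: float  # J/mol, ΔC_p-neglect error added back
    dG_chemical: float  # J/mol, from linear extrapolation
    dCp: float  # J/(mol K)
    correction: float  # J/mol (the ΔC_p-neglect error; negative)
    diff_uncorrected: float  # thermal(ΔC_p=0) − chemical
    diff_corrected: float  # thermal(corrected) − chemical


def reconcile_thermal_chemical(
    thermal: StabilityRecord, chem: LemResult, dCp: float, Tref: float = T_STD
) -> ReconcileReport:
    """Reconcile a thermal-unfolding ΔG_u°′ (fitted with ΔC_p = 0) with a
    chemical-unfolding ΔG°′ by restoring the neglected ΔC_p term.

    The corrected thermal value adds the (negative) ΔC_p-neglect error,
    so uncorrected − corrected = −error exactly.
    """
    if math.isnan(thermal.dG_std):
        raise ValueError("thermal record lacks ΔG_u°′")
    correction = dcp_neglect_error(dCp, Tref, thermal.Tm) if dCp != 0.0 else 0.0
    corrected = thermal.dG_std + correction
    return ReconcileReport(
        dG_thermal_uncorrected=thermal.dG_std,
        dG_thermal_corrected=corrected,
        dG_chemical=chem.dG0,
        dCp=dCp,
        correction=correction,
        diff_uncorrected=thermal.dG_std - chem.dG0,
        diff_corrected=corrected - chem.dG0,
    )
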