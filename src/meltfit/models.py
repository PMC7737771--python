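"""Forward models of two-state protein unfolding.

Three parameterizations of a sigmoidal unfolding curve observed in a
thermal-ramp experiment (e.g. nanoDSF intrinsic-fluorescence ratio):

* **Equilibrium thermodynamic** — reversible two-state N ⇌ U with the
  Gibbs–Helmholtz temperature dependence of the unfolding free energy
  ΔG_u(T) = ΔH_m·(1 − T/T_m) + ΔC_p·(T − T_m − T·ln(T/T_m)).
* **Kinetic** — irreversible first-order unfolding N → U with an
  Arrhenius-type rate k_u(T) = exp(−E_a/R·(1/T − 1/T_f)); the native
  fraction x_N follows dx_N/dT = −k_u(T)·x_N / v at scan rate v.
* **Empirical** — the transition summarized by its midpoint T_m and onset
  T_onset, combined into T_eucl = sqrt(T_m² + T_onset²).

All temperatures are kelvin, energies J/mol.  The observable signal is a
baseline-weighted mixture of linear native and unfolded baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

#: Universal gas constant, J/(mol K).
R = 8.314

#: Standard reference temperature (25 °C), K.  Stability measures
#: (ΔG_u°′, pk_u°′) are extrapolated to this temperature at 100 kPa.
T_STD = 298.15

# exp() argument clamp; avoids overflow for very steep transitions
_EXP_CLAMP = 700.0


@dataclass
class Baselines:
    """Linear pre- and post-transition baselines of the observed signal.

    ``k_N``/``b_N`` are slope and intercept of the native-state signal,
    ``k_U``/``b_U`` of the unfolded-state signal (signal units per K and
    signal units respectively).
    """

    k_N: float = 0.0
    b_N: float = 0.0
    k_U: float = 0.0
    b_U: float = 1.0

    def native(self, T):
        return self.k_N * np.asarray(T, dtype=float) + self.b_N

    def unfolded(self, T):
        return self.k_U * np.asarray(T, dtype=float) + self.b_U

    def separation(self, T):
        """Signed distance between the baselines at temperature ``T``."""
        return (self.k_U - self.k_N) * np.asarray(T, dtype=float) + (self.b_U - self.b_N)


@dataclass
class ThermoParams:
    """Equilibrium two-state parameters.

    ``dHm`` — van't Hoff unfolding enthalpy at the midpoint, J/mol (> 0);
    ``Tm`` — midpoint temperature, K; ``dCp`` — heat-capacity change of
    unfolding, J/(mol K), held fixed during fitting (0 by default: the
    pure van't Hoff two-state model).
    """

    dHm: float
    Tm: float
    dCp: float = 0.0
    baselines: Baselines = field(default_factory=Baselines)

    def validate(self) -> None:
        if not self.dHm > 0:
            raise ValueError(f"dHm must be positive, got {self.dHm}")
        if not self.Tm > 0:
            raise ValueError(f"Tm must be positive, got {self.Tm}")


@dataclass
class KineticParams:
    """Irreversible-unfolding parameters.

    ``Ea`` — activation energy, J/mol; ``Tf`` — temperature at which the
    unfolding rate constant k_u equals 1 (per minute), K; ``v`` — scan
    rate, K/min.
    """

    Ea: float
    Tf: float
    v: float = 1.0
    baselines: Baselines = field(default_factory=Baselines)

    def validate(self) -> None:
        if not self.Ea > 0:
            raise ValueError(f"Ea must be positive, got {self.Ea}")
        if not 250.0 <= self.Tf <= 450.0:
            raise ValueError(f"Tf outside plausible band 250-450 K: {self.Tf}")
        if not self.v > 0:
            raise ValueError(f"scan rate must be positive, got {self.v}")


@dataclass
class EmpiricalResult:
    """Empirical description of a transition: midpoint, onset and their
    Euclidean combination."""

    Tm: float
    Tonset: float
    onset_fraction: float = 0.01
    Teucl: float = 0.0
    onset_extrapolated: bool = False


def gibbs_free_energy(p: ThermoParams, T) -> np.ndarray | float:
    """Unfolding free energy ΔG_u(T) from the Gibbs–Helmholtz equation.

    ΔG_u(T) = ΔH_m·(1 − T/T_m) + ΔC_p·(T − T_m − T·ln(T/T_m)); exactly
    zero at T = T_m for any parameter set.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    dG = p.dHm * (1.0 - T / p.Tm)
    if p.dCp != 0.0:
        dG = dG + p.dCp * (T - p.Tm - T * np.log(T / p.Tm))
    return dG if dG.ndim else float(dG)


def equilibrium_fraction(p: ThermoParams, T) -> np.ndarray | float:
    """Fraction unfolded f_unf(T) = K_u/(1 + K_u) with K_u = exp(−ΔG_u/RT)."""
    T = np.asarray(T, dtype=float)
    arg = np.clip(-np.asarray(gibbs_free_energy(p, T)) / (R * T), -_EXP_CLAMP, _EXP_CLAMP)
    K = np.exp(arg)
    f = K / (1.0 + K)
    return f if f.ndim else float(f)


def equilibrium_signal(p: ThermoParams, T) -> np.ndarray | float:
    """Observed signal of the equilibrium model: the baseline mixture
    (k_N·T + b_N)·(1 − f_unf) + (k_U·T + b_U)·f_unf."""
    T = np.asarray(T, dtype=float)
    f = np.asarray(equilibrium_fraction(p, T))
    s = p.baselines.native(T) * (1.0 - f) + p.baselines.unfolded(T) * f
    return s if s.ndim else float(s)


def unfolding_rate(p: KineticParams, T) -> np.ndarray | float:
    """Arrhenius rate constant k_u(T) = exp(−E_a/R·(1/T − 1/T_f)), 1/min."""
    T = np.asarray(T, dtype=float)
    arg = np.clip(-p.Ea / R * (1.0 / T - 1.0 / p.Tf), -_EXP_CLAMP, _EXP_CLAMP)
    k = np.exp(arg)
    return k if k.ndim else float(k)


# 4-point Gauss-Legendre nodes/weights on [-1, 1]; the Arrhenius rate is
# smooth, so per-interval Gauss quadrature is accurate to machine
# precision on sub-kelvin grids where cumulative trapezoid is not
_GL_NODES = np.array([-0.8611363115940526, -0.3399810435848563,
                      0.3399810435848563, 0.8611363115940526])
_GL_WEIGHTS = np.array([0.34785484513745385, 0.6521451548625461,
                        0.6521451548625461, 0.34785484513745385])


def kinetic_xn(p: KineticParams, T_grid) -> np.ndarray:
    """Native fraction x_N along the temperature ramp.

    The linear ODE dx_N/dT = −(1/v)·k_u(T)·x_N has the closed form
    x_N(T) = exp(−(1/v)·∫_{Tmin}^{T} k_u(τ) dτ); the integral is
    accumulated per grid interval with 4-point Gauss–Legendre quadrature.
    x_N(T_min) = 1 (fully folded at the start of the ramp); the result is
    nonincreasing in [0, 1].
    """
    T = np.asarray(T_grid, dtype=float)
    if T.ndim != 1 or T.size < 2:
        raise ValueError("T_grid must be a 1-D grid with at least 2 points")
    if np.any(np.diff(T) <= 0):
        raise ValueError("T_grid must be strictly increasing")
    half = 0.5 * np.diff(T)  # (n-1,)
    mid = 0.5 * (T[:-1] + T[1:])
    nodes = mid[:, None] + half[:, None] * _GL_NODES[None, :]  # (n-1, 4)
    ku = np.asarray(unfolding_rate(p, nodes.ravel())).reshape(nodes.shape)
    per_interval = half * (ku * _GL_WEIGHTS[None, :]).sum(axis=1)
    integral = np.concatenate(([0.0], np.cumsum(per_interval)))
    return np.exp(-np.clip(integral / p.v, 0.0, _EXP_CLAMP))


def kinetic_signal(p: KineticParams, T_grid) -> np.ndarray:
    """Observed signal of the kinetic model: native baseline weighted by
    x_N plus unfolded baseline weighted by 1 − x_N."""
    T = np.asarray(T_grid, dtype=float)
    xn = kinetic_xn(p, T)
    return p.baselines.native(T) * xn + p.baselines.unfolded(T) * (1.0 - xn)


def pku_std(p: KineticParams) -> float:
    """Kinetic stability measure pk_u°′ = −log₁₀ k_u(298.15 K).

    Zero when T_f = 298.15 K (k_u = 1 by definition of T_f); higher values
    mean slower unfolding at the reference temperature, i.e. higher
    kinetic stability.
    """
    return p.Ea / R * (1.0 / T_STD - 1.0 / p.Tf) / math.log(10.0)


def t_onset(
    p: ThermoParams,
    onset_fraction: float = 0.01,
    t_min: float | None = None,
) -> tuple[float, bool]:
    """Onset temperature of the transition on the fitted curve.

    Returns the temperature at which the fraction unfolded equals
    ``onset_fraction`` (default 1%, the conventional start of the
    transition region), found by bracketed root search on
    [``t_min``, T_m] to 1e-4 K.  If the onset lies below ``t_min`` (the
    scan start), ``t_min`` is returned with the second element True
    ("onset extrapolated").
    """
    if not 0.0 < onset_fraction < 0.5:
        raise ValueError("onset_fraction must be in (0, 0.5)")
    if t_min is None:
        t_min = max(150.0, p.Tm - 150.0)
    if t_min >= p.Tm:
        raise ValueError("t_min must be below Tm")

    def g(T: float) -> float:
        return float(equilibrium_fraction(p, T)) - onset_fraction

    if g(t_min) >= 0.0:  # already past the onset at the scan start
        return float(t_min), True
    root = brentq(g, t_min, p.Tm, xtol=1e-4)
    return float(root), False


def t_eucl(Tm: float, Tonset: float) -> float:
    """Empirical stability measure: Euclidean distance of (T_m, T_onset)
    from the origin, sqrt(T_m² + T_onset²)."""
    if Tm < 0 or Tonset < 0:
        raise ValueError("temperatures must be nonnegative")
    return math.hypot(Tm, Tonset)


def dcp_neglect_error(dCp: float, Tref: float, Tm: float) -> float:
    """Systematic error in ΔG_u(T_ref) incurred by setting ΔC_p to zero.

    Error(T_ref, T_m) = ΔC_p·(T_ref − T_m − T_ref·ln(T_ref/T_m)).  For
    T_ref < T_m and positive ΔC_p the error is always negative: neglecting
    ΔC_p overestimates ΔG_u at the reference temperature.
    """
    if Tref <= 0:
        raise ValueError("Tref must be positive")
    if Tref >= Tm:
        raise ValueError("Tref must be below Tm")
    return dCp * (Tref - Tm - Tref * math.log(Tref / Tm))
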