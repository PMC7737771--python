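"""Synthetic unfolding data with known ground truth.

Emulates nanoDSF-style thermal ramps: a 20–95 °C scan at 1 K/min sampled
every 0.5 K (151 points), ratio-like baselines (pre-transition level near
0.8, post-transition near 0.95, small positive slopes) and homoscedastic
Gaussian noise expressed as a fraction of the transition height.

Two panel generators are provided:

* :func:`panel_random` — parameters drawn independently from stated
  ranges (a set of unrelated proteins).
* :func:`panel_screen` — a condition screen of ONE protein: midpoints
  spread over a range while the unfolding enthalpy tracks the midpoint
  linearly (Kirchhoff coupling through ΔC_p) with replicate-level
  scatter.  This is what a real single-protein buffer/detergent screen
  looks like, and it is the setting in which the three stability measures
  rank conditions concordantly.

Everything is driven by an integer seed; the same seed reproduces the
same bytes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import models
from .curves import MeltingCurve, PlateLayout
from .models import Baselines, KineticParams, ThermoParams


def default_grid(t_min: float = 293.15, t_max: float = 368.15, step: float = 0.5) -> np.ndarray:
    """Default scan grid: 20–95 °C every 0.5 K (151 points)."""
    return np.arange(t_min, t_max + step / 2, step)


def default_baselines() -> Baselines:
    """Ratio-like baselines: pre ≈ 0.8, post ≈ 0.95 near the transition,
    small positive slopes."""
    return Baselines(k_N=3e-4, b_N=0.80 - 3e-4 * 330.0, k_U=2e-4, b_U=0.95 - 2e-4 * 330.0)


@dataclass
class SimSpec:
    """Specification of one synthetic curve (or a panel of them)."""

    model: str = "thermodynamic"  # thermodynamic | kinetic
    dHm: float = 400_000.0  # J/mol (thermodynamic)
    Tm: float = 330.0  # K (thermodynamic)
    dCp: float = 0.0  # J/(mol K)
    Ea: float = 300_000.0  # J/mol (kinetic)
    Tf: float = 330.0  # K (kinetic)
    scan_rate: float = 1.0  # K/min
    baselines: Baselines = field(default_factory=default_baselines)
    t_min: float = 293.15
    t_max: float = 368.15
    step: float = 0.5
    noise_sd: float = 0.0  # signal units; see noise_from_fraction
    # heteroscedastic option: SD ramps linearly to this value at the scan
    # end (None = homoscedastic)
    noise_sd_end: float | None = None
    seed: int | None = None
    n_samples: int = 1
    # panel ranges (uniform draws)
    dHm_range: tuple[float, float] = (100_000.0, 1_000_000.0)
    Tm_range: tuple[float, float] = (300.0, 360.0)
    Ea_range: tuple[float, float] = (100_000.0, 1_000_000.0)
    Tf_range: tuple[float, float] = (300.0, 360.0)

    def grid(self) -> np.ndarray:
        return default_grid(self.t_min, self.t_max, self.step)

    def params(self) -> ThermoParams | KineticParams:
        if self.model == "kinetic":
            return KineticParams(Ea=self.Ea, Tf=self.Tf, v=self.scan_rate,
                                 baselines=self.baselines)
        return ThermoParams(dHm=self.dHm, Tm=self.Tm, dCp=self.dCp,
                            baselines=self.baselines)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimSpec":
        d = json.loads(text)
        if "baselines" in d and isinstance(d["baselines"], dict):
            d["baselines"] = Baselines(**d["baselines"])
        for k in ("dHm_range", "Tm_range", "Ea_range", "Tf_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def transition_height(p: ThermoParams | KineticParams) -> float:
    """Absolute baseline separation at the transition midpoint."""
    mid = p.Tm if isinstance(p, ThermoParams) else p.Tf
    return abs(float(p.baselines.separation(mid)))


def noise_from_fraction(p: ThermoParams | KineticParams, fraction: float) -> float:
    """Noise SD as a fraction of the transition height (e.g. 0.01 = 1%)."""
    return fraction * transition_height(p)


def forward_signal(p: ThermoParams | KineticParams, T: np.ndarray) -> np.ndarray:
    if isinstance(p, KineticParams):
        return models.kinetic_signal(p, T)
    return np.asarray(models.equilibrium_signal(p, T))


def simulate_curve(
    spec: SimSpec,
    sample_id: str = "sim",
    rng: np.random.Generator | None = None,
    truncate_at_fraction: float | None = None,
) -> tuple[MeltingCurve, dict]:
    """Simulate one melting curve plus its ground-truth record.

    ``truncate_at_fraction`` cuts the scan where the unfolded fraction
    first exceeds the given value (a curve with no post-transition
    baseline, as happens for proteins melting near the scan end).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    T = spec.grid()
    p = spec.params()
    clean = forward_signal(p, T)
    if truncate_at_fraction is not None:
        if isinstance(p, KineticParams):
            frac = 1.0 - models.kinetic_xn(p, T)
        else:
            frac = np.asarray(models.equilibrium_fraction(p, T))
        keep = frac <= truncate_at_fraction
        T, clean = T[keep], clean[keep]
    if spec.noise_sd > 0:
        if spec.noise_sd_end is not None:
            sd = np.linspace(spec.noise_sd, spec.noise_sd_end, T.size)
        else:
            sd = spec.noise_sd
        signal = clean + rng.normal(0.0, 1.0, size=T.size) * sd
    else:
        signal = clean.copy()
    curve = MeltingCurve(
        sample_id=sample_id,
        temperature=T,
        signal=signal,
        readout="ratio",
        scan_rate=spec.scan_rate,
        history=[f"simulated ({spec.model}, noise_sd={spec.noise_sd:g})"],
    )
    truth = {
        "sample_id": sample_id,
        "model": spec.model,
        "noise_sd": spec.noise_sd,
        **(
            {"Ea": p.Ea, "Tf": p.Tf, "v": p.v}
            if isinstance(p, KineticParams)
            else {"dHm": p.dHm, "Tm": p.Tm, "dCp": p.dCp}
        ),
        "baselines": p.baselines,
    }
    return curve, truth


def panel_random(
    n: int,
    seed: int,
    model: str = "thermodynamic",
    noise_fraction: float = 0.01,
    base_spec: SimSpec | None = None,
) -> list[tuple[MeltingCurve, dict]]:
    """Panel of unrelated samples: parameters drawn independently and
    uniformly from the spec ranges."""
    spec = base_spec or SimSpec(model=model)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        s = SimSpec(**{**asdict(spec), "baselines": spec.baselines})
        s.model = model
        if model == "kinetic":
            s.Ea = rng.uniform(*spec.Ea_range)
            s.Tf = rng.uniform(*spec.Tf_range)
        else:
            s.dHm = rng.uniform(*spec.dHm_range)
            s.Tm = rng.uniform(*spec.Tm_range)
        s.noise_sd = noise_from_fraction(s.params(), noise_fraction)
        out.append(simulate_curve(s, sample_id=f"s{i + 1:02d}", rng=rng))
    return out


def panel_screen(
    n: int,
    seed: int,
    noise_fraction: float = 0.01,
    tm_range: tuple[float, float] = (300.0, 360.0),
    dhm_at_tm_low: float = 100_000.0,
    dhm_slope: float = 15_000.0,
    dhm_scatter: float = 0.05,
    base_spec: SimSpec | None = None,
) -> list[tuple[MeltingCurve, dict]]:
    """Condition screen of one protein.

    Midpoints are uniform over ``tm_range``; the apparent unfolding
    enthalpy follows the protein's Kirchhoff line
    ΔH_m(T_m) = ΔH_m(T_low) + slope·(T_m − T_low) with multiplicative
    replicate scatter (default 5%, the typical replicate-level error of
    ΔH_m estimates).  With the defaults the panel spans ΔH_m 100–1,000
    kJ/mol across T_m 300–360 K.
    """
    spec = base_spec or SimSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        s = SimSpec(**{**asdict(spec), "baselines": spec.baselines})
        s.model = "thermodynamic"
        s.Tm = rng.uniform(*tm_range)
        dhm = (dhm_at_tm_low + dhm_slope * (s.Tm - tm_range[0])) * (
            1.0 + dhm_scatter * rng.standard_normal()
        )
        s.dHm = float(np.clip(dhm, 61_000.0, 3_900_000.0))
        s.noise_sd = noise_from_fraction(s.params(), noise_fraction)
        out.append(simulate_curve(s, sample_id=f"s{i + 1:02d}", rng=rng))
    return out


def simulate_screen(
    panel: list[tuple[MeltingCurve, dict]],
    layout: PlateLayout,
    curves_path,
    layout_path,
) -> None:
    """Write a simulated panel as the canonical wide-CSV pair (curves +
    plate layout) consumable by :mod:`meltfit.curves`.

    Temperatures are written in °C, as an instrument would export them.
    """
    curves = [c for c, _ in panel]
    if len(curves) != len(layout.entries):
        raise ValueError(
            f"layout size {len(layout.entries)} does not match panel size {len(curves)}"
        )
    grid = curves[0].temperature
    data = {"temperature": grid - 273.15}
    for c in curves:
        if c.temperature.shape != grid.shape or not np.allclose(c.temperature, grid):
            raise ValueError("all curves in a screen must share one grid")
        data[c.sample_id] = c.signal
    pd.DataFrame(data).to_csv(curves_path, index=False)

    rows = [
        {
            "sample_id": e.sample_id,
            "well": e.well,
            "condition_label": e.condition_label,
            "replicate_group": e.replicate_group,
            "is_reference": str(e.is_reference).lower(),
        }
        for e in layout.entries
    ]
    pd.DataFrame(rows).to_csv(layout_path, index=False)


def grid_layout(sample_ids, n_rows: int = 8, n_cols: int = 12) -> PlateLayout:
    """Lay samples onto plate wells row-major (A1, A2, ...)."""
    from .curves import LayoutEntry

    if len(sample_ids) > n_rows * n_cols:
        raise ValueError("more samples than wells")
    entries = []
    for i, sid in enumerate(sample_ids):
        row, col = divmod(i, n_cols)
        entries.append(
            LayoutEntry(
                sample_id=sid,
                well=f"{chr(ord('A') + row)}{col + 1}",
                condition_label=f"cond_{i + 1}",
                replicate_group=sid,
            )
        )
    return PlateLayout(entries=entries, n_rows=n_rows, n_cols=n_cols)
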