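"""Stability measures, comparisons, correlations and plate heatmaps.

Each fitted sample is condensed into single-number stability measures:

* ΔG_u°′ — unfolding free energy extrapolated to 298.15 K, 100 kPa
  (equilibrium model); the primary ranking measure.
* pk_u°′ — negative decadic log of the unfolding rate constant at
  298.15 K (kinetic model).
* T_eucl — sqrt(T_m² + T_onset²) (empirical model).

On screens of one protein under varying conditions the three measures
rank conditions near-identically; the correlation diagnostics here
quantify that concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, pearsonr

from . import models
from .curves import CurveError, PlateLayout
from .fitting import FitResult
from .models import KineticParams, ThermoParams

MEASURES = ("dG_std", "pku_std", "Teucl")


@dataclass
class StabilityRecord:
    """Per-sample stability summary across models."""

    sample_id: str
    condition_label: str = ""
    dG_std: float = math.nan  # J/mol at 298.15 K, 100 kPa
    pku_std: float = math.nan
    Teucl: float = math.nan  # K
    Tm: float = math.nan  # K
    Tonset: float = math.nan  # K
    dHm: float = math.nan  # J/mol
    Ea: float = math.nan  # J/mol
    Tf: float = math.nan  # K
    dCp: float = 0.0  # J/(mol K), held fixed during fitting
    S: float = math.nan
    BS: float = math.nan
    Tm_sd: float = math.nan
    dHm_sd: float = math.nan
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "sample_id", "condition_label", "dG_std", "pku_std", "Teucl",
            "Tm", "Tonset", "dHm", "Ea", "Tf", "dCp", "S", "BS", "Tm_sd", "dHm_sd",
        )}
        d["flags"] = ";".join(sorted(self.flags))
        return d


def stability_measures(
    fit: FitResult, condition_label: str = "", onset_fraction: float = 0.01
) -> StabilityRecord:
    """Derive the stability measures available from one fit.

    A thermodynamic fit yields ΔG_u°′ (and T_m, ΔH_m); a kinetic fit
    yields pk_u°′; an empirical fit yields T_onset and T_eucl in addition
    to the thermodynamic quantities.  A failed fit produces a record
    carrying only the flags.
    """
    rec = StabilityRecord(sample_id=fit.sample_id, condition_label=condition_label,
                          flags=set(fit.flags))
    if not fit.success:
        return rec
    rec.S, rec.BS = fit.S, fit.BS
    p = fit.params
    if isinstance(p, KineticParams):
        rec.Ea, rec.Tf = p.Ea, p.Tf
        rec.pku_std = models.pku_std(p)
        rec.Tm_sd = fit.param_sd.get("Tf", math.nan)
    elif isinstance(p, ThermoParams):
        rec.Tm, rec.dHm, rec.dCp = p.Tm, p.dHm, p.dCp
        rec.dG_std = float(models.gibbs_free_energy(p, models.T_STD))
        rec.Tm_sd = fit.param_sd.get("Tm", math.nan)
        rec.dHm_sd = fit.param_sd.get("dHm", math.nan)
        if fit.empirical is not None:
            rec.Tonset = fit.empirical.Tonset
            rec.Teucl = fit.empirical.Teucl
    return rec


def combine_measures(
    fits: Mapping[str, FitResult], condition_label: str = ""
) -> StabilityRecord:
    """Merge per-model fits of the same sample into one record.

    ``fits`` maps model name ("thermodynamic", "kinetic", "empirical") to
    its fit; measures from each successful fit are filled in, flags are
    unioned.
    """
    recs = {m: stability_measures(f, condition_label) for m, f in fits.items()}
    out = StabilityRecord(
        sample_id=next(iter(fits.values())).sample_id, condition_label=condition_label
    )
    for m in ("thermodynamic", "empirical", "kinetic"):
        r = recs.get(m)
        if r is None:
            continue
        out.flags |= r.flags
        for name in ("dG_std", "pku_std", "Teucl", "Tm", "Tonset", "dHm", "Ea",
                     "Tf", "S", "BS", "Tm_sd", "dHm_sd"):
            val = getattr(r, name)
            if isinstance(val, float) and math.isnan(getattr(out, name)) and not math.isnan(val):
                setattr(out, name, val)
    return out


def ddg(sample: StabilityRecord, reference: StabilityRecord) -> float:
    """Stability difference ΔΔG_u°′ = sample − reference, J/mol (signed)."""
    if math.isnan(sample.dG_std) or math.isnan(reference.dG_std):
        raise ValueError("both records need a ΔG_u°′ value")
    return sample.dG_std - reference.dG_std


def measure_correlation(
    records: Sequence[StabilityRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and Kendall τ-b among the three stability
    measures over a set of samples.

    Only records carrying all three measures enter; at least 10 are
    required for the correlations to be meaningful.  Returns two 3×3
    DataFrames (Pearson, Kendall) with unit diagonals.
    """
    rows = [
        {m: getattr(r, m) for m in MEASURES}
        for r in records
        if all(not math.isnan(getattr(r, m)) for m in MEASURES)
    ]
    if len(rows) < 10:
        raise ValueError(f"need ≥10 complete records, have {len(rows)}")
    df = pd.DataFrame(rows)
    for m in MEASURES:
        if df[m].nunique() == 1:
            raise ValueError(f"measure {m} is constant; correlation undefined")
    pear = pd.DataFrame(np.eye(3), index=MEASURES, columns=MEASURES)
    kend = pd.DataFrame(np.eye(3), index=MEASURES, columns=MEASURES)
    for i, a in enumerate(MEASURES):
        for b in MEASURES[i + 1:]:
            r = pearsonr(df[a], df[b]).statistic
            t = kendalltau(df[a], df[b], variant="b").statistic
            pear.loc[a, b] = pear.loc[b, a] = r
            kend.loc[a, b] = kend.loc[b, a] = t
    return pear, kend


def heatmap_table(
    records: Sequence[StabilityRecord],
    layout: PlateLayout,
    measure: str = "dG_std",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arrange a stability measure on the plate grid.

    Returns (values, counts): DataFrames indexed by plate row letter and
    column number.  Wells in the same replicate group show the group mean;
    counts report the number of replicates behind each cell.  Failed wells
    (measure unavailable) stay NaN and are rendered as missing.
    """
    if measure not in StabilityRecord.__dataclass_fields__:
        raise ValueError(f"unknown measure {measure!r}")
    by_id = {r.sample_id: r for r in records}
    vals = {r.sample_id: getattr(r, measure) for r in records}
    if all(math.isnan(v) for v in vals.values()):
        raise ValueError(f"measure {measure!r} absent in all records")

    # group means over replicate groups
    groups: dict[str, list[float]] = {}
    for e in layout.entries:
        if e.sample_id in vals and not math.isnan(vals[e.sample_id]):
            groups.setdefault(e.replicate_group, []).append(vals[e.sample_id])

    rows = [chr(ord("A") + i) for i in range(layout.n_rows)]
    cols = list(range(1, layout.n_cols + 1))
    values = pd.DataFrame(np.nan, index=rows, columns=cols)
    counts = pd.DataFrame(0, index=rows, columns=cols)
    for e in layout.entries:
        if e.sample_id not in by_id:
            continue
        row, col = e.well[0], int(e.well[1:])
        members = groups.get(e.replicate_group, [])
        if members:
            values.loc[row, col] = float(np.mean(members))
            counts.loc[row, col] = len(members)
    return values, counts


def render_heatmap(
    values: pd.DataFrame,
    measure: str,
    png_path=None,
    svg_path=None,
    csv_path=None,
):
    """Render a plate heatmap (PNG/SVG) and optionally export the grid as
    CSV.  The color scale spans the observed min–max of the measure;
    missing wells are shown hatched."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.6 * values.shape[1]), 0.55 * values.shape[0] + 1.5))
    data = values.to_numpy(dtype=float)
    masked = np.ma.masked_invalid(data)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad(color="0.85")
    vmin = float(np.nanmin(data)) if np.isfinite(data).any() else 0.0
    vmax = float(np.nanmax(data)) if np.isfinite(data).any() else 1.0
    im = ax.imshow(masked, cmap=cmap, vmin=vmin, vmax=vmax, aspect="auto")
    ax.set_xticks(range(values.shape[1]), values.columns)
    ax.set_yticks(range(values.shape[0]), values.index)
    for (i, j), v in np.ndenumerate(data):
        if not np.isfinite(v):
            ax.text(j, i, "×", ha="center", va="center", color="0.4")
    fig.colorbar(im, ax=ax, label=measure)
    ax.set_title(f"Plate heatmap: {measure}")
    fig.tight_layout()
    if png_path is not None:
        fig.savefig(png_path, dpi=120)
    if svg_path is not None:
        fig.savefig(svg_path)
    if csv_path is not None:
        values.to_csv(csv_path)
    plt.close(fig)
    return fig
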