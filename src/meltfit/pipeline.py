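"""End-to-end screen analysis: load → preprocess → fit → rank → export.

The pipeline is deterministic: fixed initialization, no random restarts,
so two runs over the same inputs and configuration produce identical
result tables.  Per-sample failures are logged and flagged; only
file-level problems abort a run.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import fitting, preprocess, ranking
from .curves import CurveError, MeltingCurve, read_curves, read_layout, write_results
from .fitting import FLAG_NO_POST_BASELINE, FLAG_NO_TRANSITION, fit_curve
from .models import T_STD
from .ranking import StabilityRecord, combine_measures, render_heatmap

logger = logging.getLogger("meltfit")


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run (JSON round-trippable;
    written next to the outputs for provenance)."""

    input: str = ""
    layout: str | None = None
    out_dir: str = "meltfit_out"
    models: tuple[str, ...] = ("thermodynamic", "kinetic", "empirical")
    readout: str = "generic"
    temperature_unit: str = "celsius"
    scan_rate: float = 1.0  # K/min
    tref: float = T_STD
    reference: str | None = None  # sample_id used for ΔΔG
    heatmap_measure: str = "dG_std"
    # preprocessing
    trim_t_low: float | None = None
    trim_t_high: float | None = None
    smooth_window_k: float | None = None  # median filter; None = off
    bin_width_k: float | None = None  # None = off
    savgol_window_k: float = 10.0
    savgol_polyorder: int = 4
    onset_fraction: float = 0.01
    dcp: float = 0.0  # fixed during thermal fits
    # readout selection
    bs_threshold: float = 0.25
    bs_margin: float = 0.1
    write_xlsx: bool = True
    plots: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def preprocess_curve(curve: MeltingCurve, config: RunConfig) -> MeltingCurve:
    if config.trim_t_low is not None or config.trim_t_high is not None:
        curve = preprocess.trim(
            curve,
            config.trim_t_low if config.trim_t_low is not None else curve.t_min,
            config.trim_t_high if config.trim_t_high is not None else curve.t_max,
        )
    if config.smooth_window_k:
        curve = preprocess.smooth_median(curve, config.smooth_window_k)
    if config.bin_width_k:
        curve = preprocess.bin_curve(curve, config.bin_width_k)
    return curve


def analyze_curve(
    curve: MeltingCurve, config: RunConfig, return_fits: bool = False
):
    """Fit the configured models to one curve and combine the measures.

    Curves whose thermodynamic fit fails for lack of a post-transition
    baseline fall back to the derivative-peak melting temperature
    (flagged; no free-energy measure is derived from it).
    """
    shape = preprocess.estimate_shape_and_baselines(
        curve,
        savgol_window_k=config.savgol_window_k,
        savgol_polyorder=config.savgol_polyorder,
    )
    fits = {
        m: fit_curve(
            curve, m, shape=shape, dCp=config.dcp, onset_fraction=config.onset_fraction
        )
        for m in config.models
    }
    record = combine_measures(fits)
    thermo = fits.get("thermodynamic") or fits.get("empirical")
    if thermo is not None and not thermo.success and FLAG_NO_TRANSITION not in thermo.flags:
        tm, flags = fitting.fallback_tm(curve, shape)
        record.flags |= flags
        if FLAG_NO_POST_BASELINE in flags and math.isnan(record.Tm):
            record.Tm = tm
    if return_fits:
        return record, fits
    return record


def run(config: RunConfig) -> int:
    """Execute a full screen analysis; returns a process exit status
    (0 success, 2 missing input, 1 other file-level failure)."""
    out = Path(config.out_dir)
    in_path = Path(config.input)
    if not in_path.exists():
        logger.error("input file not found: %s", in_path)
        return 2
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_inner(config, out, in_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_inner(config: RunConfig, out: Path, in_path: Path) -> int:
    (out / "config.json").write_text(config.to_json())

    try:
        curves = read_curves(
            in_path,
            temperature_unit=config.temperature_unit,
            readout=config.readout,
            scan_rate=config.scan_rate,
        )
    except CurveError as exc:
        logger.error("cannot read %s: %s", in_path, exc)
        return 1
    if not curves:
        logger.error("no usable curves in %s", in_path)
        return 1

    layout = None
    if config.layout:
        try:
            layout = read_layout(config.layout)
        except (CurveError, FileNotFoundError) as exc:
            logger.error("cannot read layout %s: %s", config.layout, exc)
            return 1

    records: list[StabilityRecord] = []
    kept: list[tuple[MeltingCurve, object]] = []  # (processed curve, thermo fit)
    for curve in curves:
        try:
            cur = preprocess_curve(curve, config)
            rec, fits = analyze_curve(cur, config, return_fits=True)
            thermo = fits.get("thermodynamic") or fits.get("empirical")
            if thermo is not None and thermo.success:
                kept.append((cur, thermo))
        except CurveError as exc:
            logger.warning("sample %s skipped: %s", curve.sample_id, exc)
            rec = StabilityRecord(sample_id=curve.sample_id, flags={"fit_failed"})
        if layout is not None:
            entry = layout.entry_of(rec.sample_id)
            if entry is not None:
                rec.condition_label = entry.condition_label
        for flag in sorted(rec.flags):
            logger.info("sample %s flagged: %s", rec.sample_id, flag)
        records.append(rec)

    if config.reference is not None:
        ref = next((r for r in records if r.sample_id == config.reference), None)
        if ref is None or math.isnan(ref.dG_std):
            logger.warning("reference %s unavailable for ΔΔG", config.reference)
        else:
            for r in records:
                if not math.isnan(r.dG_std):
                    logger.info(
                        "ddG %s vs %s: %.1f J/mol",
                        r.sample_id, ref.sample_id, ranking.ddg(r, ref),
                    )

    write_results(records, out / "results.csv")
    if config.write_xlsx:
        write_results(records, out / "results.xlsx")

    if layout is not None:
        try:
            values, _counts = ranking.heatmap_table(records, layout, config.heatmap_measure)
            render_heatmap(
                values,
                config.heatmap_measure,
                png_path=out / "heatmap.png",
                svg_path=out / "heatmap.svg",
                csv_path=out / "heatmap.csv",
            )
        except ValueError as exc:
            logger.warning("heatmap skipped: %s", exc)

    if config.plots:
        _write_fraction_plots(kept, out)

    n_ok = sum(1 for r in records if not math.isnan(r.Tm))
    logger.info("analyzed %d curves, %d with a transition", len(records), n_ok)
    return 0


def _write_fraction_plots(kept, out: Path) -> None:
    """One baseline-corrected fraction-unfolded plot per fitted sample."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from . import models as _m

    plot_dir = out / "plots"
    plot_dir.mkdir(exist_ok=True)
    for cur, fit in kept:
        try:
            frac = fitting.fraction_unfolded_curve(cur, fit.params)
        except fitting.FitError:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(cur.temperature, frac, ".", ms=3, label="experimental")
        tt = np.linspace(cur.t_min, cur.t_max, 300)
        ax.plot(tt, _m.equilibrium_fraction(fit.params, tt), "-", label="fit")
        ax.axhline(0.5, ls="--", color="0.6", lw=0.8)
        ax.set_xlabel("temperature (K)")
        ax.set_ylabel("fraction unfolded")
        ax.set_title(f"{cur.sample_id}: Tm = {fit.params.Tm:.2f} K")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_dir / f"{cur.sample_id}_fraction.png", dpi=100)
        plt.close(fig)
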