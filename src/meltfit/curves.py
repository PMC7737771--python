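"""Containers and I/O for multi-sample unfolding data and plate metadata.

The canonical input is a wide table: first column temperature, one further
column per sample, header row present.  Temperatures are converted to and
stored in kelvin; degrees Celsius appear only at the I/O boundary and only
when explicitly declared.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Minimum number of retained points for a curve to be analyzable.
MIN_POINTS = 20

CELSIUS_OFFSET = 273.15

READOUTS = ("F330", "F350", "ratio", "CD", "generic")


class CurveError(ValueError):
    """Raised for malformed or unusable unfolding data."""


@dataclass
class MeltingCurve:
    """One sample's signal versus temperature.

    ``temperature`` is strictly increasing, kelvin; ``signal`` has the
    same length in arbitrary units.  ``history`` records preprocessing
    steps in order so a curve's provenance is replayable.
    """

    sample_id: str
    temperature: np.ndarray
    signal: np.ndarray
    readout: str = "generic"
    scan_rate: float = 1.0  # K/min
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise CurveError(f"{self.sample_id}: temperature/signal length mismatch")
        if self.readout not in READOUTS:
            raise CurveError(f"{self.sample_id}: unknown readout {self.readout!r}")
        if not self.scan_rate > 0:
            raise CurveError(f"{self.sample_id}: scan_rate must be positive")
        if np.any(np.diff(self.temperature) <= 0):
            raise CurveError(f"{self.sample_id}: nonmonotonic temperature")

    def __len__(self) -> int:
        return self.temperature.size

    @property
    def t_min(self) -> float:
        return float(self.temperature[0])

    @property
    def t_max(self) -> float:
        return float(self.temperature[-1])

    @property
    def median_step(self) -> float:
        return float(np.median(np.diff(self.temperature)))

    def replace_data(self, temperature: np.ndarray, signal: np.ndarray, step: str) -> "MeltingCurve":
        """Copy with new data arrays and ``step`` appended to the history."""
        return replace(
            self,
            temperature=np.asarray(temperature, dtype=float),
            signal=np.asarray(signal, dtype=float),
            history=[*self.history, step],
        )

    def validate(self) -> None:
        if len(self) < MIN_POINTS:
            raise CurveError(f"{self.sample_id}: fewer than {MIN_POINTS} points")
        if np.any(~np.isfinite(self.signal)):
            raise CurveError(f"{self.sample_id}: NaN in retained points")


@dataclass
class LayoutEntry:
    sample_id: str
    well: str
    condition_label: str = ""
    replicate_group: str = ""
    is_reference: bool = False


@dataclass
class PlateLayout:
    """Well-to-condition mapping for a (by default 96-well) plate."""

    entries: list[LayoutEntry]
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise CurveError("duplicate sample_ids in layout")
        if sum(e.is_reference for e in self.entries) > 1:
            raise CurveError("at most one is_reference entry allowed")
        for e in self.entries:
            if not self.well_ok(e.well):
                raise CurveError(f"malformed well ID {e.well!r} for sample {e.sample_id!r}")

    def well_ok(self, well: str) -> bool:
        last_row = chr(ord("A") + self.n_rows - 1)
        m = re.match(rf"^[A-{last_row}]([1-9][0-9]?)$", well)
        return bool(m) and int(m.group(1)) <= self.n_cols

    def well_of(self, sample_id: str) -> str | None:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e.well
        return None

    def entry_of(self, sample_id: str) -> LayoutEntry | None:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        return None


def _load_table(path, fmt: str | None) -> pd.DataFrame:
    if fmt is None:
        fmt = "xlsx" if str(path).lower().endswith((".xlsx", ".xls")) else "csv"
    if fmt == "csv":
        # pandas mangles duplicate header names; check the raw header
        raw = pd.read_csv(path, header=None, nrows=1).iloc[0].tolist()
        if len(set(map(str, raw))) != len(raw):
            raise CurveError("duplicate sample IDs in header")
        return pd.read_csv(path)
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=0)
        return df
    raise CurveError(f"unknown format {fmt!r}")


def read_curves(
    path,
    format: str | None = None,
    temperature_unit: str = "celsius",
    readout: str = "generic",
    scan_rate: float = 1.0,
) -> list[MeltingCurve]:
    """Read a wide temperature-vs-signal table into melting curves.

    The first column is temperature (unit per ``temperature_unit``,
    converted to kelvin on load), each further column one sample.  Columns
    with fewer than 20 finite points are skipped with a warning rather
    than failing the whole file.  Missing interior points are dropped, not
    interpolated, and the drop count is recorded in the curve history.
    Duplicate sample IDs or a nonmonotonic temperature column reject the
    file.
    """
    df = _load_table(path, format)
    if df.shape[1] < 2:
        raise CurveError("need a temperature column plus at least one sample column")
    sample_ids = [str(c) for c in df.columns[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise CurveError("duplicate sample IDs in header")

    temp = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(temp)):
        raise CurveError("non-numeric temperature values")
    if temperature_unit == "celsius":
        temp = temp + CELSIUS_OFFSET
    elif temperature_unit != "kelvin":
        raise CurveError(f"unknown temperature unit {temperature_unit!r}")
    if np.any(np.diff(temp) <= 0):
        raise CurveError("nonmonotonic temperature")

    curves: list[MeltingCurve] = []
    for col, sid in zip(df.columns[1:], sample_ids):
        sig = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        finite = np.isfinite(sig)
        if finite.sum() < MIN_POINTS:
            warnings.warn(f"sample {sid!r} unreadable (<{MIN_POINTS} finite points); skipped")
            continue
        history = [f"loaded from {path} ({temperature_unit} input)"]
        n_dropped = int((~finite).sum())
        if n_dropped:
            history.append(f"dropped {n_dropped} missing points")
        curves.append(
            MeltingCurve(
                sample_id=sid,
                temperature=temp[finite],
                signal=sig[finite],
                readout=readout,
                scan_rate=scan_rate,
                history=history,
            )
        )
    return curves


def write_results(records, path, format: str | None = None) -> None:
    """Export per-sample results (fit parameters, SDs, quality metrics,
    stability measures, flags) as one row per sample, CSV or XLSX."""
    records = list(records)
    if not records:
        raise CurveError("no records to write")
    df = pd.DataFrame([r.to_dict() for r in records])
    if format is None:
        format = "xlsx" if str(path).lower().endswith((".xlsx", ".xls")) else "csv"
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise CurveError(f"unknown format {format!r}")


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    if str(path).lower().endswith((".xlsx", ".xls")):
        return pd.read_excel(path, sheet_name=0)
    return pd.read_csv(path)


def read_layout(path, n_rows: int = 8, n_cols: int = 12) -> PlateLayout:
    """Read a plate-layout CSV with columns sample_id, well,
    condition_label and optional replicate_group / is_reference.

    A missing replicate_group defaults to the sample_id (each sample its
    own group).  Malformed well IDs raise an error naming the offending
    row.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "well"}
    if not required.issubset(df.columns):
        raise CurveError(f"layout must have columns {sorted(required)}")
    probe = PlateLayout(entries=[], n_rows=n_rows, n_cols=n_cols)
    entries = []
    for i, row in df.iterrows():
        well = row["well"].strip()
        if not probe.well_ok(well):
            raise CurveError(f"layout row {i + 1}: malformed well ID {well!r}")
        rep = row.get("replicate_group", "") or row["sample_id"]
        ref_raw = str(row.get("is_reference", "")).strip().lower()
        entries.append(
            LayoutEntry(
                sample_id=row["sample_id"],
                well=well,
                condition_label=row.get("condition_label", ""),
                replicate_group=rep,
                is_reference=ref_raw in ("true", "1", "yes"),
            )
        )
    return PlateLayout(entries=entries, n_rows=n_rows, n_cols=n_cols)
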