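"""Domain containers and CSV I/O for CV and EIS data.

The canonical on-disk form for cyclic-voltammetry data is a *long* CSV with
columns ``electrode_id, sweep, potential_V, current_uA``.  Potentiostat-style
*wide* exports (repeated potential/current column pairs, one pair per sweep,
optionally preceded by metadata lines) are supported through a sniffing
reader.  EIS Bode tables carry ``sensor_id, group, frequency_Hz, z_imag_ohm``.

Units are normalized at read time to volts and microamperes.  Current columns
declared in mA or A (via the header suffix, e.g. ``current_mA``) are
converted; an undeclared unit is assumed to be microamperes and logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ligqc")

#: Potential grids of sweeps within one electrode must agree to this many volts.
GRID_TOLERANCE_V = 1e-6

_CURRENT_UNIT_FACTORS = {"ua": 1.0, "µa": 1.0, "ma": 1e3, "a": 1e6}
_POTENTIAL_UNIT_FACTORS = {"v": 1.0, "mv": 1e-3}


class FormatError(ValueError):
    """A file does not match the expected CSV dialect (missing/odd columns)."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class StructuralError(ValueError):
    """Parsed content violates a structural invariant (grids, sweep indices)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Voltammogram:
    """One CV sweep: a closed loop traced in the (potential, current) plane.

    Parameters
    ----------
    potential : ndarray
        Applied potential in volts, tracing one triangular cycle.
    current : ndarray
        Measured current in microamperes, same length as ``potential``.
    sweep_index : int
        1-based sweep number within the electrode's conditioning run.
    electrode_id : str
        Identifier of the electrode the sweep belongs to.
    """

    potential: np.ndarray
    current: np.ndarray
    sweep_index: int = 1
    electrode_id: str = ""

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.potential.shape != self.current.shape:
            raise StructuralError(
                f"electrode {self.electrode_id!r} sweep {self.sweep_index}: "
                f"potential ({self.potential.size}) and current "
                f"({self.current.size}) lengths differ"
            )
        if self.potential.size < 4:
            raise StructuralError(
                f"electrode {self.electrode_id!r} sweep {self.sweep_index}: "
                f"need at least 4 points, got {self.potential.size}"
            )
        if not (np.isfinite(self.potential).all() and np.isfinite(self.current).all()):
            raise StructuralError(
                f"electrode {self.electrode_id!r} sweep {self.sweep_index}: "
                "non-finite values"
            )

    @property
    def n_points(self) -> int:
        return int(self.potential.size)

    def is_triangular(self, rtol: float = 0.05) -> bool:
        """True if the potential rises to a single maximum then returns.

        ``rtol`` is the tolerated non-monotone wiggle as a fraction of the
        potential window (instrument quantization produces tiny reversals).
        """
        v = self.potential
        imax = int(np.argmax(v))
        window = float(v.max() - v.min())
        if window <= 0:
            return False
        tol = rtol * window
        up = np.all(np.diff(v[: imax + 1]) > -tol)
        down = np.all(np.diff(v[imax:]) < tol)
        return bool(up and down)


@dataclass
class ElectrodeRecord:
    """Ordered sweeps 1..K for one electrode."""

    electrode_id: str
    sweeps: list[Voltammogram]

    def __post_init__(self) -> None:
        indices = [s.sweep_index for s in self.sweeps]
        if indices != list(range(1, len(self.sweeps) + 1)):
            raise StructuralError(
                f"electrode {self.electrode_id!r}: sweep indices {indices} "
                f"are not 1..{len(self.sweeps)} without gaps"
            )
        ids = {s.electrode_id for s in self.sweeps}
        if ids - {self.electrode_id}:
            raise StructuralError(
                f"electrode {self.electrode_id!r}: sweeps carry foreign ids {ids}"
            )
        grid = self.sweeps[0].potential
        for s in self.sweeps[1:]:
            if s.potential.size != grid.size:
                raise StructuralError(
                    f"electrode {self.electrode_id!r} sweep {s.sweep_index}: "
                    f"grid length {s.potential.size} != {grid.size}"
                )
            if np.abs(s.potential - grid).max() > GRID_TOLERANCE_V:
                raise StructuralError(
                    f"electrode {self.electrode_id!r} sweep {s.sweep_index}: "
                    f"potential grid deviates by more than {GRID_TOLERANCE_V} V"
                )

    @property
    def K(self) -> int:
        return len(self.sweeps)

    @property
    def potential_grid(self) -> np.ndarray:
        return self.sweeps[0].potential


@dataclass
class BatchDataset:
    """A batch of electrodes fabricated and CV-tested together."""

    batch_id: str
    electrodes: list[ElectrodeRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.electrode_id for e in self.electrodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StructuralError(f"batch {self.batch_id!r}: duplicate electrode ids {dupes}")

    def __iter__(self):
        return iter(self.electrodes)

    def __len__(self) -> int:
        return len(self.electrodes)

    def get(self, electrode_id: str) -> ElectrodeRecord:
        for e in self.electrodes:
            if e.electrode_id == electrode_id:
                return e
        raise KeyError(electrode_id)


@dataclass
class ImpedanceDataset:
    """Bode Z'' spectrum for one sensor, labelled treatment or control."""

    sensor_id: str
    group: str
    frequency: np.ndarray
    z_imag: np.ndarray

    VALID_GROUPS = ("treatment", "control")

    def __post_init__(self) -> None:
        self.group = str(self.group).strip().lower()
        if self.group not in self.VALID_GROUPS:
            raise ValueError(
                f"sensor {self.sensor_id!r}: unknown group {self.group!r}; "
                f"expected one of {self.VALID_GROUPS}"
            )
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.z_imag = np.asarray(self.z_imag, dtype=float)
        if self.frequency.shape != self.z_imag.shape:
            raise StructuralError(f"sensor {self.sensor_id!r}: length mismatch")
        if not (np.isfinite(self.frequency).all() and np.isfinite(self.z_imag).all()):
            raise StructuralError(f"sensor {self.sensor_id!r}: non-finite values")
        order = np.argsort(-self.frequency)
        self.frequency = self.frequency[order]
        self.z_imag = self.z_imag[order]
        if np.any(np.diff(self.frequency) >= 0):
            raise StructuralError(
                f"sensor {self.sensor_id!r}: duplicate or non-monotone frequencies"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

@dataclass
class CVDialect:
    """Column naming and units for CV CSV files."""

    electrode_col: str = "electrode_id"
    sweep_col: str = "sweep"
    potential_col: str = "potential_V"
    current_col: str = "current_uA"
    separator: str = ","

    def current_factor(self) -> float:
        return _unit_factor(self.current_col, _CURRENT_UNIT_FACTORS, "current")

    def potential_factor(self) -> float:
        return _unit_factor(self.potential_col, _POTENTIAL_UNIT_FACTORS, "potential")


def _unit_factor(column: str, table: dict[str, float], kind: str) -> float:
    m = re.search(r"_([a-zA-Zµ]+)$", column)
    unit = m.group(1).lower() if m else None
    if unit in table:
        return table[unit]
    logger.warning(
        "column %r declares no recognized %s unit; assuming canonical units", column, kind
    )
    return 1.0


def _numeric(series: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ParseError(
            f"non-numeric value {series[row]!r} in column {column!r} at data row {row}"
        )
    if out.isna().any():
        row = int(out.isna().idxmax())
        raise ParseError(f"missing value in column {column!r} at data row {row}")
    return out


def read_cv_long(path: str | Path, dialect: CVDialect | None = None) -> BatchDataset:
    """Read a canonical long-format CV CSV into a :class:`BatchDataset`.

    Rows may appear in any order; sweeps are sorted by index and points keep
    file order within each (electrode, sweep) group.
    """
    dialect = dialect or CVDialect()
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.separator, dtype=str, skipinitialspace=True)
    required = [dialect.electrode_col, dialect.sweep_col,
                dialect.potential_col, dialect.current_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path.name}: no data rows")

    df = df.copy()
    df["_sweep"] = _numeric(df[dialect.sweep_col], dialect.sweep_col).astype(int)
    df["_v"] = _numeric(df[dialect.potential_col], dialect.potential_col) \
        * dialect.potential_factor()
    df["_i"] = _numeric(df[dialect.current_col], dialect.current_col) \
        * dialect.current_factor()

    electrodes = []
    # keep first-appearance electrode order for stable downstream ids
    for eid in df[dialect.electrode_col].drop_duplicates():
        sub = df[df[dialect.electrode_col] == eid]
        sweeps = []
        indices = sorted(sub["_sweep"].unique())
        if indices != list(range(1, len(indices) + 1)):
            raise StructuralError(
                f"electrode {eid!r}: sweep indices {indices} have gaps or do not start at 1"
            )
        for k in indices:
            block = sub[sub["_sweep"] == k]
            sweeps.append(Voltammogram(
                potential=block["_v"].to_numpy(),
                current=block["_i"].to_numpy(),
                sweep_index=int(k),
                electrode_id=str(eid),
            ))
        electrodes.append(ElectrodeRecord(electrode_id=str(eid), sweeps=sweeps))
    return BatchDataset(batch_id=path.stem, electrodes=electrodes)


def read_cv_wide(path: str | Path, n_header_lines: int | None = None,
                 electrode_id: str | None = None) -> BatchDataset:
    """Read a potentiostat-style wide CV export (one V/I column pair per sweep).

    Metadata lines before the numeric table are skipped automatically when
    ``n_header_lines`` is None (sniffing: the first line whose fields are all
    numeric, minus one for the column-label line, starts the table).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path.name}: empty file")

    def _all_numeric(fields: Sequence[str]) -> bool:
        if not fields:
            return False
        try:
            [float(f) for f in fields]
            return True
        except ValueError:
            return False

    if n_header_lines is None:
        first_data = None
        for i, line in enumerate(lines):
            if _all_numeric([f for f in line.split(",") if f.strip() != ""]):
                first_data = i
                break
        if first_data is None or first_data == 0:
            raise FormatError(
                f"{path.name}: could not sniff a header line before numeric data; "
                "pass n_header_lines explicitly"
            )
        n_header_lines = first_data - 1  # the line right above data is the header

    df = pd.read_csv(path, skiprows=n_header_lines)
    if df.shape[1] % 2 != 0:
        raise FormatError(
            f"{path.name}: wide format needs an even number of data columns "
            f"(V/I pairs), got {df.shape[1]}"
        )
    n_sweeps = df.shape[1] // 2
    eid = electrode_id or path.stem
    sweeps = []
    for k in range(n_sweeps):
        vcol, icol = df.columns[2 * k], df.columns[2 * k + 1]
        v = _numeric(df[vcol], vcol).to_numpy() \
            * _unit_factor(str(vcol), _POTENTIAL_UNIT_FACTORS, "potential")
        i = _numeric(df[icol], icol).to_numpy() \
            * _unit_factor(str(icol), _CURRENT_UNIT_FACTORS, "current")
        sweeps.append(Voltammogram(v, i, sweep_index=k + 1, electrode_id=eid))
    record = ElectrodeRecord(electrode_id=eid, sweeps=sweeps)
    return BatchDataset(batch_id=path.stem, electrodes=[record])


def read_eis(path: str | Path) -> list[ImpedanceDataset]:
    """Read an EIS Bode table into one :class:`ImpedanceDataset` per sensor."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    required = ["sensor_id", "group", "frequency_Hz", "z_imag_ohm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path.name}: no data rows")
    df = df.copy()
    df["_f"] = _numeric(df["frequency_Hz"], "frequency_Hz")
    df["_z"] = _numeric(df["z_imag_ohm"], "z_imag_ohm")

    sensors = []
    for sid in df["sensor_id"].drop_duplicates():
        sub = df[df["sensor_id"] == sid]
        groups = sub["group"].str.strip().str.lower().unique()
        if len(groups) != 1:
            raise StructuralError(f"sensor {sid!r}: inconsistent group labels {list(groups)}")
        if sub["_f"].duplicated().any():
            f = sub["_f"][sub["_f"].duplicated()].iloc[0]
            raise StructuralError(f"sensor {sid!r}: duplicate frequency {f} Hz")
        sensors.append(ImpedanceDataset(
            sensor_id=str(sid), group=groups[0],
            frequency=sub["_f"].to_numpy(), z_imag=sub["_z"].to_numpy(),
        ))
    return sensors


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_batch_long(batch: BatchDataset, path: str | Path,
                     dialect: CVDialect | None = None, float_fmt: str = "%.9g") -> None:
    """Write a batch back to the canonical long CSV (round-trips with read_cv_long)."""
    dialect = dialect or CVDialect()
    rows = []
    for e in batch.electrodes:
        for s in e.sweeps:
            rows.append(pd.DataFrame({
                dialect.electrode_col: e.electrode_id,
                dialect.sweep_col: s.sweep_index,
                dialect.potential_col: s.potential,
                dialect.current_col: s.current,
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=float_fmt)


def write_eis(sensors: Iterable[ImpedanceDataset], path: str | Path,
              float_fmt: str = "%.9g") -> None:
    rows = [pd.DataFrame({
        "sensor_id": s.sensor_id, "group": s.group,
        "frequency_Hz": s.frequency, "z_imag_ohm": s.z_imag,
    }) for s in sensors]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=float_fmt)


def write_reports(report, out_dir: str | Path) -> list[Path]:
    """Write any report object exposing ``to_frames() -> dict[str, DataFrame]``.

    Emits one deterministic CSV per frame; returns written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in report.to_frames().items():
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.9g")
        written.append(p)
    return written
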