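"""Waveform and table I/O.

File dialects
-------------
Waveforms are two-column delimited text (time in ps, field amplitude in
arbitrary units). Comment lines start with ``#`` and may carry ``key = value``
metadata; the delimiter is auto-detected among comma, tab and whitespace,
because lab instruments emit all three.

The pellet-geometry and biochemistry tables are ordinary delimited tables with
a named header row (CSV or TSV). Small reference copies of both tables ship
with the package and are exposed through :func:`load_pellet_table` and
:func:`load_biochem_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, LookupError_, SchemaError, ValidationError

#: relative tolerance on time-step jitter; an FFT needs a uniform grid
GRID_JITTER_TOL = 1e-6

_MIN_SAMPLES = 8


def _check_uniform_grid(times: np.ndarray) -> float:
    """Return the (median) time step, raising ValidationError on a bad grid."""
    if times.ndim != 1 or times.size < _MIN_SAMPLES:
        raise ValidationError(
            f"waveform needs at least {_MIN_SAMPLES} samples, got {times.size}"
        )
    steps = np.diff(times)
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 1
        raise ValidationError(f"time axis not strictly increasing at row {row + 1}")
    dt = float(np.median(steps))
    jitter = np.abs(steps - dt) / dt
    if np.any(jitter > GRID_JITTER_TOL):
        row = int(np.argmax(jitter > GRID_JITTER_TOL)) + 1
        raise ValidationError(
            f"non-uniform time grid at row {row + 1}: step {steps[row - 1]:.6g} ps "
            f"vs median {dt:.6g} ps (tolerance {GRID_JITTER_TOL:g} relative)"
        )
    return dt


@dataclass(eq=False)
class Waveform:
    """A sampled THz field trace: amplitude versus delay-line time.

    Parameters
    ----------
    times:
        Sample times in ps; strictly increasing, uniform step.
    amplitudes:
        Field amplitude in arbitrary units, same length as ``times``.
    meta:
        Free-text metadata (sample id, ``channel`` in {reference, sample}, ...).
    """

    times: np.ndarray
    amplitudes: np.ndarray
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != self.times.shape:
            raise ValidationError(
                f"times ({self.times.size}) and amplitudes ({self.amplitudes.size}) "
                "must have equal length"
            )
        self._dt = _check_uniform_grid(self.times)
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValidationError("amplitudes contain non-finite values")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Sample spacing, ps."""
        return self._dt

    @property
    def span(self) -> float:
        """Total duration, ps."""
        return float(self.times[-1] - self.times[0])

    def copy(self, amplitudes: np.ndarray | None = None) -> "Waveform":
        amp = self.amplitudes if amplitudes is None else amplitudes
        return Waveform(self.times.copy(), np.array(amp, dtype=float), dict(self.meta))


def _detect_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # str.split(None): any whitespace


def read_waveform(path: str | Path, dialect: str | None = None) -> Waveform:
    """Read a two-column (ps, a.u.) delimited text file into a Waveform.

    ``dialect`` forces a delimiter ("," / "\\t" / None for whitespace);
    by default it is auto-detected from the first data row.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    amps: list[float] = []
    delim = dialect
    detected = dialect is not None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                elif body:
                    meta.setdefault("comment", body)
                continue
            if not detected:
                delim = _detect_delimiter(line)
                detected = True
            fields = line.split(delim)
            fields = [f for f in fields if f != ""]
            if len(fields) != 2:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                times.append(float(fields[0]))
                amps.append(float(fields[1]))
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-numeric field") from exc
    if len(times) < _MIN_SAMPLES:
        raise FormatError(
            f"{path.name}: waveform needs at least {_MIN_SAMPLES} samples, "
            f"got {len(times)}"
        )
    try:
        return Waveform(np.array(times), np.array(amps), meta)
    except ValidationError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc


def write_waveform(w: Waveform, path: str | Path, delimiter: str = "\t") -> None:
    """Write a Waveform as delimited text with '#' metadata headers.

    Floats are written with repr-level precision so read(write(w)) round-trips
    exactly.
    """
    path = Path(path)
    lines = [f"# {key} = {value}" for key, value in w.meta.items()]
    lines.extend(
        f"{float(t)!r}{delimiter}{float(a)!r}" for t, a in zip(w.times, w.amplitudes)
    )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pellet geometry


def density_from_dimensions(mass_mg: float, diameter_mm: float, thickness_mm: float) -> float:
    """Pellet density rho_o = m / (pi D^2/4 * d), in mg/mm^3.

    The cylinder-volume relation for a pressed pellet of mass m, diameter D
    and thickness d.
    """
    if mass_mg <= 0 or diameter_mm <= 0 or thickness_mm <= 0:
        raise ValidationError("mass, diameter and thickness must all be positive")
    return mass_mg / (math.pi * diameter_mm**2 / 4.0 * thickness_mm)


@dataclass
class PelletGeometry:
    """Macroscopic pellet characteristics; density is derived on construction."""

    diameter_mm: float
    thickness_mm: float
    mass_mg: float
    class_label: str
    density_mg_mm3: float = field(init=False)

    def __post_init__(self) -> None:
        self.density_mg_mm3 = density_from_dimensions(
            self.mass_mg, self.diameter_mm, self.thickness_mm
        )


_PELLET_ALIASES = {
    "class": "class",
    "type": "class",
    "class_label": "class",
    "type_of_pellet": "class",
    "diameter": "diameter",
    "diameter_mm": "diameter",
    "thickness": "thickness",
    "thickness_mm": "thickness",
    "weight": "weight",
    "weight_mg": "weight",
    "mass": "weight",
    "mass_mg": "weight",
}


def read_pellet_table(path: str | Path) -> list[PelletGeometry]:
    """Read a pellet-geometry table (columns class, diameter, thickness, weight).

    Extra columns (e.g. a printed density or moulding pressure) are ignored.
    Each row's density is recomputed from its dimensions.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "_")
        if key in _PELLET_ALIASES:
            cols.setdefault(_PELLET_ALIASES[key], col)
    missing = {"class", "diameter", "thickness", "weight"} - set(cols)
    if missing:
        raise SchemaError(f"pellet table missing column(s): {sorted(missing)}")
    records: list[PelletGeometry] = []
    for idx, row in df.iterrows():
        label = str(row[cols["class"]]).strip().lower().replace("-", "_").replace(" ", "_")
        try:
            records.append(
                PelletGeometry(
                    diameter_mm=float(row[cols["diameter"]]),
                    thickness_mm=float(row[cols["thickness"]]),
                    mass_mg=float(row[cols["weight"]]),
                    class_label=label,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"pellet table row {idx + 1}: {exc}") from exc
    return records


def load_pellet_table() -> list[PelletGeometry]:
    """The packaged nine-pellet reference table (6 diabetic, 3 non-diabetic)."""
    with resources.as_file(
        resources.files("thzpellet.data") / "pellet_geometry.csv"
    ) as p:
        return read_pellet_table(p)


# ---------------------------------------------------------------------------
# biochemistry


@dataclass
class BiochemTable:
    """Blood-plasma biochemistry: one row per analyte, both class values."""

    frame: pd.DataFrame  # columns: analyte, non_diabetic, diabetic, units, reference_interval

    def analytes(self) -> list[str]:
        return list(self.frame["analyte"])

    def _row(self, analyte: str) -> pd.Series:
        mask = self.frame["analyte"].str.lower() == analyte.strip().lower()
        if not mask.any():
            raise LookupError_(f"unknown analyte: {analyte!r}")
        return self.frame[mask].iloc[0]


def read_biochem_table(path: str | Path) -> BiochemTable:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    missing = {"analyte", "non_diabetic", "diabetic"} - set(df.columns)
    if missing:
        raise SchemaError(f"biochemistry table missing column(s): {sorted(missing)}")
    return BiochemTable(df)


def load_biochem_table() -> BiochemTable:
    """The packaged biochemistry reference table (8 analytes)."""
    with resources.as_file(
        resources.files("thzpellet.data") / "biochemistry.csv"
    ) as p:
        return read_biochem_table(p)


def fold_change(table: BiochemTable, analyte: str) -> float:
    """Diabetic / non-diabetic concentration ratio, round-half-up to 1 decimal.

    One decimal matches how such fold changes are conventionally quoted.
    """
    row = table._row(analyte)
    non_diab = float(row["non_diabetic"])
    diab = float(row["diabetic"])
    if non_diab <= 0 or diab <= 0:
        raise ValidationError(f"analyte {analyte!r}: both values must be positive")
    ratio = diab / non_diab
    return float(Decimal(repr(ratio)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
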