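"""Readers and writers for the plain-text formats the pipeline consumes.

All external files are diffable text:

* **isotherm traces** — delimited text (default comma, header row) with
  one area column (Å²/molecule) and one pressure column (mN/m);
* **diffraction maps** — two header lines ``# qxy: ...`` / ``# qz: ...``
  followed by the intensity matrix, one Qz row per line;
* **spectra** — two columns, wavenumber (cm⁻¹) and absorbance;
* **coordinate frames** — extended-XYZ style: atom count, a comment
  line carrying ``box="Lx Ly Lz"``, then
  ``name  x  y  z  mol_id  mol_type`` records in nm.

Units are fixed inside the package (Å², mN/m, Å⁻¹, cm⁻¹, nm); any
conversion happens in these readers only.
"""

from __future__ import annotations

import io as _io
import json
import logging
import re
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atr import Spectrum
from .gixd import GIXDMap
from .isotherm import Isotherm
from .traj import Frame

__all__ = [
    "FormatError",
    "TraceDialect",
    "read_isotherm",
    "write_isotherm",
    "read_map",
    "write_map",
    "read_spectrum",
    "write_spectrum",
    "read_frame",
    "write_frame",
    "read_frames",
    "load_config",
    "setup_logging",
]

logger = logging.getLogger("monolayer")


class FormatError(ValueError):
    """An input file does not match its declared dialect/format."""


def setup_logging(verbosity: int = 0) -> None:
    """Structured logging to stderr; verbosity 0=warning, 1=info, 2=debug."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class TraceDialect:
    """Column roles and CSV dialect of an isotherm trace file."""

    delimiter: str = ","
    decimal: str = "."
    area_column: str = "area"          # Å²/molecule
    pressure_column: str = "pressure"  # mN/m
    time_column: str | None = None     # optional, s


def read_isotherm(
    path: str | Path,
    dialect: TraceDialect | None = None,
    temperature: float = 294.0,
    subphase: str = "water",
    sort: bool = True,
) -> Isotherm:
    """Read a delimited-text π–A trace.

    With ``sort=True`` rows are ordered by decreasing area (compression
    convention); pass ``sort=False`` to keep file order, e.g. for
    time-ordered compression–expansion traces.
    """
    dialect = dialect or TraceDialect()
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal)
    except Exception as exc:  # noqa: BLE001 - surface any parser failure as ours
        raise FormatError(f"{path}: cannot parse trace file: {exc}") from exc
    for col in (dialect.area_column, dialect.pressure_column):
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing column {col!r} (found {list(df.columns)})"
            )
    for col in (dialect.area_column, dialect.pressure_column):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size:
            raise FormatError(f"{path}: non-numeric value in {col!r} at data row {bad[0]}")
        if coerced.isna().any():
            raise FormatError(f"{path}: empty cell in column {col!r}")
        df[col] = coerced
    if len(df) < 3:
        raise FormatError(f"{path}: trace has {len(df)} rows; need >= 3")
    area = df[dialect.area_column].to_numpy(dtype=float)
    pressure = df[dialect.pressure_column].to_numpy(dtype=float)
    if sort:
        order = np.argsort(area)[::-1]
        area, pressure = area[order], pressure[order]
    logger.info("read isotherm %s: %d points", path, area.size)
    return Isotherm(area, pressure, temperature, subphase, metadata={"path": str(path)})


def write_isotherm(iso: Isotherm, path: str | Path, dialect: TraceDialect | None = None) -> None:
    dialect = dialect or TraceDialect()
    df = pd.DataFrame(
        {dialect.area_column: iso.area, dialect.pressure_column: iso.pressure}
    )
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.12g")


def read_map(path: str | Path, wavelength: float = 1.55) -> GIXDMap:
    """Read a plain-text diffraction map with ``# qxy:`` / ``# qz:`` headers."""
    qxy = qz = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(qxy|qz)\s*:\s*(.*)$", line, re.IGNORECASE)
                if m:
                    vec = np.array([float(v) for v in m.group(2).split()])
                    if m.group(1).lower() == "qxy":
                        qxy = vec
                    else:
                        qz = vec
                continue
            rows.append([float(v) for v in line.split()])
    if qxy is None or qz is None:
        raise FormatError(f"{path}: missing '# qxy:' or '# qz:' axis header")
    intensity = np.array(rows, dtype=float)
    if intensity.shape != (qz.size, qxy.size):
        raise FormatError(
            f"{path}: matrix shape {intensity.shape} does not match axes "
            f"({qz.size}, {qxy.size})"
        )
    resolution = float(np.median(np.diff(qxy)))
    logger.info("read map %s: %s grid", path, intensity.shape)
    return GIXDMap(qxy=qxy, qz=qz, intensity=intensity, wavelength=wavelength,
                   resolution=resolution, metadata={"path": str(path)})


def write_map(gmap: GIXDMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        # full float precision so round trips are bitwise on the axes
        fh.write("# qxy: " + " ".join(f"{v:.17g}" for v in gmap.qxy) + "\n")
        fh.write("# qz: " + " ".join(f"{v:.17g}" for v in gmap.qz) + "\n")
        np.savetxt(fh, gmap.intensity, fmt="%.17g")


def read_spectrum(
    path: str | Path, polarization: str = "unpolarized", stage: str = ""
) -> Spectrum:
    """Read a two-column wavenumber/absorbance text file."""
    try:
        data = np.loadtxt(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse spectrum: {exc}") from exc
    if data.ndim != 2 or data.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns, got shape {data.shape}")
    return Spectrum(data[:, 0], data[:, 1], polarization=polarization, stage=stage,
                    metadata={"path": str(path)})


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([spec.wavenumber, spec.absorbance]), fmt="%.12g")


_BOX_RE = re.compile(r'box="([^"]+)"')


def read_frame(path_or_buffer) -> Frame:
    """Read one extended-XYZ frame (box on the comment line, nm units)."""
    if hasattr(path_or_buffer, "read"):
        fh = path_or_buffer
        label = "<buffer>"
        return _parse_frame(fh, label)
    with open(path_or_buffer) as fh:
        return _parse_frame(fh, str(path_or_buffer))


def _parse_frame(fh, label: str) -> Frame:
    header = fh.readline()
    if not header.strip():
        raise FormatError(f"{label}: empty frame")
    try:
        n = int(header.split()[0])
    except ValueError as exc:
        raise FormatError(f"{label}: first line must be the atom count") from exc
    comment = fh.readline()
    m = _BOX_RE.search(comment)
    if not m:
        raise FormatError(
            f"{label}: comment line lacks box=\"Lx Ly Lz\" (periodic descriptors need it)"
        )
    box = np.array([float(v) for v in m.group(1).split()])
    names, pos, mids, mtypes = [], [], [], []
    for i in range(n):
        line = fh.readline()
        parts = line.split()
        if len(parts) < 6:
            raise FormatError(f"{label}: atom line {i} malformed: {line!r}")
        names.append(parts[0])
        pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
        mids.append(int(parts[4]))
        mtypes.append(parts[5])
    return Frame(
        positions=np.array(pos),
        box=box,
        mol_ids=np.array(mids),
        mol_types=np.array(mtypes, dtype=object),
        atom_names=np.array(names, dtype=object),
        metadata={"path": label},
    )


def write_frame(frame: Frame, path_or_buffer) -> None:
    buf = _io.StringIO()
    buf.write(f"{len(frame)}\n")
    buf.write(f'box="{frame.box[0]:.12g} {frame.box[1]:.12g} {frame.box[2]:.12g}"\n')
    for i in range(len(frame)):
        x, y, z = frame.positions[i]
        buf.write(
            f"{frame.atom_names[i]} {x:.12g} {y:.12g} {z:.12g} "
            f"{frame.mol_ids[i]} {frame.mol_types[i]}\n"
        )
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(buf.getvalue())
    else:
        Path(path_or_buffer).write_text(buf.getvalue())


def read_frames(path: str | Path) -> list[Frame]:
    """Read concatenated extended-XYZ frames from one file."""
    frames = []
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.strip():
                break
            fh.seek(pos)
            frames.append(_parse_frame(fh, str(path)))
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return frames


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
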