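"""Readers and writers for the package's plain-text and TIFF formats."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .afm.heightmap import HeightMap
from .dsc import Thermogram
from .errors import ParseError
from .kinetics import KineticTrace

__all__ = ["read_trace", "read_thermogram", "read_heightmap", "read_two_column"]


def read_two_column(path: str | Path, delimiter: str | None = None):
    """Parse a 2-column numeric CSV/TSV with an optional single header row.

    Returns (x, y, header_fields).  Raises :class:`ParseError` with the
    offending line number for non-numeric rows past the header.
    """
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","

    header: list[str] = []
    rows = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(delimiter)]
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if lineno == 1 and not rows:
                header = parts
                continue
            raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
    if not rows:
        raise ParseError(f"{path}: no numeric data rows")
    arr = np.array(rows, dtype=float)
    return arr[:, 0], arr[:, 1], header


def _sorted_with_warning(x, y, what: str):
    if not np.all(np.diff(x) > 0):
        warnings.warn(f"{what}: abscissa not strictly increasing; sorting")
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        keep = np.concatenate([[True], np.diff(x) > 0])
        x, y = x[keep], y[keep]
    return x, y


def read_trace(path: str | Path, delimiter: str | None = None) -> KineticTrace:
    """Read a kinetic trace; times sorted (with a warning) if needed."""
    t, y, header = read_two_column(path, delimiter)
    t, y = _sorted_with_warning(t, y, str(path))
    if len(t) < 5:
        raise ParseError(f"{path}: need at least 5 points, got {len(t)}")
    label = ",".join(header) if header else Path(path).stem
    return KineticTrace(t=t, y=y, label=label)


def read_thermogram(path: str | Path, scan_index: int = 1,
                    delimiter: str | None = None) -> Thermogram:
    T, Cp, header = read_two_column(path, delimiter)
    T, Cp = _sorted_with_warning(T, Cp, str(path))
    if len(T) < 20:
        raise ParseError(f"{path}: need at least 20 points, got {len(T)}")
    label = ",".join(header) if header else Path(path).stem
    return Thermogram(T=T, Cp=Cp, scan_index=scan_index, label=label)


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        return {}
    return json.loads(sidecar.read_text())


def read_heightmap(path: str | Path, pixel_size: float | None = None) -> HeightMap:
    """Read a TIFF or ASCII-matrix height map.

    The nm-per-pixel scale comes from ``pixel_size`` or from a JSON sidecar
    ``<path>.json`` with key ``pixel_size_nm``.  Integer TIFFs are scaled by
    the sidecar's ``scale_nm_per_count``.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_nm")
    if pixel_size is None:
        raise ParseError(
            f"{path}: pixel size unknown; provide a --pixel-size flag or a "
            f"{path.name}.json sidecar with key 'pixel_size_nm'"
        )

    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
        if np.issubdtype(data.dtype, np.integer):
            scale = meta.get("scale_nm_per_count", 1.0)
            data = data.astype(float) * scale
        else:
            data = data.astype(float)
    else:
        try:
            data = np.loadtxt(path)
        except ValueError as exc:
            raise ParseError(f"{path}: non-rectangular or non-numeric ASCII matrix: {exc}") from None
        if data.ndim != 2:
            raise ParseError(f"{path}: expected a 2-D matrix, got shape {data.shape}")
    return HeightMap(heights=data, pixel_size=float(pixel_size), label=path.stem)
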