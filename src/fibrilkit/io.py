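"""Readers and writers for the package's on-disk formats.

- Kinetics: delimited text with columns ``time_min, intensity, replicate,
  condition`` (header required, '.' decimal point).
- AFM: single-channel float TIFF (nm) or a Gwyddion-style ASCII matrix
  export with ``#``-prefixed header lines; physical width/height are parsed
  from the header when present, else the default 5 um / 1024 px calibration
  applies.
- FTIR: two-column delimited text ``wavenumber_cm1, absorbance``; either
  monotone direction is accepted.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .afm import DEFAULT_PIXEL_SIZE_NM, HeightMap
from .errors import ValidationError
from .ftir import Spectrum
from .kinetics import KineticTrace

__all__ = [
    "read_kinetics_csv",
    "write_kinetics_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_heightmap",
    "write_heightmap_ascii",
    "write_heightmap_tiff",
    "write_json",
]

_UNIT_SCALE_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "mm": 1e6, "m": 1e9}


def read_kinetics_csv(path: str | Path, sep: str = ",") -> list[KineticTrace]:
    """Load replicate traces grouped by (condition, replicate)."""
    df = pd.read_csv(path, sep=sep)
    required = {"time_min", "intensity", "replicate", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"kinetics file missing columns: {sorted(missing)}")
    traces = []
    for (condition, replicate), grp in df.groupby(
        ["condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_min")
        traces.append(
            KineticTrace(
                times=grp["time_min"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                condition=str(condition),
                replicate=int(replicate),
            )
        )
    return traces


def write_kinetics_csv(path: str | Path, traces: Iterable[KineticTrace]) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_min": tr.times,
                "intensity": tr.intensities,
                "replicate": tr.replicate,
                "condition": tr.condition,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, sep: str = ",") -> Spectrum:
    df = pd.read_csv(path, sep=sep)
    if not {"wavenumber_cm1", "absorbance"} <= set(df.columns):
        raise ValidationError(
            "spectrum file needs columns wavenumber_cm1, absorbance"
        )
    return Spectrum(
        wavenumbers=df["wavenumber_cm1"].to_numpy(float),
        absorbance=df["absorbance"].to_numpy(float),
    )


def write_spectrum_csv(path: str | Path, spectrum: Spectrum) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": spectrum.wavenumbers, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)


def _parse_ascii_header(lines: list[str]) -> dict[str, float]:
    """Extract physical sizes (nm) from '# Width: 5.0 µm'-style header lines."""
    out: dict[str, float] = {}
    pattern = re.compile(
        r"#\s*(width|height|xreal|yreal)\s*[:=]\s*([0-9.eE+-]+)\s*(nm|um|µm|mm|m)?",
        re.IGNORECASE,
    )
    for line in lines:
        m = pattern.search(line)
        if m:
            key = m.group(1).lower()
            key = {"xreal": "width", "yreal": "height"}.get(key, key)
            scale = _UNIT_SCALE_NM.get((m.group(3) or "nm").lower(), 1.0)
            out[key] = float(m.group(2)) * scale
    return out


def read_heightmap(
    path: str | Path, pixel_size: float | None = None, source_id: str | None = None
) -> HeightMap:
    """Load a topography from TIFF or Gwyddion-style ASCII export.

    Explicit ``pixel_size`` (nm) wins; otherwise ASCII headers carrying the
    physical width are used; otherwise the default 5 um / 1024 px
    calibration applies.
    """
    path = Path(path)
    source = source_id if source_id is not None else path.stem
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = np.asarray(tifffile.imread(path), dtype=float)
        ps = pixel_size if pixel_size is not None else DEFAULT_PIXEL_SIZE_NM
        return HeightMap(heights=heights, pixel_size=ps, source_id=source)
    header_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                break
    heights = np.loadtxt(path, comments="#")
    if heights.ndim != 2:
        raise ValidationError(f"{path}: expected a 2-D matrix")
    if pixel_size is not None:
        ps = pixel_size
    else:
        meta = _parse_ascii_header(header_lines)
        if "width" in meta:
            ps = meta["width"] / heights.shape[1]
        else:
            ps = DEFAULT_PIXEL_SIZE_NM
    return HeightMap(heights=heights, pixel_size=ps, source_id=source)


def write_heightmap_ascii(path: str | Path, hmap: HeightMap) -> None:
    """Gwyddion-style ASCII matrix export with physical sizes in the header."""
    ny, nx = hmap.heights.shape
    header = (
        f"# Channel: Height\n"
        f"# Width: {nx * hmap.pixel_size:.6g} nm\n"
        f"# Height: {ny * hmap.pixel_size:.6g} nm\n"
        f"# Value units: nm\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, hmap.heights, fmt="%.6g")


def write_heightmap_tiff(path: str | Path, hmap: HeightMap) -> None:
    tifffile.imwrite(path, hmap.heights.astype(np.float32))


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
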