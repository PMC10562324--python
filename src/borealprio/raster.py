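"""Single-band raster I/O in the ESRI ASCII grid format.

Plain-text, row-major from the north-west origin; adequate for the
synthetic landscapes this package produces and trivially diffable.
A minimal affine placement (lower-left corner + cell size) is carried
through; no CRS handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import numpy as np

__all__ = ["GridMeta", "write_ascii_grid", "read_ascii_grid",
           "write_legend_csv"]

NODATA = -9999.0


@dataclass(frozen=True)
class GridMeta:
    ncols: int
    nrows: int
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 96.0
    nodata: float = NODATA


def write_ascii_grid(path: str | Path, array: np.ndarray,
                     cellsize: float = 96.0, xllcorner: float = 0.0,
                     yllcorner: float = 0.0,
                     mask: np.ndarray | None = None,
                     fmt: str = "%.6g") -> None:
    """Write a 2-D array; masked-out cells become the NODATA value."""
    array = np.asarray(array, dtype=float)
    if array.ndim != 2:
        raise ValueError("expected a 2-D array")
    data = array.copy()
    if mask is not None:
        data[~mask] = NODATA
    nrows, ncols = data.shape
    header = (f"ncols {ncols}\nnrows {nrows}\n"
              f"xllcorner {xllcorner}\nyllcorner {yllcorner}\n"
              f"cellsize {cellsize}\nNODATA_value {NODATA}\n")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path: str | Path) -> Tuple[np.ndarray, GridMeta]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    with open(path) as fh:
        header: Dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    meta = GridMeta(
        ncols=int(header["ncols"]), nrows=int(header["nrows"]),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
        nodata=header.get("nodata_value", NODATA),
    )
    data = np.atleast_2d(data)
    data[data == meta.nodata] = np.nan
    return data, meta


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_legend_csv(path: str | Path, legend: Dict[int, str],
                     name: str = "class") -> None:
    """CSV legend for a categorical raster (code,label)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"code,{name}\n")
        for code, label in sorted(legend.items()):
            fh.write(f"{code},{label}\n")
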