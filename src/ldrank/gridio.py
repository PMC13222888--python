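"""Esri ASCII grid I/O for integer category rasters and real-valued surfaces.

The ASCII grid format is a plain-text header (ncols, nrows, xllcorner,
yllcorner, cellsize, NODATA_value) followed by row-major cell values, top row
first.  Integer grids round-trip exactly; real grids round-trip to repr
precision.
"""

from __future__ import annotations

import numpy as np

from .landcover import DEFAULT_SCHEME, ClassScheme, LandCoverGrid

__all__ = ["read_ascii_grid", "write_ascii_grid", "read_landcover", "write_landcover"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_ascii_grid(
    path,
    values: np.ndarray,
    nodata=-9999,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
) -> None:
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("grid must be 2-D")
    nrows, ncols = values.shape
    is_int = np.issubdtype(values.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if is_int else "%.10g"
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_grid(path, dtype=float) -> tuple[np.ndarray, dict]:
    """Read an ASCII grid; returns (values, header dict)."""
    header: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                key = parts[0].lower()
                header[key] = float(parts[1]) if "." in parts[1] or "e" in parts[1].lower() else int(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, dtype=dtype, ndmin=2)
    for key in ("ncols", "nrows"):
        if key in header and values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(
                f"grid body shape {values.shape} does not match header "
                f"({header.get('nrows')}, {header.get('ncols')})"
            )
    return values, header


def write_landcover(path, grid: LandCoverGrid) -> None:
    # cells are squares: cellsize = sqrt(cell_area) in km
    write_ascii_grid(
        path,
        grid.values.astype(np.int64),
        nodata=grid.nodata,
        cellsize=float(np.sqrt(grid.cell_area)),
    )


def read_landcover(
    path, epoch: int = 0, scheme: ClassScheme = DEFAULT_SCHEME
) -> LandCoverGrid:
    values, header = read_ascii_grid(path, dtype=np.int64)
    nodata = int(header.get("nodata_value", -9999))
    cellsize = float(header.get("cellsize", 1.0))
    return LandCoverGrid(
        values, nodata=nodata, cell_area=cellsize**2, epoch=epoch, scheme=scheme
    )
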