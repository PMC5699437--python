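"""Minimal aligned-raster container and plain-text grid I/O.

Gridded covariates (land-use class fractions, cropland-intensity class,
human population density, country/subregion IDs) are held as a stack of
equally shaped 2-D arrays sharing one geotransform. Layers are stored on
disk as ESRI ASCII grids (``.asc``), one file per layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0

#: collapsed land-use levels used throughout the analysis
LAND_USE_LEVELS = (
    "seminatural",
    "pasture",
    "cropland_low",
    "cropland_medium",
    "cropland_high",
    "urban",
)

#: raw land-use classes carried by the fraction layers (before collapsing)
FRACTION_CLASSES = (
    "primary",
    "secondary",
    "cropland",
    "plantation",
    "pasture",
    "urban",
)

#: integer codes of the cropland/pasture use-intensity layer
INTENSITY_CODES = {
    0: "other",
    1: "extensive_pasture",
    2: "intensive_pasture",
    3: "light",
    4: "moderate",
    5: "intensive",
}


@dataclass
class RasterStack:
    """Aligned single-band grids sharing origin, cell size and nodata.

    ``layers`` maps layer name -> 2-D float array. Fraction layers are named
    ``frac_<class>`` for each class in :data:`FRACTION_CLASSES`; the
    remaining layers are ``intensity_class``, ``hpd``, ``country_id`` and
    ``subregion_id``.
    """

    layers: dict[str, np.ndarray]
    cellsize: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)  # x_ll, y_ll
    nodata: float = NODATA
    crs: str = "local-equal-area"
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"misaligned layers: shapes {shapes}")

    def mask(self) -> np.ndarray:
        """Boolean grid of cells where every layer is defined."""
        m = np.ones(self.shape, dtype=bool)
        for a in self.layers.values():
            m &= a != self.nodata
            m &= ~np.isnan(a)
        return m

    def fractions(self) -> dict[str, np.ndarray]:
        return {
            c: self.layers[f"frac_{c}"] for c in FRACTION_CLASSES if f"frac_{c}" in self.layers
        }


def write_ascii_grid(
    path: str | Path,
    array: np.ndarray,
    cellsize: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    nodata: float = NODATA,
) -> None:
    """Write one layer as an ESRI ASCII grid (row 0 = northernmost row)."""
    a = np.asarray(array, dtype=float)
    nrows, ncols = a.shape
    out = np.where(np.isnan(a), nodata, a)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.10g}\n")
        fh.write(f"yllcorner {origin[1]:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Read an ESRI ASCII grid; returns (array, cellsize, origin, nodata)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    a = np.asarray(rows, dtype=float)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if a.shape != (nrows, ncols):
        raise ValueError(f"grid body {a.shape} does not match header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", NODATA)
    return a, header["cellsize"], (header["xllcorner"], header["yllcorner"]), nodata


def write_stack(stack: RasterStack, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, layer in stack.layers.items():
        p = directory / f"{name}.asc"
        write_ascii_grid(p, layer, stack.cellsize, stack.origin, stack.nodata)
        written.append(p)
    return written


def read_stack(directory: str | Path) -> RasterStack:
    directory = Path(directory)
    layers = {}
    cellsize, origin, nodata = 1.0, (0.0, 0.0), NODATA
    paths = sorted(directory.glob("*.asc"))
    if not paths:
        raise FileNotFoundError(f"no .asc layers under {directory}")
    for p in paths:
        a, cs, org, nd = read_ascii_grid(p)
        layers[p.stem] = a
        if not math.isclose(cs, cellsize) and len(layers) > 1:
            raise ValueError("layers disagree on cellsize")
        cellsize, origin, nodata = cs, org, nd
    return RasterStack(layers=layers, cellsize=cellsize, origin=origin, nodata=nodata)
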