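"""Driver indicator tables: zonal aggregation, interpolation, normalization
and orientation.

Counties (banners) are the analysis units; each is described by a set of
indicators organised in four driver groups — natural, human activities,
economic and urbanisation.  Before partial-order ranking every indicator is
min–max normalised to [0, 1] and oriented so that larger values consistently
mean a stronger land-degradation influence; indicators whose raw reading
works the other way (precipitation, distances to built-up features) are
flipped with v -> 1 - v.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "IndicatorMeta",
    "DriverTable",
    "NormalizedTable",
    "PointSamples",
    "GridSpec",
    "default_metas",
    "zonal_mean",
    "idw_interpolate",
    "normalize",
    "orient",
    "collinearity_screen",
]

GROUPS = ("natural", "human", "economic", "urbanisation")
ORIENTATIONS = ("direct", "inverse")


@dataclass(frozen=True)
class IndicatorMeta:
    """Name, driver group, measurement unit and effect direction of one
    indicator.  ``orientation="inverse"`` means larger raw values indicate a
    *weaker* degradation influence and the normalized column must be flipped."""

    name: str
    group: str
    unit: str = ""
    orientation: str = "direct"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown driver group {self.group!r}; expected one of {GROUPS}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")


def default_metas() -> list[IndicatorMeta]:
    """The twelve-indicator configuration: 2 natural, 2 human, 4 economic and
    4 urbanisation indicators, with precipitation and the four distance
    indicators inverse-oriented."""
    return [
        IndicatorMeta("annual_mean_temperature", "natural", "degC"),
        IndicatorMeta("annual_total_precipitation", "natural", "mm", "inverse"),
        IndicatorMeta("population_density", "human", "persons km-2"),
        IndicatorMeta("sheep_density", "human", "heads km-2"),
        IndicatorMeta("primary_gdp_density", "economic", "1e4 CNY km-2"),
        IndicatorMeta("secondary_gdp_density", "economic", "1e4 CNY km-2"),
        IndicatorMeta("tertiary_gdp_density", "economic", "1e4 CNY km-2"),
        IndicatorMeta("total_gdp_density", "economic", "1e4 CNY km-2"),
        IndicatorMeta("distance_to_urban_land", "urbanisation", "km", "inverse"),
        IndicatorMeta("distance_to_rural_settlements", "urbanisation", "km", "inverse"),
        IndicatorMeta("distance_to_roads", "urbanisation", "km", "inverse"),
        IndicatorMeta("distance_to_other_builtup", "urbanisation", "km", "inverse"),
    ]


@dataclass
class DriverTable:
    """Units × indicators matrix of raw driver values."""

    values: pd.DataFrame  # index = unit ids, columns = indicator names
    metas: list[IndicatorMeta]
    epoch: str = ""

    def __post_init__(self) -> None:
        names = [m.name for m in self.metas]
        if len(set(names)) != len(names):
            raise ValueError("indicator names must be unique")
        if list(self.values.columns) != names:
            raise ValueError("table columns must match indicator metadata order")
        if self.values.index.duplicated().any():
            raise ValueError("unit ids must be unique")

    @property
    def unit_ids(self) -> list:
        return list(self.values.index)

    def group_columns(self, group: str) -> list[str]:
        return [m.name for m in self.metas if m.group == group]

    def meta(self, name: str) -> IndicatorMeta:
        for m in self.metas:
            if m.name == name:
                return m
        raise KeyError(name)

    # --- I/O ------------------------------------------------------------
    def to_csv(self, path, meta_path=None) -> None:
        self.values.to_csv(path, index_label="unit")
        if meta_path is not None:
            payload = {
                "epoch": self.epoch,
                "indicators": [vars(m) for m in self.metas],
            }
            with open(meta_path, "w") as fh:
                json.dump(payload, fh, indent=2)

    @classmethod
    def from_csv(cls, path, meta_path) -> "DriverTable":
        df = pd.read_csv(path, index_col="unit")
        with open(meta_path) as fh:
            payload = json.load(fh)
        metas = [IndicatorMeta(**m) for m in payload["indicators"]]
        return cls(df[[m.name for m in metas]], metas, epoch=payload.get("epoch", ""))


@dataclass
class NormalizedTable(DriverTable):
    """A driver table after min–max normalization; ``oriented`` records
    whether inverse indicators have been flipped yet."""

    oriented: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise ValueError("normalized values must lie in [0, 1]")


@dataclass(frozen=True)
class PointSamples:
    """Scattered station observations (x, y, value)."""

    x: np.ndarray
    y: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if not (x.shape == y.shape == v.shape) or x.ndim != 1 or x.size == 0:
            raise ValueError("x, y, value must be equal-length non-empty 1-D arrays")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("sample coordinates must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "value", v)

    @classmethod
    def from_csv(cls, path) -> "PointSamples":
        df = pd.read_csv(path)
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), df["value"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"x": self.x, "y": self.y, "value": self.value}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: Esri-style lower-left origin, square cells.
    Cell (r, c) has its centre at (xmin + (c + 1/2)·cellsize,
    ymin + (nrows - r - 1/2)·cellsize), row 0 being the top row."""

    nrows: int
    ncols: int
    xmin: float = 0.0
    ymin: float = 0.0
    cellsize: float = 1.0

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        cx = self.xmin + (cols + 0.5) * self.cellsize
        cy = self.ymin + (self.nrows - rows - 0.5) * self.cellsize
        return np.meshgrid(cx, cy)


def zonal_mean(
    raster: np.ndarray,
    zones: np.ndarray,
    unit_ids,
    nodata: float | None = None,
) -> pd.Series:
    """Mean raster value per zone, one value per requested unit.

    NaN cells (and cells equal to ``nodata``, if given) are ignored; a zone
    with no valid cell raises, naming the unit.
    """
    raster = np.asarray(raster, dtype=float)
    zones = np.asarray(zones)
    if raster.shape != zones.shape:
        raise ValueError(f"raster shape {raster.shape} != zones shape {zones.shape}")
    valid = np.isfinite(raster)
    if nodata is not None:
        valid &= raster != nodata

    out = {}
    for uid in unit_ids:
        in_zone = zones == uid
        if not in_zone.any():
            raise ValueError(f"unit {uid!r} does not occur in the zone map")
        sel = in_zone & valid
        if not sel.any():
            raise ValueError(f"unit {uid!r} has no valid raster cells")
        out[uid] = float(raster[sel].mean())
    return pd.Series(out)


def idw_interpolate(
    samples: PointSamples, grid: GridSpec, power: float = 2.0
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of point samples onto a grid.

    Cell value = Σ w_k v_k / Σ w_k with w_k = d_k^(−power) over *all* samples
    (no neighbourhood cutoff).  A cell whose centre coincides with a sample
    point takes that sample's value exactly.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    gx, gy = grid.cell_centres()
    dx = gx[..., None] - samples.x
    dy = gy[..., None] - samples.y
    d = np.hypot(dx, dy)

    exact = d == 0.0
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[exact] = 0.0
    out = np.where(
        exact.any(axis=-1),
        samples.value[np.argmax(exact, axis=-1)],
        (w * samples.value).sum(axis=-1) / np.maximum(w.sum(axis=-1), np.finfo(float).tiny),
    )
    return out


def normalize(table: DriverTable) -> NormalizedTable:
    """Min–max normalize each indicator column to [0, 1].

    v -> (v − min) / (max − min) per column; a constant column (max = min)
    maps to 0.5 everywhere, a neutral value that leaves all pairwise
    comparisons on that column tied.
    """
    if table.values.empty:
        raise ValueError("driver table is empty")
    df = table.values.astype(float)
    lo, hi = df.min(axis=0), df.max(axis=0)
    span = hi - lo
    const = span == 0
    span = span.where(~const, 1.0)
    out = (df - lo) / span
    out.loc[:, const[const].index] = 0.5
    return NormalizedTable(out, list(table.metas), epoch=table.epoch, oriented=False)


def orient(table: NormalizedTable) -> NormalizedTable:
    """Flip inverse-oriented indicator columns with v -> 1 − v so that every
    column reads "larger = stronger degradation influence".

    Orienting a table twice raises: the flip is an involution and applying it
    again would silently undo the orientation.
    """
    if table.oriented:
        raise ValueError("table is already oriented")
    df = table.values.copy()
    for m in table.metas:
        if m.orientation == "inverse":
            df[m.name] = 1.0 - df[m.name]
    return NormalizedTable(df, list(table.metas), epoch=table.epoch, oriented=True)


def collinearity_screen(
    table: DriverTable,
    group_a: str = "economic",
    group_b: str = "urbanisation",
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Pairwise Pearson r between the indicators of two driver groups.

    Returns a tidy frame (indicator_a, indicator_b, r, flagged) where
    ``flagged`` marks |r| ≥ threshold — the conventional point at which
    collinearity starts to distort multi-indicator rankings.  Zero-variance
    columns yield an undefined (NaN) r, reported and flagged.
    """
    cols_a = table.group_columns(group_a)
    cols_b = table.group_columns(group_b)
    if not cols_a or not cols_b:
        raise ValueError(f"both groups must be present ({group_a!r}, {group_b!r})")
    if len(table.values) < 3:
        raise ValueError("need at least 3 units for a correlation screen")

    rows = []
    for ca in cols_a:
        for cb in cols_b:
            a = table.values[ca].to_numpy(dtype=float)
            b = table.values[cb].to_numpy(dtype=float)
            if np.std(a) == 0 or np.std(b) == 0:
                r = float("nan")
                flagged = True
            else:
                r = float(np.corrcoef(a, b)[0, 1])
                flagged = bool(abs(r) >= threshold)
            rows.append(
                {"indicator_a": ca, "indicator_b": cb, "r": r, "flagged": flagged}
            )
    return pd.DataFrame(rows)
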