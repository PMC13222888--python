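"""Land-cover change accounting.

Reclassification of fine land-cover classes into major categories, the
class-to-class area transition matrix between two epochs, flagging of
degradation/restoration transitions, period change areas with annual rates,
and Euclidean distance-to-class surfaces used as urbanisation indicators.

Degradation is operationalised as the conversion of grassland, forest or
water bodies into cropland, bare areas or impervious surfaces; restoration
as the conversion of cropland or bare areas into grassland, forest or water
bodies.  Everything else that changes class is "other change".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ClassScheme",
    "ReclassMap",
    "LandCoverGrid",
    "TransitionMatrix",
    "ChangeMap",
    "ChangeRates",
    "DEFAULT_SCHEME",
    "CROPLAND",
    "FOREST",
    "GRASSLAND",
    "WATER",
    "BARE",
    "IMPERVIOUS",
    "STABLE",
    "DEGRADATION",
    "RESTORATION",
    "OTHER_CHANGE",
    "NODATA_LABEL",
    "reclassify",
    "transition_matrix",
    "classify_change",
    "change_rates",
    "distance_to_class",
    "transition_summary",
]

# Default major-category codes (six classes, fixed order).
CROPLAND, FOREST, GRASSLAND, WATER, BARE, IMPERVIOUS = 1, 2, 3, 4, 5, 6

# Change-map label codes.
STABLE, DEGRADATION, RESTORATION, OTHER_CHANGE = 0, 1, 2, 3
NODATA_LABEL = 255

# Conversion rule sets for degradation / restoration flagging.
LD_SOURCES = frozenset({GRASSLAND, FOREST, WATER})
LD_TARGETS = frozenset({CROPLAND, BARE, IMPERVIOUS})
LR_SOURCES = frozenset({CROPLAND, BARE})
LR_TARGETS = frozenset({GRASSLAND, FOREST, WATER})


@dataclass(frozen=True)
class ClassScheme:
    """An ordered set of integer land-cover category codes with labels."""

    codes: tuple[int, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = tuple(int(c) for c in self.codes)
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "names", names)
        if len(codes) != len(names):
            raise ValueError("codes and names must have equal length")
        if len(codes) < 2:
            raise ValueError("a class scheme needs at least two categories")
        if len(set(codes)) != len(codes):
            raise ValueError("class codes must be unique")

    @property
    def n(self) -> int:
        return len(self.codes)

    def index(self, code: int) -> int:
        return self.codes.index(code)

    def name_of(self, code: int) -> str:
        return self.names[self.index(code)]


DEFAULT_SCHEME = ClassScheme(
    codes=(CROPLAND, FOREST, GRASSLAND, WATER, BARE, IMPERVIOUS),
    names=(
        "cropland",
        "forest",
        "grassland",
        "water bodies",
        "bare areas",
        "impervious surfaces",
    ),
)


@dataclass(frozen=True)
class ReclassMap:
    """Mapping from fine land-cover codes to major category codes.

    Every fine code appears exactly once; every target must be a code of the
    major scheme the map reclassifies into.
    """

    entries: dict[int, int]
    scheme: ClassScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        entries = {int(k): int(v) for k, v in self.entries.items()}
        object.__setattr__(self, "entries", entries)
        bad = sorted({v for v in entries.values()} - set(self.scheme.codes))
        if bad:
            raise ValueError(
                f"reclassification targets {bad} are not in the class scheme"
            )

    @classmethod
    def from_csv(cls, path, scheme: ClassScheme = DEFAULT_SCHEME) -> "ReclassMap":
        """Read a fine→major table from CSV (columns fine_code, major_code)."""
        df = pd.read_csv(path)
        for col in ("fine_code", "major_code"):
            if col not in df.columns:
                raise ValueError(f"reclass CSV missing column {col!r}")
        if df["fine_code"].duplicated().any():
            dup = sorted(df.loc[df["fine_code"].duplicated(), "fine_code"])
            raise ValueError(f"duplicate fine codes in reclass CSV: {dup}")
        return cls(dict(zip(df["fine_code"], df["major_code"])), scheme=scheme)


@dataclass
class LandCoverGrid:
    """One epoch of an integer category raster.

    Parameters
    ----------
    values : 2-D integer array of category codes.
    nodata : code marking missing cells (excluded from all areas).
    cell_area : area of one cell in km².
    epoch : acquisition year.
    scheme : the category scheme the codes belong to.
    """

    values: np.ndarray
    nodata: int = -9999
    cell_area: float = 1.0
    epoch: int = 0
    scheme: ClassScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        present = set(np.unique(self.values[self.values != self.nodata]).tolist())
        unknown = sorted(present - set(self.scheme.codes))
        if unknown:
            raise ValueError(f"grid holds codes outside the scheme: {unknown}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def class_areas(self) -> pd.Series:
        """Area per category (km²) over valid cells."""
        areas = {
            name: float(np.count_nonzero(self.values == code) * self.cell_area)
            for code, name in zip(self.scheme.codes, self.scheme.names)
        }
        return pd.Series(areas, name=f"area_km2_{self.epoch}")


def reclassify(grid: LandCoverGrid, reclass: ReclassMap) -> LandCoverGrid:
    """Map fine class codes to major categories, preserving nodata.

    Raises if the grid holds a code absent from the map; the error names the
    offending code(s) and how many cells carry them.
    """
    values = grid.values
    valid = values != grid.nodata
    present = np.unique(values[valid])
    missing = [int(c) for c in present if int(c) not in reclass.entries]
    if missing:
        counts = {c: int(np.count_nonzero(values == c)) for c in missing}
        detail = ", ".join(f"code {c} ({n} cells)" for c, n in counts.items())
        raise ValueError(f"unmapped fine land-cover codes: {detail}")

    out = np.full_like(values, grid.nodata)
    for fine, major in reclass.entries.items():
        out[values == fine] = major
    out[~valid] = grid.nodata
    return LandCoverGrid(
        out,
        nodata=grid.nodata,
        cell_area=grid.cell_area,
        epoch=grid.epoch,
        scheme=reclass.scheme,
    )


def _check_pair(a: LandCoverGrid, b: LandCoverGrid) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if a.scheme != b.scheme:
        raise ValueError("grids use different class schemes")
    if a.cell_area != b.cell_area:
        raise ValueError("grids have different cell areas")


@dataclass
class TransitionMatrix:
    """Class-to-class transition areas S_ij (km²) between two epochs.

    Entry (i, j) is the area that was class i in the first epoch and class j
    in the second; only cells valid in both epochs contribute.
    """

    areas: np.ndarray
    labels: ClassScheme
    period: tuple[int, int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.areas, index=list(self.labels.names), columns=list(self.labels.names)
        )

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def block_sum(self, sources, targets) -> float:
        """Total area over a source-set × target-set block, diagonal excluded
        when a class appears in both sets."""
        si = [self.labels.index(c) for c in sources]
        ti = [self.labels.index(c) for c in targets]
        total = float(self.areas[np.ix_(si, ti)].sum())
        for c in set(sources) & set(targets):
            k = self.labels.index(c)
            total -= float(self.areas[k, k])
        return total


def transition_matrix(a: LandCoverGrid, b: LandCoverGrid) -> TransitionMatrix:
    """Compute S_ij over cells valid in both epochs."""
    _check_pair(a, b)
    if a.epoch >= b.epoch:
        raise ValueError(f"epochs out of order: {a.epoch} !< {b.epoch}")
    scheme = a.scheme
    valid = a.valid_mask & b.valid_mask
    idx = {code: k for k, code in enumerate(scheme.codes)}
    ai = np.vectorize(idx.get, otypes=[np.int64])(a.values[valid])
    bi = np.vectorize(idx.get, otypes=[np.int64])(b.values[valid])
    n = scheme.n
    counts = np.bincount(ai * n + bi, minlength=n * n).reshape(n, n)
    return TransitionMatrix(
        areas=counts.astype(float) * a.cell_area,
        labels=scheme,
        period=(a.epoch, b.epoch),
    )


@dataclass
class ChangeMap:
    """Per-cell change labels: stable / degradation / restoration /
    other_change, with nodata wherever either epoch is missing."""

    labels: np.ndarray
    cell_area: float
    period: tuple[int, int]

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    @property
    def valid_count(self) -> int:
        return int(np.count_nonzero(self.labels != NODATA_LABEL))


def classify_change(a: LandCoverGrid, b: LandCoverGrid) -> ChangeMap:
    """Label each cell by its transition type between the two epochs."""
    _check_pair(a, b)
    valid = a.valid_mask & b.valid_mask
    src, dst = a.values, b.values

    labels = np.full(a.shape, OTHER_CHANGE, dtype=np.uint8)
    labels[src == dst] = STABLE
    ld = np.isin(src, list(LD_SOURCES)) & np.isin(dst, list(LD_TARGETS))
    lr = np.isin(src, list(LR_SOURCES)) & np.isin(dst, list(LR_TARGETS))
    labels[ld] = DEGRADATION
    labels[lr] = RESTORATION
    labels[~valid] = NODATA_LABEL
    return ChangeMap(labels=labels, cell_area=a.cell_area, period=(a.epoch, b.epoch))


@dataclass
class ChangeRates:
    """Degradation/restoration areas and annual change rates for one period.

    The annual rate is the changed fraction of the jointly valid area divided
    by the period length, expressed in % yr⁻¹.
    """

    ld_area: float
    lr_area: float
    ld_annual_rate: float
    lr_annual_rate: float
    period_years: int
    total_area: float

    def to_dict(self) -> dict:
        return {
            "ld_area_km2": self.ld_area,
            "lr_area_km2": self.lr_area,
            "ld_annual_rate_pct": self.ld_annual_rate,
            "lr_annual_rate_pct": self.lr_annual_rate,
            "period_years": self.period_years,
            "total_area_km2": self.total_area,
        }


def change_rates(cm: ChangeMap, period_years: int | None = None) -> ChangeRates:
    """Period LD/LR areas and annual rates from a change map.

    ``period_years`` defaults to the change map's epoch difference.
    """
    if period_years is None:
        period_years = cm.period[1] - cm.period[0]
    if period_years < 1:
        raise ValueError("period_years must be at least 1")
    n_valid = cm.valid_count
    if n_valid == 0:
        raise ValueError("change map holds no valid cells")
    total_area = n_valid * cm.cell_area
    ld_area = cm.count(DEGRADATION) * cm.cell_area
    lr_area = cm.count(RESTORATION) * cm.cell_area
    return ChangeRates(
        ld_area=ld_area,
        lr_area=lr_area,
        ld_annual_rate=100.0 * (ld_area / total_area) / period_years,
        lr_annual_rate=100.0 * (lr_area / total_area) / period_years,
        period_years=period_years,
        total_area=total_area,
    )


def distance_to_class(grid: LandCoverGrid, code: int) -> np.ndarray:
    """Euclidean distance (km) from every cell centre to the nearest cell
    centre holding ``code``.

    Cells are treated as squares of side sqrt(cell_area); distances are
    planar (no geodesic correction).
    """
    if code not in grid.scheme.codes:
        raise ValueError(f"code {code} is not in the class scheme")
    source = grid.values == code
    if not source.any():
        raise ValueError(
            f"code {code} ({grid.scheme.name_of(code)}) is absent from the grid"
        )
    side = float(np.sqrt(grid.cell_area))
    # exact Euclidean distance transform; background = source cells
    return ndimage.distance_transform_edt(~source, sampling=side)


def transition_summary(tm: TransitionMatrix) -> dict:
    """Headline changes for one period: the class with the largest net loss
    and the class with the largest net gain, each with its main transitions.

    Loss/gain are reported both as area (km²) and as percent of the total
    jointly valid area.
    """
    df = tm.to_dataframe()
    gains = df.sum(axis=0) - np.diag(df.values)  # inflow per target class
    losses = df.sum(axis=1) - np.diag(df.values)  # outflow per source class
    net = gains - losses
    total = tm.total_area

    dec = net.idxmin()
    inc = net.idxmax()
    dec_out = df.loc[dec].drop(dec).sort_values(ascending=False)
    inc_in = df[inc].drop(inc).sort_values(ascending=False)

    return {
        "period": list(tm.period),
        "most_decreased": {
            "class": dec,
            "net_change_km2": float(net[dec]),
            "net_change_pct": float(100.0 * net[dec] / total) if total else 0.0,
            "main_transitions_km2": {
                k: float(v) for k, v in dec_out.head(2).items() if v > 0
            },
        },
        "most_increased": {
            "class": inc,
            "net_change_km2": float(net[inc]),
            "net_change_pct": float(100.0 * net[inc] / total) if total else 0.0,
            "main_sources_km2": {
                k: float(v) for k, v in inc_in.head(2).items() if v > 0
            },
        },
    }
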