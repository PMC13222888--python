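"""Synthetic study-region generator with planted ground truth.

Desk-scale stand-ins for the real inputs of a county-level degradation
analysis: a zone (county) map of contiguous blocks, a raw driver table in
which each unit has one *planted* dominant driver group (its indicators are
offset by an effect size δ, everything jittered with Gaussian noise σ), and
a land-cover grid pair in which each cell flips class with planted per-pair
transition probabilities.  Every generator is deterministic under the
configured seed; one global seed feeds independent per-generator
substreams, so adding a generator never perturbs existing outputs.

The default configuration mirrors the twelve-indicator setup (2 natural,
2 human, 4 economic, 4 urbanisation; precipitation and the four distance
indicators inverse-oriented) so that synthetic runs exercise the same table
shape and orientation step as a real study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .drivers import GROUPS, DriverTable, IndicatorMeta, default_metas
from .gridio import write_ascii_grid, write_landcover
from .landcover import (
    CROPLAND,
    DEFAULT_SCHEME,
    GRASSLAND,
    LD_SOURCES,
    LD_TARGETS,
    LR_SOURCES,
    LR_TARGETS,
    LandCoverGrid,
)

__all__ = ["ScenarioConfig", "SyntheticBundle", "gen_zone_map", "gen_drivers",
           "gen_landcover_pair", "make_bundle", "write_bundle"]

# Plausible raw scales per default indicator: raw = intercept + slope * v,
# with v the latent influence level.  Inverse indicators get negative slopes
# so they are emitted on their natural (uninverted) scale and the pipeline's
# orientation step is genuinely exercised.  Normalization is affine-invariant,
# so these scales are cosmetic.
_RAW_SCALES = {
    "annual_mean_temperature": (2.0, 6.0),
    "annual_total_precipitation": (550.0, -300.0),
    "population_density": (10.0, 90.0),
    "sheep_density": (20.0, 150.0),
    "primary_gdp_density": (30.0, 250.0),
    "secondary_gdp_density": (40.0, 500.0),
    "tertiary_gdp_density": (35.0, 400.0),
    "total_gdp_density": (110.0, 1100.0),
    "distance_to_urban_land": (45.0, -35.0),
    "distance_to_rural_settlements": (12.0, -9.0),
    "distance_to_roads": (18.0, -14.0),
    "distance_to_other_builtup": (30.0, -22.0),
}

_DEFAULT_MIXTURE = {
    CROPLAND: 0.25,
    2: 0.15,  # forest
    GRASSLAND: 0.40,
    4: 0.05,  # water bodies
    5: 0.10,  # bare areas
    6: 0.05,  # impervious surfaces
}

# Default change regime: grassland reclamation dominates, with some
# restoration of cropland/bare land back to grassland.
_DEFAULT_TRANSITIONS = {
    (GRASSLAND, CROPLAND): 0.2,
    (2, CROPLAND): 0.05,
    (CROPLAND, GRASSLAND): 0.1,
    (5, GRASSLAND): 0.1,
}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    ``effect_size`` (δ) is the offset added to every indicator of a unit's
    planted dominant group on the latent influence scale (the whole scale
    spans [0, 1] after normalization); ``noise_sigma`` (σ) is the standard
    deviation of iid Gaussian jitter on the same scale.  δ = 0.5, σ = 0.05
    gives a clearly separated but noisy scenario; σ = 0 is noise-free.
    """

    n_units: int = 20
    grid_shape: tuple[int, int] = (50, 50)
    effect_size: float = 0.5
    noise_sigma: float = 0.05
    base_level: float = 0.5
    planted_dominant: dict[int, str] | None = None
    epochs: tuple[int, int] = (1990, 2000)
    period_years: int = 10
    cell_area: float = 1.0
    class_mixture: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    transition_probs: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(_DEFAULT_TRANSITIONS)
    )
    n_regions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        if self.effect_size < 0 or self.noise_sigma < 0:
            raise ValueError("effect_size and noise_sigma must be non-negative")
        if self.period_years < 1:
            raise ValueError("period_years must be at least 1")
        total = sum(self.class_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class mixture must sum to 1, got {total}")
        self._validate_transitions()
        if self.planted_dominant is None:
            self.planted_dominant = {
                u: GROUPS[(u - 1) % len(GROUPS)] for u in range(1, self.n_units + 1)
            }
        bad = sorted(set(self.planted_dominant.values()) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown planted groups: {bad}")

    def _validate_transitions(self) -> None:
        rows: dict[int, float] = {}
        for (i, j), p in self.transition_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transition probability for {(i, j)} not in [0,1]: {p}")
            if i != j:
                rows[i] = rows.get(i, 0.0) + p
        for i, s in rows.items():
            if s > 1.0 + 1e-12:
                raise ValueError(
                    f"outgoing transition probabilities from class {i} sum to {s} > 1"
                )

    @property
    def unit_ids(self) -> list[int]:
        return list(range(1, self.n_units + 1))

    def region_map(self) -> dict[int, str]:
        """Units grouped into ``n_regions`` contiguous blocks of ids."""
        k = max(1, self.n_regions)
        return {
            u: f"R{(u - 1) * k // self.n_units + 1}" for u in self.unit_ids
        }

    # --- YAML round-trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            "n_units": self.n_units,
            "grid_shape": list(self.grid_shape),
            "effect_size": self.effect_size,
            "noise_sigma": self.noise_sigma,
            "base_level": self.base_level,
            "planted_dominant": {int(k): v for k, v in self.planted_dominant.items()},
            "epochs": list(self.epochs),
            "period_years": self.period_years,
            "cell_area": self.cell_area,
            "class_mixture": {int(k): float(v) for k, v in self.class_mixture.items()},
            "transition_probs": {
                f"{i}->{j}": float(p) for (i, j), p in self.transition_probs.items()
            },
            "n_regions": self.n_regions,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        if "epochs" in data:
            data["epochs"] = tuple(data["epochs"])
        if "planted_dominant" in data and data["planted_dominant"] is not None:
            data["planted_dominant"] = {
                int(k): str(v) for k, v in data["planted_dominant"].items()
            }
        if "class_mixture" in data:
            data["class_mixture"] = {
                int(k): float(v) for k, v in data["class_mixture"].items()
            }
        if "transition_probs" in data:
            parsed = {}
            for key, p in data["transition_probs"].items():
                i, j = key.split("->")
                parsed[(int(i), int(j))] = float(p)
            data["transition_probs"] = parsed
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValueError(f"invalid scenario config: {exc}") from exc


def _substreams(cfg: ScenarioConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(cfg.seed)
    names = ("zone", "drivers", "landcover")
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


def gen_zone_map(cfg: ScenarioConfig) -> np.ndarray:
    """Partition the grid into ``n_units`` contiguous rectangular zones.

    Zones are laid out as a grid of blocks (rows split into strips, strips
    split into blocks); every unit id 1..n_units appears as exactly one
    rectangular block.
    """
    rows, cols = cfg.grid_shape
    n = cfg.n_units
    if n > rows * cols:
        raise ValueError(f"cannot fit {n} units on a {rows}x{cols} grid")
    br = int(np.floor(np.sqrt(n)))
    while n % br:
        br -= 1
    bc = n // br
    if br > rows or bc > cols:
        # fall back to a single strip along the longer axis
        if n <= cols:
            br, bc = 1, n
        elif n <= rows:
            br, bc = n, 1
        else:
            raise ValueError(
                f"cannot partition a {rows}x{cols} grid into {n} rectangular blocks"
            )
    row_edges = np.linspace(0, rows, br + 1).astype(int)
    col_edges = np.linspace(0, cols, bc + 1).astype(int)
    zones = np.zeros((rows, cols), dtype=np.int64)
    uid = 1
    for r in range(br):
        for c in range(bc):
            zones[row_edges[r] : row_edges[r + 1], col_edges[c] : col_edges[c + 1]] = uid
            uid += 1
    return zones


def gen_drivers(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> DriverTable:
    """Raw driver table with one planted dominant group per unit.

    On the latent influence scale, indicators of unit u's planted group sit
    at base + δ (+ noise); all others at base (+ noise).  Values are then
    mapped to plausible raw units per indicator — with decreasing maps for
    inverse-oriented indicators — so normalization *and* orientation are
    both exercised downstream.
    """
    if rng is None:
        rng = _substreams(cfg)["drivers"]
    metas = default_metas()
    units = cfg.unit_ids
    latent = np.empty((len(units), len(metas)))
    for ui, u in enumerate(units):
        g_star = cfg.planted_dominant[u]
        for mi, m in enumerate(metas):
            v = cfg.base_level + (cfg.effect_size if m.group == g_star else 0.0)
            latent[ui, mi] = v + rng.normal(0.0, cfg.noise_sigma)

    raw = np.empty_like(latent)
    for mi, m in enumerate(metas):
        b, a = _RAW_SCALES.get(m.name, (0.0, 1.0 if m.orientation == "direct" else -1.0))
        raw[:, mi] = b + a * latent[:, mi]

    df = pd.DataFrame(raw, index=units, columns=[m.name for m in metas])
    df.index.name = "unit"
    epoch = f"{cfg.epochs[0]}-{cfg.epochs[1]}"
    return DriverTable(df, metas, epoch=epoch)


def gen_landcover_pair(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[LandCoverGrid, LandCoverGrid]:
    """A two-epoch land-cover pair under planted transition probabilities.

    The first epoch draws every cell iid from the class mixture; the second
    flips each cell of class i to class j with probability
    transition_probs[(i, j)], independently per cell, staying put with the
    remaining probability.
    """
    if rng is None:
        rng = _substreams(cfg)["landcover"]
    rows, cols = cfg.grid_shape
    codes = np.array(sorted(cfg.class_mixture))
    probs = np.array([cfg.class_mixture[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    v1 = rng.choice(codes, size=(rows, cols), p=probs)

    v2 = v1.copy()
    for i in np.unique(v1):
        mask = v1 == i
        out_pairs = [(j, p) for (src, j), p in cfg.transition_probs.items()
                     if src == i and j != i and p > 0]
        if not out_pairs:
            continue
        targets = [j for j, _ in out_pairs] + [int(i)]
        p_out = [p for _, p in out_pairs]
        p_full = p_out + [1.0 - sum(p_out)]
        v2[mask] = rng.choice(targets, size=int(mask.sum()), p=p_full)

    g1 = LandCoverGrid(v1, cell_area=cfg.cell_area, epoch=cfg.epochs[0])
    g2 = LandCoverGrid(v2, cell_area=cfg.cell_area, epoch=cfg.epochs[1])
    return g1, g2


def expected_change_areas(cfg: ScenarioConfig) -> dict:
    """Expected LD/LR areas (km²) implied by the mixture and the planted
    transition probabilities."""
    rows, cols = cfg.grid_shape
    total = rows * cols * cfg.cell_area
    ld = sum(
        cfg.class_mixture.get(i, 0.0) * p
        for (i, j), p in cfg.transition_probs.items()
        if i in LD_SOURCES and j in LD_TARGETS
    )
    lr = sum(
        cfg.class_mixture.get(i, 0.0) * p
        for (i, j), p in cfg.transition_probs.items()
        if i in LR_SOURCES and j in LR_TARGETS
    )
    return {
        "expected_ld_area_km2": total * ld,
        "expected_lr_area_km2": total * lr,
        "expected_ld_annual_rate_pct": 100.0 * ld / cfg.period_years,
        "expected_lr_annual_rate_pct": 100.0 * lr / cfg.period_years,
        "total_area_km2": total,
    }


@dataclass
class SyntheticBundle:
    """Everything one scenario produces, plus its ground truth."""

    config: ScenarioConfig
    zone_map: np.ndarray
    driver_table: DriverTable
    landcover: tuple[LandCoverGrid, LandCoverGrid]
    truth: dict


def make_bundle(cfg: ScenarioConfig) -> SyntheticBundle:
    rngs = _substreams(cfg)
    zones = gen_zone_map(cfg)
    table = gen_drivers(cfg, rngs["drivers"])
    pair = gen_landcover_pair(cfg, rngs["landcover"])
    truth = {
        "seed": cfg.seed,
        "planted_dominant": {int(u): g for u, g in cfg.planted_dominant.items()},
        "region_map": {int(u): r for u, r in cfg.region_map().items()},
        **expected_change_areas(cfg),
    }
    return SyntheticBundle(cfg, zones, table, pair, truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write a bundle in the formats the pipeline reads; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    paths = {
        "zones": outdir / "zones.asc",
        "landcover_a": outdir / f"landcover_{cfg.epochs[0]}.asc",
        "landcover_b": outdir / f"landcover_{cfg.epochs[1]}.asc",
        "drivers": outdir / "drivers.csv",
        "drivers_meta": outdir / "drivers_meta.json",
        "truth": outdir / "truth.json",
        "scenario": outdir / "scenario.yaml",
    }
    write_ascii_grid(paths["zones"], bundle.zone_map, nodata=0,
                     cellsize=float(np.sqrt(cfg.cell_area)))
    write_landcover(paths["landcover_a"], bundle.landcover[0])
    write_landcover(paths["landcover_b"], bundle.landcover[1])
    bundle.driver_table.to_csv(paths["drivers"], paths["drivers_meta"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
    cfg.to_yaml(paths["scenario"])
    return paths
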