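"""Dominant-driver attribution from per-group Hasse diagrams.

A unit's position in the Hasse diagram of one driver group measures how
strongly that group influences degradation there: units at higher levels are
dominated by fewer units.  Scoring each unit's height in every group's
diagram on a common [0, 1] scale and taking the argmax (with an optional tie
tolerance) yields the dominant driver group(s) per unit; counting dominated
units per region gives the regional ranking of driver groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .drivers import GROUPS, NormalizedTable
from .poset import HasseDiagram, build_poset, hasse, lpom_average_rank

__all__ = [
    "GroupScore",
    "DominanceResult",
    "group_diagrams",
    "group_height_scores",
    "dominant_groups",
    "region_summary",
    "rank_groups",
]

SCORE_METHODS = ("level_height", "lpom_norm")


@dataclass(frozen=True)
class GroupScore:
    """Units × driver-groups matrix of height scores in [0, 1]."""

    scores: pd.DataFrame  # index = unit ids, columns = group names
    method: str

    def __post_init__(self) -> None:
        if self.method not in SCORE_METHODS:
            raise ValueError(f"method must be one of {SCORE_METHODS}")
        vals = self.scores.to_numpy(dtype=float)
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("scores must lie in [0, 1]")


@dataclass(frozen=True)
class DominanceResult:
    """Per-unit dominant driver group set (co-dominance allowed)."""

    dominant: dict  # unit id -> frozenset of group names
    scores: GroupScore
    tie_tol: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"unit": u, "dominant": ";".join(sorted(g))}
            for u, g in self.dominant.items()
        ]
        return pd.DataFrame(rows).set_index("unit")


def group_diagrams(
    table: NormalizedTable, groups=None, tol: float = 0.0
) -> dict[str, HasseDiagram]:
    """One Hasse diagram per driver group, each built on that group's
    indicator columns only."""
    if groups is None:
        groups = [g for g in GROUPS if table.group_columns(g)]
    out = {}
    for g in groups:
        cols = table.group_columns(g)
        if not cols:
            raise ValueError(f"no indicators for group {g!r}")
        out[g] = hasse(build_poset(table, cols, tol=tol))
    return out


def _unit_rep(h: HasseDiagram, unit_id):
    for rep, mem in h.members.items():
        if unit_id in mem:
            return rep
    raise KeyError(unit_id)


def group_height_scores(
    diagrams: dict[str, HasseDiagram],
    method: str = "level_height",
    posets: dict | None = None,
) -> GroupScore:
    """Score every unit's height in every group diagram on [0, 1].

    ``level_height``: (level − 1)/(L − 1); a one-level (structureless)
    diagram scores 0.5 for everyone, so it neither wins nor loses.
    ``lpom_norm``: (Rav − 1)/(N − 1) from the LPOM0 rank table; requires the
    matching posets and degenerates to 0.5 when N = 1.
    """
    if method not in SCORE_METHODS:
        raise ValueError(f"method must be one of {SCORE_METHODS}")
    units = sorted(
        {u for h in diagrams.values() for mem in h.members.values() for u in mem},
        key=str,
    )
    for g, h in diagrams.items():
        covered = {u for mem in h.members.values() for u in mem}
        missing = [u for u in units if u not in covered]
        if missing:
            raise ValueError(f"units {missing} missing from diagram of group {g!r}")

    cols = {}
    for g, h in diagrams.items():
        if method == "level_height":
            if h.n_levels == 1:
                cols[g] = {u: 0.5 for u in units}
            else:
                cols[g] = {
                    u: (h.unit_level(u) - 1) / (h.n_levels - 1) for u in units
                }
        else:
            if posets is None or g not in posets:
                raise ValueError("lpom_norm scoring needs the per-group posets")
            p = posets[g]
            if p.n == 1:
                cols[g] = {u: 0.5 for u in units}
            else:
                rav = lpom_average_rank(p, h)["Rav"]
                cols[g] = {
                    u: (float(rav[_unit_rep(h, u)]) - 1) / (p.n - 1) for u in units
                }
    df = pd.DataFrame(cols, index=units)[list(diagrams.keys())]
    return GroupScore(scores=df, method=method)


def dominant_groups(gs: GroupScore, tie_tol: float = 0.0) -> DominanceResult:
    """Dominant group set per unit: every group whose score reaches the
    unit's maximum minus ``tie_tol`` (argmax set when tie_tol = 0)."""
    if tie_tol < 0:
        raise ValueError("tie_tol must be non-negative")
    dominant = {}
    for unit, row in gs.scores.iterrows():
        top = row.max()
        dominant[unit] = frozenset(row.index[row >= top - tie_tol])
    return DominanceResult(dominant=dominant, scores=gs, tie_tol=tie_tol)


def region_summary(dr: DominanceResult, region_map: dict) -> pd.DataFrame:
    """Count, per region and driver group, the units whose dominant set
    contains the group.  A unit with k co-dominant groups contributes one
    count to each of the k columns."""
    groups = list(dr.scores.scores.columns)
    unmapped = [u for u in dr.dominant if u not in region_map]
    if unmapped:
        raise ValueError(f"units without a region: {unmapped}")
    regions = sorted(set(region_map.values()), key=str)
    counts = pd.DataFrame(0, index=regions, columns=groups)
    for unit, doms in dr.dominant.items():
        for g in doms:
            counts.loc[region_map[unit], g] += 1
    counts.index.name = "region"
    return counts


def rank_groups(
    table: NormalizedTable,
    method: str = "level_height",
    tie_tol: float = 0.0,
    tol: float = 0.0,
):
    """End-to-end group ranking from an oriented table.

    Builds one poset + Hasse diagram per driver group, scores unit heights,
    and selects dominant groups.  Returns (diagrams, scores, dominance).
    """
    groups = [g for g in GROUPS if table.group_columns(g)]
    posets = {g: build_poset(table, table.group_columns(g), tol=tol) for g in groups}
    diagrams = {g: hasse(p) for g, p in posets.items()}
    scores = group_height_scores(diagrams, method=method, posets=posets)
    return diagrams, scores, dominant_groups(scores, tie_tol=tie_tol)
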