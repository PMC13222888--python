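"""Small built-in example inputs.

The six-county example reproduces a known Hasse-diagram structure for the
natural driver group: a three-level order AES < {TQ, KYQ, WL} < KYZ with
exactly three maximal chains (KYQ→KYZ, AES→TQ→KYZ, WL→KYZ) and ZLT isolated
because of its extreme temperature/precipitation combination.  The indicator
values are synthetic — constructed to induce exactly that cover structure —
since only the structure itself, not the underlying table, is published.
"""

from __future__ import annotations

import pandas as pd

from .drivers import IndicatorMeta, NormalizedTable

__all__ = ["six_county_example", "SIX_COUNTY_STRUCTURE"]

# The target structure the synthetic table realises.
SIX_COUNTY_STRUCTURE = {
    "covers": {("AES", "TQ"), ("TQ", "KYZ"), ("KYQ", "KYZ"), ("WL", "KYZ")},
    "levels": {"AES": 1, "TQ": 2, "KYQ": 2, "WL": 2, "KYZ": 3, "ZLT": 3},
    "n_levels": 3,
    "chains": {("AES", "TQ", "KYZ"), ("KYQ", "KYZ"), ("WL", "KYZ")},
    "isolated": {"ZLT"},
}

# Synthetic oriented values (temperature, precipitation-after-orientation).
# ZLT pairs an extreme high on one indicator with an extreme low on the
# other, which makes it incomparable with every other county.
_VALUES = {
    "KYZ": (0.9, 0.9),
    "TQ": (0.6, 0.6),
    "KYQ": (0.8, 0.2),
    "WL": (0.2, 0.8),
    "AES": (0.5, 0.3),
    "ZLT": (1.0, 0.0),
}


def six_county_example() -> NormalizedTable:
    """Oriented natural-group table for the six-county worked example."""
    metas = [
        IndicatorMeta("annual_mean_temperature", "natural", "degC"),
        # already flipped (1 - normalized precipitation), hence direct here
        IndicatorMeta("oriented_precipitation", "natural", "1"),
    ]
    df = pd.DataFrame.from_dict(_VALUES, orient="index",
                                columns=[m.name for m in metas])
    df.index.name = "unit"
    return NormalizedTable(df, metas, epoch="1990-2000", oriented=True)
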