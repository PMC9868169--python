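"""Land-use naturalness scoring (LNI layer).

Naturalness measures how far a land-use class departs from untouched natural
cover.  The scoring follows the HAILS scheme (Human Activity Intensity of
Land Surface): each of the nine land-use classes carries a classification
sign describing the state of the natural cover and a disturbance score on
the 0–10 scale, with 0 for untouched cover (natural water, unused land) and
10 for fully sealed settlement/industrial surfaces.

The per-class scores are the operative LNI values; the coarser two-tier
HAILS category table (second-level CS1–CS3, first-level FCS1–FCS5, on a 0–2
scale) is retained as metadata describing the classification signs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ScoringError
from .grid import LAND_USE_CLASSES, LandUseGrid, ValueGrid

__all__ = [
    "NaturalnessTable",
    "default_naturalness_table",
    "hails_classification",
    "hails_score",
    "assign_naturalness",
]

_SIGNS = {
    "arable": "Natural cover of land surface changes and annual crops are planted",
    "forest": "Natural cover of land surface does not change but is used",
    "grassland": "Natural cover of land surface does not change but is used",
    "artificial_water": (
        "There are artificial insulation layers on the surface. Water could be "
        "exchanged. The exchanges of nutrients, air, and heat are impeded"
    ),
    "natural_water": "Natural cover of the land surface does not change and is not used",
    "urban": (
        "There are artificial insulation layers on the surface. The exchanges of "
        "nutrients, air, water, and heat are impeded"
    ),
    "rural": (
        "There are artificial insulation layers on the surface. The exchanges of "
        "nutrients, air, water, and heat are impeded"
    ),
    "industrial": (
        "There are artificial insulation layers on the surface. The exchanges of "
        "nutrients, air, water, and heat are impeded"
    ),
    "unused": "Natural cover of the land surface does not change and is not used",
}

_DEFAULT_SCORES = {
    "arable": 2.0,
    "forest": 0.67,
    "grassland": 1.33,
    "artificial_water": 6.0,
    "natural_water": 0.0,
    "urban": 10.0,
    "rural": 10.0,
    "industrial": 10.0,
    "unused": 0.0,
}

#: HAILS two-tier classification metadata: category → (level, sign, score on 0–2 scale).
_HAILS_CATEGORIES = {
    "natural": ("zero", "Natural cover of the land surface does not change and is not used", 0.0),
    "CS1": ("second", "Natural cover of land surface does not change but is used", 0.67),
    "CS2": ("second", "Natural cover of land surface changes and perennial crops are planted", 1.33),
    "CS3": ("second", "Natural cover of land surface changes and annual crops are planted", 2.0),
    "FCS1": ("first", "Natural cover of land surface changes", 2.0),
    "FCS2": (
        "first",
        "There are artificial insulation layers on the land surface. Water could be exchanged. "
        "The exchanges of nutrients, air, and heat are impeded",
        2.0,
    ),
    "FCS3": (
        "first",
        "There are artificial insulation layers on the land surface. Nutrients could be exchanged. "
        "The exchanges of water, air, and heat are impeded",
        2.0,
    ),
    "FCS4": (
        "first",
        "There are artificial insulation layers on the land surface. Air could be exchanged. "
        "The exchanges of water, nutrients, and heat are impeded",
        2.0,
    ),
    "FCS5": (
        "first",
        "There are artificial insulation layers on the land surface. Heat could be exchanged. "
        "The exchanges of water, air, and nutrients are impeded",
        2.0,
    ),
    "sealed": (
        "first",
        "There are artificial insulation layers on the land surface. The exchanges of water, "
        "nutrients, air, and heat are impeded",
        2.0,
    ),
}


def hails_classification() -> pd.DataFrame:
    """The HAILS category table as a DataFrame (category, level, sign, score)."""
    return pd.DataFrame(
        [(cat, lvl, sign, score) for cat, (lvl, sign, score) in _HAILS_CATEGORIES.items()],
        columns=["category", "level", "classification_sign", "score"],
    )


def hails_score(category: str) -> float:
    """Score of a HAILS category (e.g. ``hails_score("CS1") == 0.67``)."""
    if category not in _HAILS_CATEGORIES:
        raise KeyError(f"unknown HAILS category {category!r}")
    return _HAILS_CATEGORIES[category][2]


@dataclass
class NaturalnessTable:
    """Per-class naturalness scores with their classification signs.

    ``entries`` maps each land-use class to ``(classification_sign, score)``
    with scores in [0, 10].
    """

    entries: Mapping[str, tuple[str, float]]

    def __post_init__(self) -> None:
        self.entries = dict(self.entries)
        for cls, (_, score) in self.entries.items():
            if not 0.0 <= score <= 10.0:
                raise ValueError(f"naturalness score for {cls!r} outside [0, 10]: {score}")

    def score(self, cls: str) -> float:
        if cls not in self.entries:
            raise ScoringError(f"land-use class {cls!r} missing from naturalness table")
        return self.entries[cls][1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(c, s, v) for c, (s, v) in self.entries.items()],
            columns=["class", "classification_sign", "score"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NaturalnessTable":
        df = pd.read_csv(path)
        return cls({r["class"]: (r.get("classification_sign", ""), float(r["score"])) for _, r in df.iterrows()})


def default_naturalness_table() -> NaturalnessTable:
    """The default per-class LNI scores for the nine land-use classes."""
    return NaturalnessTable({c: (_SIGNS[c], _DEFAULT_SCORES[c]) for c in LAND_USE_CLASSES})


def assign_naturalness(land_use: LandUseGrid, table: NaturalnessTable | None = None) -> ValueGrid:
    """Map each cell's land-use class to its naturalness score.

    Pure table lookup — no interpolation.  Nodata cells stay nodata.  A class
    present in the grid but absent from the table raises
    :class:`~hdikit.errors.ScoringError` naming the class.
    """
    if table is None:
        table = default_naturalness_table()
    out = np.full(land_use.spec.shape, np.nan)
    for code, cls in land_use.legend.items():
        sel = land_use.codes == code
        if cls == "nodata" or not sel.any():
            continue
        out[sel] = table.score(cls)
    return ValueGrid(land_use.spec, out, units="score")
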