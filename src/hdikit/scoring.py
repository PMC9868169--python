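"""Standardization, HDI combination, level classification and tabulation.

Raw consumption/emission surfaces are standardized to integer disturbance
scores with natural-breaks (Fisher–Jenks) classification: breaks are
computed once on values pooled across all periods of a dataset, so a given
raw value maps to the same score in every period and scores are temporally
comparable.  Exact-zero cells (no activity at all) score 0; nonzero cells
receive scores 1..k by Jenks class membership, giving the 0–10 scale for
k = 10.

The composite index sums the naturalness layer (0–10), the two resource
scores (0–20) and the three emission scores (0–30) into HDI on [0, 60],
which is cut into ten equal-interval disturbance levels I..X of width 6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError, RangeError
from .grid import GridSpec, LandUseGrid, ValueGrid

__all__ = [
    "BreaksSpec",
    "HDIGrid",
    "LevelGrid",
    "ROMAN_LEVELS",
    "jenks_breaks",
    "standardize_scores",
    "sum_layers",
    "combine_hdi",
    "classify_levels",
    "tabulate_levels",
    "goodness_of_variance_fit",
]

ROMAN_LEVELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass
class BreaksSpec:
    """Class boundaries of a 1-D classification.

    ``boundaries`` are k+1 strictly increasing reals; class ``m`` (1-based)
    covers ``(boundaries[m-1], boundaries[m]]`` with the first class closed
    on the left.  Ties at a boundary go to the lower class.
    """

    boundaries: list[float]
    score_labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) < 2 or not (np.diff(b) > 0).all():
            raise ValueError("boundaries must be strictly increasing with at least two entries")
        self.boundaries = [float(x) for x in b]
        if not self.score_labels:
            self.score_labels = list(range(1, len(self.boundaries)))
        if len(self.score_labels) != len(self.boundaries) - 1:
            raise ValueError("need one score label per class")

    @property
    def k(self) -> int:
        return len(self.boundaries) - 1

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Class labels for values; values outside the fitted range clamp to
        the first/last class."""
        inner = np.asarray(self.boundaries[1:-1])
        idx = np.searchsorted(inner, values, side="left")
        return np.asarray(self.score_labels)[idx]

    def to_dict(self) -> dict:
        return {"boundaries": self.boundaries, "score_labels": self.score_labels}

    @classmethod
    def from_dict(cls, d: Mapping) -> "BreaksSpec":
        return cls(list(d["boundaries"]), list(d["score_labels"]))


# ---------------------------------------------------------------------------
# Fisher–Jenks natural breaks
# ---------------------------------------------------------------------------

def _weighted_jenks_dp(values: np.ndarray, weights: np.ndarray, k: int) -> list[int]:
    """Optimal 1-D partition minimizing within-class weighted SSD.

    ``values`` must be sorted ascending.  Returns the k−1 split indices
    (half-open: class m is values[s_{m-1}:s_m]).  Dynamic program over
    prefix sums, O(k·n²) with a vectorized inner minimization.
    """
    n = len(values)
    cw = np.concatenate([[0.0], np.cumsum(weights)])
    cwv = np.concatenate([[0.0], np.cumsum(weights * values)])
    cwv2 = np.concatenate([[0.0], np.cumsum(weights * values * values)])

    def ssd_row(i: np.ndarray, j: int) -> np.ndarray:
        # within-class weighted SSD of values[i:j] for a vector of i
        w = cw[j] - cw[i]
        s = cwv[j] - cwv[i]
        q = cwv2[j] - cwv2[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = q - np.where(w > 0, s * s / np.maximum(w, 1e-300), 0.0)
        return np.maximum(out, 0.0)

    # dp[j] = best cost of partitioning values[:j] into m classes
    dp = np.array([ssd_row(np.array([0]), j)[0] for j in range(n + 1)])
    back = np.zeros((k, n + 1), dtype=int)
    for m in range(2, k + 1):
        new = np.full(n + 1, np.inf)
        for j in range(m, n + 1):
            i = np.arange(m - 1, j)
            costs = dp[i] + ssd_row(i, j)
            best = int(np.argmin(costs))
            new[j] = costs[best]
            back[m - 1, j] = i[best]
        dp = new
    splits = []
    j = n
    for m in range(k, 1, -1):
        j = int(back[m - 1, j])
        splits.append(j)
    return splits[::-1]


def jenks_breaks(values, k: int, max_exact: int = 2048) -> BreaksSpec:
    """Fisher–Jenks natural breaks of a value multiset into k classes.

    Deterministic and optimal (minimum total within-class sum of squared
    deviations).  Inputs larger than ``max_exact`` distinct values are
    first binned to ``max_exact`` quantile bins with multiplicity weights
    before the dynamic program; pass a large ``max_exact`` for exactness on
    small data.  Fewer than k distinct values raise
    :class:`~hdikit.errors.DegenerateInputError`.
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    vals = vals[np.isfinite(vals)]
    if k < 1:
        raise ValueError("k must be >= 1")
    uniq, counts = np.unique(vals, return_counts=True)
    if len(uniq) < k:
        raise DegenerateInputError(f"{len(uniq)} distinct values < k = {k}")
    if len(uniq) > max_exact:
        # quantile binning: weighted representatives preserve the DP structure
        qs = np.quantile(vals, np.linspace(0, 1, max_exact + 1))
        idx = np.clip(np.searchsorted(qs[1:-1], vals, side="left"), 0, max_exact - 1)
        reps, counts = [], []
        for b in np.unique(idx):
            sel = idx == b
            reps.append(vals[sel].mean())
            counts.append(sel.sum())
        uniq = np.asarray(reps)
        counts = np.asarray(counts, dtype=float)
    if k == 1:
        return BreaksSpec([float(uniq[0]), float(uniq[-1])] if uniq[0] < uniq[-1] else [float(uniq[0]) - 0.5, float(uniq[0]) + 0.5])
    splits = _weighted_jenks_dp(uniq.astype(float), counts.astype(float), k)
    # class boundary sits midway between the last value of the lower class and
    # the first of the upper one; no data value can fall strictly between two
    # adjacent distinct values, so boundaries are strictly increasing and a
    # value equal to a boundary lands in the lower class (searchsorted left)
    bounds = (
        [float(uniq[0])]
        + [float(uniq[s - 1] + uniq[s]) / 2.0 for s in splits]
        + [float(uniq[-1])]
    )
    return BreaksSpec(bounds)


def goodness_of_variance_fit(values, breaks: BreaksSpec) -> float:
    """GVF = 1 − SDCM/SDAM for a classification of ``values``."""
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    sdam = float(((vals - vals.mean()) ** 2).sum())
    labels = breaks.assign(vals)
    sdcm = 0.0
    for lab in np.unique(labels):
        sel = vals[labels == lab]
        sdcm += float(((sel - sel.mean()) ** 2).sum())
    return 1.0 - sdcm / sdam if sdam > 0 else 1.0


# ---------------------------------------------------------------------------
# Standardization and combination
# ---------------------------------------------------------------------------

def standardize_scores(
    surfaces: Sequence[ValueGrid],
    k: int = 10,
    max_exact: int = 2048,
) -> tuple[list[ValueGrid], BreaksSpec | None]:
    """Standardize one dataset's per-period surfaces to integer 0..k scores.

    Breaks are computed once on nonzero values pooled across *all* periods,
    so the same raw value scores identically in every period.  Exact zeros
    score 0 (no activity); nonzero cells get 1..k by Jenks class.  If the
    pooled nonzero values have fewer than k distinct values, equal-interval
    breaks over the pooled range are used instead (with a warning); an
    all-zero dataset returns all-zero scores and ``None`` breaks.
    """
    if not surfaces:
        raise ValueError("no surfaces to standardize")
    spec = surfaces[0].spec
    if any(s.spec != spec for s in surfaces):
        raise AlignmentError("surfaces to standardize are not aligned")
    pooled = np.concatenate([s.values[np.isfinite(s.values)] for s in surfaces])
    nonzero = pooled[pooled != 0.0]
    breaks: BreaksSpec | None
    if nonzero.size == 0:
        breaks = None
    else:
        try:
            breaks = jenks_breaks(nonzero, k, max_exact=max_exact)
        except DegenerateInputError:
            lo, hi = float(nonzero.min()), float(nonzero.max())
            if hi == lo:
                lo, hi = lo - 0.5, hi + 0.5
            warnings.warn(
                "pooled distribution degenerate for natural breaks; "
                "falling back to equal-interval standardization",
                stacklevel=2,
            )
            breaks = BreaksSpec(list(np.linspace(lo, hi, k + 1)))
    out = []
    for s in surfaces:
        scores = np.full(spec.shape, np.nan)
        ok = np.isfinite(s.values)
        scores[ok] = 0.0
        nz = ok & (s.values != 0.0)
        if breaks is not None and nz.any():
            scores[nz] = breaks.assign(s.values[nz]).astype(float)
        out.append(ValueGrid(spec, scores, units="score"))
    return out, breaks


def sum_layers(layers: Sequence[ValueGrid], weights: Sequence[float] | None = None) -> ValueGrid:
    """Cellwise weighted sum of score layers (equal weights by default)."""
    if not layers:
        raise ValueError("no layers to sum")
    spec = layers[0].spec
    if any(l.spec != spec for l in layers):
        raise AlignmentError("layers to sum are not aligned")
    if weights is None:
        weights = [1.0] * len(layers)
    if len(weights) != len(layers):
        raise ValueError("one weight per layer required")
    total = np.zeros(spec.shape)
    for w, l in zip(weights, layers):
        total = total + w * l.values
    return ValueGrid(spec, total, units="score")


@dataclass
class HDIGrid:
    """Composite human-disturbance surface with its three component layers."""

    spec: GridSpec
    hdi: np.ndarray
    components: dict[str, ValueGrid]

    def as_value_grid(self) -> ValueGrid:
        return ValueGrid(self.spec, self.hdi, units="hdi")


def combine_hdi(lni: ValueGrid, rci: ValueGrid, pei: ValueGrid) -> HDIGrid:
    """HDI = LNI + RCI + PEI, cellwise, on [0, 60].

    Component ranges are validated (LNI ≤ 10, RCI ≤ 20, PEI ≤ 30); a layer
    out of range raises :class:`~hdikit.errors.RangeError` naming it.
    """
    spec = lni.spec
    if rci.spec != spec or pei.spec != spec:
        raise AlignmentError("HDI component layers are not aligned")
    for name, layer, hi in (("LNI", lni, 10.0), ("RCI", rci, 20.0), ("PEI", pei, 30.0)):
        v = layer.values[np.isfinite(layer.values)]
        if v.size and (v.min() < -1e-9 or v.max() > hi + 1e-9):
            raise RangeError(f"{name} layer outside [0, {hi:g}]: range [{v.min():g}, {v.max():g}]")
    hdi = lni.values + rci.values + pei.values
    return HDIGrid(spec, hdi, {"LNI": lni, "RCI": rci, "PEI": pei})


@dataclass
class LevelGrid:
    """Integer disturbance levels 1..10 (I..X); 0 marks nodata."""

    spec: GridSpec
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.shape != self.spec.shape:
            raise ValueError("levels shape mismatch")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


def classify_levels(hdi: HDIGrid | ValueGrid) -> LevelGrid:
    """Cut HDI into ten equal-interval levels of width 6.

    Level 1 (I) covers [0, 6]; level n covers (6(n−1), 6n] for n ≥ 2, so on
    integers the ranges read 0–6, 7–12, …, 55–60.  Values outside [0, 60]
    raise :class:`~hdikit.errors.RangeError`.
    """
    vals = hdi.hdi if isinstance(hdi, HDIGrid) else hdi.values
    spec = hdi.spec
    ok = np.isfinite(vals)
    v = vals[ok]
    if v.size and (v.min() < -1e-9 or v.max() > 60 + 1e-9):
        raise RangeError(f"HDI outside [0, 60]: range [{v.min():g}, {v.max():g}]")
    levels = np.zeros(spec.shape, dtype=int)
    levels[ok] = np.maximum(1, np.ceil(np.clip(vals[ok], 0, 60) / 6.0 - 1e-12)).astype(int)
    return LevelGrid(spec, levels)


def tabulate_levels(
    levels: LevelGrid,
    zones: LandUseGrid | None = None,
    period_label: str = "",
    round_to: int | None = None,
) -> pd.DataFrame:
    """Percentage of valid cells in each disturbance level, per zone.

    Returns one row per zone (one ``"all"`` row without zones) with columns
    ``zone, period, I..X``; percentages sum to 100 exactly before optional
    rounding (``round_to`` digits emulates printed tables).  Empty zones are
    skipped with a warning.
    """
    if zones is not None and zones.spec != levels.spec:
        raise AlignmentError("zone raster not aligned with level grid")
    rows = []
    if zones is None:
        zone_items = [("all", levels.mask)]
    else:
        zone_items = []
        for code, name in sorted(zones.legend.items()):
            if name == "nodata":
                continue
            sel = (zones.codes == code) & levels.mask
            if not sel.any():
                warnings.warn(f"zone {name!r} has no valid cells; omitted", stacklevel=2)
                continue
            zone_items.append((name, sel))
    for zone_name, sel in zone_items:
        n = int(sel.sum())
        shares = [100.0 * float((levels.levels[sel] == lv).sum()) / n for lv in range(1, 11)]
        if round_to is not None:
            shares = [round(s, round_to) for s in shares]
        rows.append({"zone": zone_name, "period": period_label, **dict(zip(ROMAN_LEVELS, shares))})
    return pd.DataFrame(rows, columns=["zone", "period", *ROMAN_LEVELS])
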