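"""Humphrey 30-2 visual-field eligibility rules.

Implements the study's two field-level screens:

* reliability — a test counts only if fixation losses are below 20% and the
  false-positive rate below 33%;
* the glaucomatous-defect classifier — a cluster of at least three contiguous
  non-edge points depressed below the 5% probability level on the pattern
  deviation plot, one of them below 1%, or a glaucoma hemifield test result
  of "outside normal limits"; the defect must be reproduced on two reliable
  tests.

The 30-2 point layout (76 points at 6 degree spacing, offset 3 degrees from
the meridians) ships as a packaged table marking edge-ring membership and the
two blind-spot locations, so the edge definition is data rather than code.
Adjacency defaults to the 8-neighbourhood on the 6 degree lattice and
clusters are confined to one hemifield; both conventions are configurable
because instruments and papers vary.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PCategory",
    "GhtStatus",
    "VfReliability",
    "PdPoint",
    "PatternDeviationMap",
    "VfExam",
    "load_grid",
    "is_reliable",
    "find_defect_clusters",
    "classify_glaucomatous_vf",
    "confirmed_defect",
]

_GRID_SPACING = 6  # degrees between neighbouring 30-2 points


class PCategory(IntEnum):
    """Pattern-deviation probability category; larger = more depressed."""

    GE5 = 0    # within normal limits (p >= 5%)
    LT5 = 1    # p < 5%
    LT2 = 2    # p < 2%
    LT1 = 3    # p < 1%
    LT05 = 4   # p < 0.5%

    @classmethod
    def parse(cls, label: str | int | "PCategory") -> "PCategory":
        if isinstance(label, cls):
            return label
        if isinstance(label, int):
            return cls(label)
        key = str(label).strip().replace(" ", "").lower().rstrip("%")
        table = {
            ">=5": cls.GE5, "ge5": cls.GE5, "ns": cls.GE5, "normal": cls.GE5,
            "<5": cls.LT5, "lt5": cls.LT5,
            "<2": cls.LT2, "lt2": cls.LT2,
            "<1": cls.LT1, "lt1": cls.LT1,
            "<0.5": cls.LT05, "lt0.5": cls.LT05, "lt05": cls.LT05,
        }
        try:
            return table[key]
        except KeyError:
            raise ValueError(f"unrecognised probability category: {label!r}") from None

    @property
    def depressed(self) -> bool:
        """Below the 5% probability level."""
        return self >= PCategory.LT5

    @property
    def severe(self) -> bool:
        """Below the 1% probability level."""
        return self >= PCategory.LT1


class GhtStatus(str, Enum):
    """Glaucoma hemifield test instrument classification."""

    WITHIN_NORMAL_LIMITS = "within normal limits"
    BORDERLINE = "borderline"
    OUTSIDE_NORMAL_LIMITS = "outside normal limits"
    GENERAL_REDUCTION = "general reduction"
    ABNORMALLY_HIGH = "abnormally high"


@dataclass(frozen=True)
class VfReliability:
    """Catch-trial reliability indices of one field test, in percent."""

    fixation_loss: float
    false_positive: float

    def __post_init__(self) -> None:
        for name in ("fixation_loss", "false_positive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v!r} outside [0, 100]")


def is_reliable(rel: VfReliability) -> bool:
    """True iff fixation losses < 20% and false positives < 33% (strict)."""
    return rel.fixation_loss < 20.0 and rel.false_positive < 33.0


@dataclass(frozen=True)
class PdPoint:
    x_deg: int
    y_deg: int
    p_category: PCategory


@lru_cache(maxsize=1)
def _grid_cached() -> pd.DataFrame:
    with resources.files("rocglm.data").joinpath("grid_30_2.csv").open() as fh:
        df = pd.read_csv(fh)
    df["is_edge"] = df["is_edge"].astype(bool)
    df["is_blind_spot"] = df["is_blind_spot"].astype(bool)
    return df


def load_grid() -> pd.DataFrame:
    """Packaged 30-2 layout: x_deg, y_deg, is_edge, is_blind_spot."""
    return _grid_cached().copy()


@dataclass
class PatternDeviationMap:
    """Per-point probability categories of one 30-2 pattern deviation plot.

    Only depressed points need be listed; absent grid points are treated as
    within normal limits.
    """

    points: tuple[PdPoint, ...]
    grid_id: str = "30-2"

    def __post_init__(self) -> None:
        grid = load_grid()
        valid = set(zip(grid["x_deg"], grid["y_deg"]))
        pts = []
        seen = set()
        for p in self.points:
            if not isinstance(p, PdPoint):
                x, y, cat = p
                p = PdPoint(int(x), int(y), PCategory.parse(cat))
            if (p.x_deg, p.y_deg) not in valid:
                raise ValueError(
                    f"({p.x_deg}, {p.y_deg}) is not a {self.grid_id} grid point"
                )
            if (p.x_deg, p.y_deg) in seen:
                raise ValueError(f"duplicate point ({p.x_deg}, {p.y_deg})")
            seen.add((p.x_deg, p.y_deg))
            pts.append(p)
        self.points = tuple(pts)

    @classmethod
    def from_csv(cls, path: str | Path, *, delimiter: str = ",") -> "PatternDeviationMap":
        df = pd.read_csv(path, sep=delimiter)
        return cls(
            tuple(
                PdPoint(int(r.x_deg), int(r.y_deg), PCategory.parse(r.p_category))
                for r in df.itertuples()
            )
        )


def _neighbours(x: int, y: int, diagonal: bool) -> Iterable[tuple[int, int]]:
    s = _GRID_SPACING
    steps = [(-s, 0), (s, 0), (0, -s), (0, s)]
    if diagonal:
        steps += [(-s, -s), (-s, s), (s, -s), (s, s)]
    for dx, dy in steps:
        yield x + dx, y + dy


def find_defect_clusters(
    pd_map: PatternDeviationMap,
    *,
    diagonal_adjacency: bool = True,
    within_hemifield: bool = True,
) -> list[frozenset[tuple[int, int]]]:
    """Maximal clusters satisfying the glaucomatous-defect point rule.

    A qualifying cluster is a maximal connected set of non-edge, non-blind-
    spot points depressed below p<5%, of size >= 3, containing at least one
    point below p<1%.  With ``within_hemifield`` (default) connectivity never
    crosses the horizontal midline.
    """
    grid = load_grid()
    eligible_pos = {
        (int(r.x_deg), int(r.y_deg))
        for r in grid.itertuples()
        if not r.is_edge and not r.is_blind_spot
    }
    cat = {
        (p.x_deg, p.y_deg): p.p_category
        for p in pd_map.points
        if p.p_category.depressed and (p.x_deg, p.y_deg) in eligible_pos
    }

    clusters: list[frozenset[tuple[int, int]]] = []
    unvisited = set(cat)
    while unvisited:
        seed = unvisited.pop()
        component = {seed}
        frontier = [seed]
        while frontier:
            x, y = frontier.pop()
            for nb in _neighbours(x, y, diagonal_adjacency):
                if nb not in unvisited:
                    continue
                if within_hemifield and (nb[1] > 0) != (y > 0):
                    continue
                unvisited.discard(nb)
                component.add(nb)
                frontier.append(nb)
        if len(component) >= 3 and any(cat[p].severe for p in component):
            clusters.append(frozenset(component))
    return clusters


def classify_glaucomatous_vf(pd_map: PatternDeviationMap, ght: GhtStatus, **cluster_opts) -> bool:
    """Defect present iff a qualifying cluster exists or GHT is outside normal limits."""
    if ght == GhtStatus.OUTSIDE_NORMAL_LIMITS:
        return True
    return bool(find_defect_clusters(pd_map, **cluster_opts))


@dataclass(frozen=True)
class VfExam:
    """One field test: its reliability indices and defect classification."""

    reliability: VfReliability
    glaucomatous: bool


def confirmed_defect(exams: Sequence[VfExam]) -> bool:
    """True iff at least two reliable tests each show a glaucomatous defect."""
    if not exams:
        raise ValueError("at least one field test is required")
    n = sum(1 for e in exams if is_reliable(e.reliability) and e.glaucomatous)
    return n >= 2
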