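"""Four-criterion cardiotoxicity-potential ranking rubric.

Each drug is scored on four anchorage criteria — residence time,
membrane hydrogen bonds, distance from the bilayer mid-plane, and the
reduction of its diffusion coefficient near the membrane — against
configurable first/second-category bands:

================  =========================  =========================
criterion          1st category               2nd category
================  =========================  =========================
residence (%)      > 20                       12 to 20
hbonds (/frame)    > 0.1                      0.05 to 0.1
midplane (nm)      < 2.6                      2.6 to 4.16
diffusion (%)      < 25                       25 to 35
================  =========================  =========================

Leaflet-resolved criteria (residence, hbonds, midplane) are evaluated
per leaflet; a drug's category for the criterion is the best any
leaflet achieves, tagged ``U`` (upper), ``L`` (lower) or ``B`` (both
leaflets reach the best category).  A drug ranks higher the more first
categories it collects, then second categories; remaining ties break by
the layer breadth of the residence mark (both leaflets beats one), then
by which criteria hold the marks in column order (residence > hbonds >
midplane > diffusion).  Drugs identical under every rule are reported
as an explicit tie group, listed alphabetically.  Band boundary
inclusivity is configurable because prose thresholds are ambiguous at
exact boundaries; defaults read "more than" as strict and "between a
and b" as the closed interval.

Outputs are an anchorage-based potential ranking; no clinical inference
is made.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CRITERIA = ("residence", "hbonds", "midplane", "diffusion_ratio")
LEAFLET_CRITERIA = ("residence", "hbonds", "midplane")
CATEGORY_ORDER = {"first": 0, "second": 1, "none": 2, "unavailable": 3}
CATEGORY_SYMBOL = {"first": "*", "second": "x", "none": "", "unavailable": "?"}


@dataclass(frozen=True)
class Interval:
    """A numeric band with configurable boundary inclusivity."""

    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = True

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"empty interval: lo={self.lo} > hi={self.hi}")

    def contains(self, x: float) -> bool:
        above = x >= self.lo if self.lo_closed else x > self.lo
        below = x <= self.hi if self.hi_closed else x < self.hi
        return above and below

    def overlaps(self, other: "Interval") -> bool:
        lo = max(self.lo, other.lo)
        hi = min(self.hi, other.hi)
        if lo > hi:
            return False
        if lo < hi:
            return True
        # single shared point: overlap only if closed on both sides
        a_closed = (self.lo_closed if lo == self.lo else True) and \
                   (self.hi_closed if lo == self.hi else True)
        b_closed = (other.lo_closed if lo == other.lo else True) and \
                   (other.hi_closed if lo == other.hi else True)
        return a_closed and b_closed


@dataclass(frozen=True)
class CriterionBands:
    """First/second category bands for one criterion."""

    first: Interval
    second: Interval

    def __post_init__(self) -> None:
        if self.first.overlaps(self.second):
            raise ValueError("first and second bands overlap")

    def categorize(self, value: float) -> str:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "unavailable"
        if self.first.contains(value):
            return "first"
        if self.second.contains(value):
            return "second"
        return "none"


INF = float("inf")


@dataclass(frozen=True)
class RubricConfig:
    """Category thresholds for the four anchorage criteria."""

    residence: CriterionBands = field(default_factory=lambda: CriterionBands(
        first=Interval(20.0, INF, lo_closed=False),
        second=Interval(12.0, 20.0),
    ))
    hbonds: CriterionBands = field(default_factory=lambda: CriterionBands(
        first=Interval(0.1, INF, lo_closed=False),
        second=Interval(0.05, 0.1),
    ))
    midplane: CriterionBands = field(default_factory=lambda: CriterionBands(
        first=Interval(-INF, 2.6, hi_closed=False),
        second=Interval(2.6, 4.16),
    ))
    diffusion_ratio: CriterionBands = field(default_factory=lambda: CriterionBands(
        first=Interval(-INF, 25.0, hi_closed=False),
        second=Interval(25.0, 35.0),
    ))

    def bands(self, criterion: str) -> CriterionBands:
        if criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {criterion!r}")
        return getattr(self, criterion)


@dataclass
class DrugMetricBundle:
    """Per-drug metric values feeding the rubric.

    Leaflet-resolved criteria map leaflet/side labels ("upper",
    "lower") to values; a missing or NaN value marks that leaflet (or
    the whole criterion) unavailable.
    """

    residence: Mapping[str, float] = field(default_factory=dict)
    hbonds: Mapping[str, float] = field(default_factory=dict)
    midplane: Mapping[str, float] = field(default_factory=dict)
    diffusion_ratio: float | None = None


@dataclass(frozen=True)
class Cell:
    """One drug x criterion rubric assignment."""

    category: str          # first | second | none | unavailable
    layer: str             # U | L | B | -


class CategoryTable:
    """Per-drug, per-criterion category/layer assignments."""

    def __init__(self, cells: Mapping[str, Mapping[str, Cell]]):
        self._cells = {d: dict(c) for d, c in cells.items()}

    @property
    def drugs(self) -> list[str]:
        return list(self._cells)

    def cell(self, drug: str, criterion: str) -> Cell:
        return self._cells[drug][criterion]

    def counts(self, drug: str) -> tuple[int, int]:
        cats = [c.category for c in self._cells[drug].values()]
        return cats.count("first"), cats.count("second")

    def to_dataframe(self) -> pd.DataFrame:
        """Symbol table: '*' first, 'x' second, layer tag appended."""
        rows = {}
        for drug, cells in self._cells.items():
            row = {}
            for crit in CRITERIA:
                c = cells[crit]
                sym = CATEGORY_SYMBOL[c.category]
                row[crit] = f"{c.layer}{sym}" if sym and c.layer != "-" else sym
            rows[drug] = row
        return pd.DataFrame.from_dict(rows, orient="index")[list(CRITERIA)]


def _categorize_leaflet_criterion(
    values: Mapping[str, float], bands: CriterionBands, lower_is_better: bool
) -> Cell:
    per_leaflet = {}
    for leaflet in ("upper", "lower"):
        v = values.get(leaflet)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        per_leaflet[leaflet] = bands.categorize(v)
    if not per_leaflet:
        return Cell("unavailable", "-")
    best = min(per_leaflet.values(), key=CATEGORY_ORDER.__getitem__)
    if best in ("none", "unavailable"):
        return Cell(best, "-")
    achieving = [lf for lf, c in per_leaflet.items() if c == best]
    layer = "B" if len(achieving) == 2 else ("U" if achieving[0] == "upper" else "L")
    return Cell(best, layer)


def categorize(
    bundles: Mapping[str, DrugMetricBundle],
    config: RubricConfig | None = None,
) -> CategoryTable:
    """Apply the rubric to per-drug metric bundles.

    For each leaflet-resolved criterion the overall category is the best
    leaflet's category and the layer tag records which leaflet(s)
    achieved it.  A missing metric marks the criterion ``unavailable``
    (excluded from the first/second counts) with a logged warning.
    """
    config = config or RubricConfig()
    cells: dict[str, dict[str, Cell]] = {}
    for drug, bundle in bundles.items():
        row: dict[str, Cell] = {}
        for crit in LEAFLET_CRITERIA:
            cell = _categorize_leaflet_criterion(
                getattr(bundle, crit), config.bands(crit),
                lower_is_better=(crit == "midplane"),
            )
            if cell.category == "unavailable":
                logger.warning("%s: criterion %r unavailable", drug, crit)
            row[crit] = cell
        v = bundle.diffusion_ratio
        if v is None or (isinstance(v, float) and math.isnan(v)):
            logger.warning("%s: criterion 'diffusion_ratio' unavailable", drug)
            row["diffusion_ratio"] = Cell("unavailable", "-")
        else:
            row["diffusion_ratio"] = Cell(
                config.bands("diffusion_ratio").categorize(v), "-"
            )
        cells[drug] = row
    return CategoryTable(cells)


@dataclass
class RankingResult:
    """Deterministic drug ordering with explicit tie groups."""

    order: list[str]
    tie_groups: list[list[str]]

    def position(self, drug: str) -> int:
        return self.order.index(drug)

    def tied_ranks(self) -> dict[str, float]:
        """Competition-free average rank per drug (1-based, ties share)."""
        ranks: dict[str, float] = {}
        next_rank = 1
        for group in self.tie_groups:
            avg = next_rank + (len(group) - 1) / 2.0
            for d in group:
                ranks[d] = avg
            next_rank += len(group)
        return ranks


_LAYER_BREADTH = {"B": 2, "U": 1, "L": 1, "-": 0}


def _sort_key(table: CategoryTable, drug: str) -> tuple:
    n_first, n_second = table.counts(drug)
    residence_breadth = _LAYER_BREADTH[table.cell(drug, "residence").layer]
    # which criteria hold the marks, in column-priority order
    crit_vector = tuple(
        -{"first": 2, "second": 1}.get(table.cell(drug, c).category, 0)
        for c in CRITERIA
    )
    return (-n_first, -n_second, -residence_breadth, crit_vector)


def rank(table: CategoryTable) -> RankingResult:
    """Total preorder over the drugs of a category table.

    Sort by count of first categories (descending), then count of
    seconds, then residence layer breadth (both > single), then by
    which criteria hold the marks in column-priority order.  Drugs equal
    under all keys form a declared tie group and are listed
    alphabetically.
    """
    keys = {d: _sort_key(table, d) for d in table.drugs}
    ordered = sorted(table.drugs, key=lambda d: (keys[d], d))
    tie_groups: list[list[str]] = []
    for d in ordered:
        if tie_groups and keys[tie_groups[-1][0]] == keys[d]:
            tie_groups[-1].append(d)
        else:
            tie_groups.append([d])
    return RankingResult(order=ordered, tie_groups=tie_groups)


def rank_correlation(
    ranking: RankingResult | Sequence[str],
    dipoles: Mapping[str, float],
) -> float:
    """Spearman rank correlation between the ranking and dipole moments.

    Tie groups in the ranking receive average ranks.  Needs at least
    three drugs with both a rank and a dipole value.  A coefficient
    near zero indicates the dipole moment carries no information about
    the anchorage-based ordering.
    """
    if isinstance(ranking, RankingResult):
        ranks = ranking.tied_ranks()
    else:
        ranks = {d: i + 1.0 for i, d in enumerate(ranking)}
    common = [d for d in ranks if d in dipoles]
    if len(common) < 3:
        raise ValueError(
            f"rank correlation needs >= 3 paired observations, got {len(common)}"
        )
    r = [ranks[d] for d in common]
    mu = [dipoles[d] for d in common]
    rho, _ = stats.spearmanr(r, mu)
    return float(rho)
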