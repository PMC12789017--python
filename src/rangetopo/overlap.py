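"""Multi-way intersection/union ratios over core-range polygons.

A *core range* is the concentrated-use portion of one individual's seasonal
home range, taken here as a given planar polygon (possibly multi-part, with
holes) in metric coordinates.  For a subset ``S`` of individuals the overlap
ratio is

    w(S) = Area(intersection of ranges in S) / Area(union of ranges in S),

a multi-set Jaccard index in ``[0, 1]``.  :func:`enumerate_overlaps` tabulates
``w`` for every subset of size ``2..n_max`` with non-negligible common
intersection, pruning the subset lattice apriori-style: intersection area is
monotonically non-increasing under subset inclusion, so a subset with an
empty intersection is never extended.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from shapely import union_all
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .optimality import AlphaMapping, DEFAULT_MAPPING

__all__ = [
    "SQ_M_PER_HA",
    "DEFAULT_EPS_AREA_HA",
    "CoreRange",
    "OverlapRecord",
    "OverlapTable",
    "polygon_area",
    "intersection_union_ratio",
    "enumerate_overlaps",
]

logger = logging.getLogger(__name__)

SQ_M_PER_HA = 10_000.0

#: Default sliver threshold: 1 m^2.  Tiny boolean-operation slivers must not
#: create spurious simplices downstream.
DEFAULT_EPS_AREA_HA = 1e-4

SEASONS = ("dry", "wet")


def _clean(geometry: BaseGeometry) -> BaseGeometry:
    """Repair a geometry for boolean operations; raise if unrecoverable."""
    if geometry is None or geometry.is_empty:
        raise ValueError("empty geometry")
    if not geometry.is_valid:
        geometry = make_valid(geometry)
        if not geometry.is_valid:
            raise ValueError("geometry could not be repaired")
    return geometry


@dataclass
class CoreRange:
    """One individual's seasonal core-range polygon.

    Coordinates are planar and in metres; no CRS handling is performed.
    """

    individual_id: str
    geometry: BaseGeometry
    season: str = "dry"
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValueError("individual_id must be a non-empty token")
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        self.geometry = _clean(self.geometry)
        if self.geometry.area <= 0:
            raise ValueError(
                f"core range {self.individual_id!r} has zero area"
            )

    @property
    def area_ha(self) -> float:
        return self.geometry.area / SQ_M_PER_HA


def polygon_area(geometry: BaseGeometry) -> float:
    """Planar area of a (multi-)polygon in hectares, holes subtracted.

    Attempts a validity repair on broken rings before failing.
    """
    geometry = _clean(geometry)
    return geometry.area / SQ_M_PER_HA


def intersection_union_ratio(
    geometries: list[BaseGeometry],
) -> tuple[float, float, float]:
    """Intersection area, union area (both hectares) and their ratio ``w``.

    ``w = 1`` iff all geometries coincide; ``w = 0`` iff the common
    intersection is empty.
    """
    if not geometries:
        raise ValueError("at least one geometry is required")
    cleaned = [_clean(g) for g in geometries]
    inter = cleaned[0]
    for g in cleaned[1:]:
        inter = inter.intersection(g)
        if inter.is_empty:
            break
    union = union_all(cleaned)
    inter_ha = (0.0 if inter.is_empty else inter.area) / SQ_M_PER_HA
    union_ha = union.area / SQ_M_PER_HA
    if union_ha <= 0:
        raise ValueError("union has zero area")
    return inter_ha, union_ha, inter_ha / union_ha


@dataclass(frozen=True)
class OverlapRecord:
    """Overlap of one subset of individuals.

    ``members`` is the canonical (sorted) id tuple; all downstream keys use
    this form.  ``alpha`` is the filtration index solving
    ``w = f(alpha) / (n + 1)``.
    """

    members: tuple[str, ...]
    intersection_ha: float
    union_ha: float
    w: float
    alpha: float

    def __post_init__(self) -> None:
        if tuple(sorted(self.members)) != self.members:
            raise ValueError("members must be a sorted tuple")
        if len(set(self.members)) != len(self.members):
            raise ValueError("members must be distinct")
        if self.union_ha <= 0:
            raise ValueError("union area must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")
        if abs(self.w - self.intersection_ha / self.union_ha) > 1e-9:
            raise ValueError("w inconsistent with intersection/union areas")

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class OverlapTable:
    """All overlap records for one season, subsets of size ``2..n_max``."""

    records: list[OverlapRecord]
    n_max: int
    eps_area: float = DEFAULT_EPS_AREA_HA
    season: str | None = None

    def __post_init__(self) -> None:
        if self.n_max < 2:
            raise ValueError("n_max must be >= 2")
        self.records = sorted(self.records, key=lambda r: (r.n, r.members))

    def by_members(self) -> dict[tuple[str, ...], OverlapRecord]:
        return {r.members: r for r in self.records}

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(sorted({m for r in self.records for m in r.members}))

    def check_monotonicity(self, tol: float = 1e-9) -> None:
        """Assert ``w(T) <= w(S) + tol`` for every recorded ``S`` subset of ``T``."""
        lookup = self.by_members()
        for members, rec in lookup.items():
            if len(members) == 2:
                continue
            for k in range(2, len(members)):
                for sub in itertools.combinations(members, k):
                    sub_rec = lookup.get(sub)
                    if sub_rec is not None and rec.w > sub_rec.w + tol:
                        raise AssertionError(
                            f"w monotonicity violated: w{members}={rec.w} > "
                            f"w{sub}={sub_rec.w}"
                        )


def enumerate_overlaps(
    ranges: list[CoreRange],
    n_max: int = 6,
    eps_area: float = DEFAULT_EPS_AREA_HA,
    mapping: AlphaMapping = DEFAULT_MAPPING,
    season: str | None = None,
) -> OverlapTable:
    """Tabulate ``w`` for every subset of size ``2..n_max`` with common overlap.

    A subset enters the table iff its common intersection area exceeds
    ``eps_area`` (hectares).  Enumeration grows subsets one id at a time and
    never extends a subset whose intersection is already below threshold,
    which is exact because intersection area is monotone non-increasing in
    subset inclusion.

    ``n_max`` larger than the number of ranges is capped with a logged
    warning.
    """
    if len(ranges) < 2:
        raise ValueError("need at least two core ranges")
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    ids = [r.individual_id for r in ranges]
    if len(set(ids)) != len(ids):
        raise ValueError("individual ids must be unique")
    if n_max > len(ranges):
        logger.warning(
            "n_max=%d exceeds the %d available ranges; capping", n_max, len(ranges)
        )
        n_max = len(ranges)

    geoms = {r.individual_id: _clean(r.geometry) for r in ranges}
    order = sorted(geoms)
    eps_m2 = eps_area * SQ_M_PER_HA

    records: list[OverlapRecord] = []
    # frontier: canonical subset tuple -> cached intersection geometry
    frontier: dict[tuple[str, ...], BaseGeometry] = {
        (i,): geoms[i] for i in order
    }
    for size in range(2, n_max + 1):
        next_frontier: dict[tuple[str, ...], BaseGeometry] = {}
        for subset, inter in frontier.items():
            start = order.index(subset[-1]) + 1
            for j in order[start:]:
                new_inter = inter.intersection(geoms[j])
                if new_inter.is_empty or new_inter.area <= eps_m2:
                    continue
                members = subset + (j,)
                next_frontier[members] = new_inter
                union_ha = union_all([geoms[m] for m in members]).area / SQ_M_PER_HA
                inter_ha = new_inter.area / SQ_M_PER_HA
                w = inter_ha / union_ha
                records.append(
                    OverlapRecord(
                        members=members,
                        intersection_ha=inter_ha,
                        union_ha=union_ha,
                        w=w,
                        alpha=mapping.alpha_from_w(w, len(members)),
                    )
                )
        frontier = next_frontier
        if not frontier:
            break

    return OverlapTable(records=records, n_max=n_max, eps_area=eps_area, season=season)
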