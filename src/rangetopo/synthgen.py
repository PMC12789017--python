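"""Synthetic inputs: core-range polygons, overlap-table fixtures, phenology.

Every downstream stage is testable without field data.  Core ranges are
built as union(hub disc at a common centre, per-individual disc offset on a
ring): the hub guarantees an all-way overlap (in the real system all core
ranges coincide in a small central area) while the offset lobes give each
individual a region of its own.  Geometry-free fixtures construct overlap
tables with prescribed topology directly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon
from shapely import union_all

from .optimality import AlphaMapping, DEFAULT_MAPPING
from .overlap import CoreRange, OverlapRecord, OverlapTable, SEASONS

__all__ = [
    "GeneratorConfig",
    "FixtureSpec",
    "GenerationError",
    "gen_core_ranges",
    "gen_ring_fixture",
    "gen_four_rectangle_fixture",
    "gen_phenology",
    "gen_patch_table",
    "overlap_table_from_fixture",
    "PhenologyRow",
]

#: Dry-season ranges are larger and less overlapping than wet-season ones;
#: no specific ratio is known, so this is a free parameter, not an estimate.
DRY_RANGE_FACTOR = 1.5


class GenerationError(ValueError):
    """A generator configuration produced degenerate (zero-area) output."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the hub-plus-lobe core-range generator.

    All lengths are metres.  ``lobe_offset_m`` and ``jitter_sd_m`` may be
    zero; every other length must be strictly positive.  The same seed
    always yields byte-identical output.
    """

    n_individuals: int
    seed: int = 0
    season_label: str = "wet"
    hub_radius_m: float = 150.0
    lobe_offset_m: float = 500.0
    range_radius_mean_m: float = 400.0
    polygon_vertices: int = 64
    jitter_sd_m: float = 25.0
    dry_season_factor: float = DRY_RANGE_FACTOR
    year: int = 2012

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.season_label not in SEASONS:
            raise ValueError(f"season_label must be one of {SEASONS}")
        if self.hub_radius_m <= 0 or self.range_radius_mean_m <= 0:
            raise GenerationError("radii must be strictly positive")
        if self.lobe_offset_m < 0 or self.jitter_sd_m < 0:
            raise ValueError("lobe_offset_m and jitter_sd_m must be >= 0")
        if self.polygon_vertices < 8:
            raise ValueError("polygon_vertices must be >= 8")
        if self.dry_season_factor <= 0:
            raise ValueError("dry_season_factor must be > 0")

    @property
    def effective_range_radius_m(self) -> float:
        factor = self.dry_season_factor if self.season_label == "dry" else 1.0
        return self.range_radius_mean_m * factor


def _disc(cx: float, cy: float, radius: float, k: int) -> Polygon:
    """Regular k-gon inscribed in the circle of the given centre/radius."""
    angles = np.linspace(0.0, 2.0 * math.pi, k, endpoint=False)
    coords = np.column_stack((cx + radius * np.cos(angles), cy + radius * np.sin(angles)))
    return Polygon(coords)


def gen_core_ranges(config: GeneratorConfig) -> list[CoreRange]:
    """Generate ``n_individuals`` partially overlapping core-range polygons.

    Every polygon contains the central hub disc, so the intersection of all
    of them is non-empty; when ``lobe_offset_m > 0`` each individual's lobe
    extends away from the hub along its own ring angle, giving it a region
    not covered by the others (for non-pathological radii).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    k = config.polygon_vertices
    hub = _disc(0.0, 0.0, config.hub_radius_m, k)
    radius = config.effective_range_radius_m

    ranges: list[CoreRange] = []
    for i in range(n):
        theta = 2.0 * math.pi * i / n
        cx = config.lobe_offset_m * math.cos(theta) + rng.normal(0.0, config.jitter_sd_m)
        cy = config.lobe_offset_m * math.sin(theta) + rng.normal(0.0, config.jitter_sd_m)
        r_i = radius + rng.normal(0.0, config.jitter_sd_m)
        if r_i <= 0:
            raise GenerationError(
                f"jittered radius for individual {i} is non-positive ({r_i:.1f} m); "
                "reduce jitter_sd_m or increase range_radius_mean_m"
            )
        geom = union_all([hub, _disc(cx, cy, r_i, k)])
        if geom.is_empty or geom.area <= 0:
            raise GenerationError(f"degenerate polygon for individual {i}")
        ranges.append(
            CoreRange(
                individual_id=f"ind{i:02d}",
                geometry=geom,
                season=config.season_label,
                year=config.year,
            )
        )
    return ranges


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry-free overlap table: subsets of a vertex universe with target w.

    ``target_w`` must respect monotonicity: the w of a superset never exceeds
    the w of any of its recorded subsets.
    """

    vertex_universe: tuple[str, ...]
    target_w: dict[tuple[str, ...], float]

    def __post_init__(self) -> None:
        universe = set(self.vertex_universe)
        for members, w in self.target_w.items():
            if tuple(sorted(members)) != members:
                raise ValueError(f"subset {members} not canonical (sorted)")
            if not set(members) <= universe:
                raise ValueError(f"subset {members} outside vertex universe")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"target w for {members} outside [0, 1]")
        for members, w in self.target_w.items():
            for k in range(2, len(members)):
                for sub in itertools.combinations(members, k):
                    sub_w = self.target_w.get(sub)
                    if sub_w is not None and w > sub_w + 1e-9:
                        raise ValueError(
                            f"monotonicity violated: w{members}={w} > w{sub}={sub_w}"
                        )


def overlap_table_from_fixture(
    spec: FixtureSpec,
    n_max: int | None = None,
    mapping: AlphaMapping = DEFAULT_MAPPING,
) -> OverlapTable:
    """Materialise a :class:`FixtureSpec` as an overlap table.

    Areas are synthetic: each record gets union area 1 ha and intersection
    area ``w`` ha, which reproduces the requested ratio exactly.
    """
    if n_max is None:
        n_max = max((len(m) for m in spec.target_w), default=2)
    records = [
        OverlapRecord(
            members=members,
            intersection_ha=w,
            union_ha=1.0,
            w=w,
            alpha=mapping.alpha_from_w(w, len(members)),
        )
        for members, w in spec.target_w.items()
    ]
    return OverlapTable(records=records, n_max=n_max, eps_area=0.0)


def gen_ring_fixture(k: int, w_pair: float) -> FixtureSpec:
    """A k-cycle of pairwise overlaps and nothing else.

    Exactly the ``k`` cyclic pairs ``{i, i+1 mod k}`` carry ``w = w_pair``;
    no subset of size >= 3 is present, so the cycle is never filled and the
    filtration carries exactly one dimension-1 feature once all pairs have
    entered.  ``k < 4`` is rejected to keep the contract unambiguous.
    """
    if k < 4:
        raise ValueError(f"ring fixture requires k >= 4, got {k}")
    if not 0.0 < w_pair < 1.0:
        raise ValueError(f"w_pair must lie strictly in (0, 1), got {w_pair}")
    universe = tuple(f"v{i}" for i in range(k))
    target = {
        tuple(sorted((universe[i], universe[(i + 1) % k]))): w_pair for i in range(k)
    }
    return FixtureSpec(vertex_universe=universe, target_w=target)


#: Rectangles (metres) of the four-range worked example: A, B, C, D.
_QUARTET_BOUNDS = {
    "A": (0.0, 0.0, 1000.0, 1000.0),
    "B": (250.0, 0.0, 1150.0, 600.0),
    "C": (550.0, 0.0, 1550.0, 1000.0),
    "D": (900.0, -4000.0, 5000.0, 900.0),
}


def gen_four_rectangle_fixture(season: str = "dry", year: int = 2012) -> list[CoreRange]:
    """Four rectangles A-D with a prescribed overlap hierarchy.

    Constructed so that w(A,B) > w(B,C) > w(A,C) > w(A,B,C) > every w
    involving D > 0, and the four-way intersection is non-empty.  Under the
    default alpha mapping the filtration therefore adds the A-B edge first,
    then B-C, then A-C (closing a 1-dimensional hole), then the triangle
    [A,B,C] (filling it); D's interactions enter last and complete a full
    3-dimensional simplex without opening any further hole.
    """
    ranges = []
    for name, (x0, y0, x1, y1) in _QUARTET_BOUNDS.items():
        geom = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
        ranges.append(CoreRange(individual_id=name, geometry=geom, season=season, year=year))
    return ranges


@dataclass(frozen=True)
class PhenologyRow:
    """One species in one fortnight: fruiting fraction, DBH sum, density."""

    species: str
    period: int
    tf: float
    dbh: float
    den: float


def gen_phenology(n_species: int, n_periods: int, seed: int = 0) -> list[PhenologyRow]:
    """Synthetic fortnightly fruiting table, one row per (species, period).

    Fruiting fractions lie in [0, 1] (with occasional exact zeros); DBH sums
    and densities are positive.  Reproducible under ``seed``.
    """
    if n_species < 1 or n_periods < 1:
        raise ValueError("n_species and n_periods must be >= 1")
    rng = np.random.default_rng(seed)
    dbh = rng.uniform(50.0, 400.0, size=n_species)       # cm, per species
    den = rng.uniform(0.5, 40.0, size=n_species)          # trees / ha
    rows = []
    for p in range(1, n_periods + 1):
        tf = rng.beta(1.5, 3.0, size=n_species)
        tf[rng.random(n_species) < 0.15] = 0.0            # off-season species
        for s in range(n_species):
            rows.append(
                PhenologyRow(
                    species=f"sp{s + 1:02d}",
                    period=p,
                    tf=float(tf[s]),
                    dbh=float(dbh[s]),
                    den=float(den[s]),
                )
            )
    return rows


def gen_patch_table(
    n_vertices: int,
    n_max: int,
    seed: int = 0,
    n_patches: int = 12,
    w_scale: float = 0.5,
    mapping: AlphaMapping = DEFAULT_MAPPING,
) -> OverlapTable:
    """Random geometry-free overlap table from a discrete patch model.

    Each vertex holds a random non-empty subset of ``n_patches`` habitat
    patches and ``w(S) = w_scale * |patches in common| / |patches in total|``.
    Intersections shrink and unions grow under subset inclusion, so the
    table is monotone by construction; ``w_scale < 1`` keeps every alpha
    value strictly positive at all subset sizes.  Useful as a source of
    varied, valid filtration inputs for randomised testing.
    """
    if n_vertices < 2:
        raise ValueError("n_vertices must be >= 2")
    if not 0.0 < w_scale * (n_max + 1) < 5.0:
        raise ValueError("w_scale too large: alpha would leave (0, 5)")
    rng = np.random.default_rng(seed)
    patches = []
    for _ in range(n_vertices):
        size = int(rng.integers(2, max(3, n_patches // 2) + 1))
        patches.append(frozenset(rng.choice(n_patches, size=size, replace=False).tolist()))
    ids = [f"v{i}" for i in range(n_vertices)]

    records = []
    for size in range(2, min(n_max, n_vertices) + 1):
        for combo in itertools.combinations(range(n_vertices), size):
            inter = frozenset.intersection(*(patches[i] for i in combo))
            if not inter:
                continue
            union = frozenset.union(*(patches[i] for i in combo))
            w = w_scale * len(inter) / len(union)
            members = tuple(sorted(ids[i] for i in combo))
            records.append(
                OverlapRecord(
                    members=members,
                    intersection_ha=w,
                    union_ha=1.0,
                    w=w,
                    alpha=mapping.alpha_from_w(w, size),
                )
            )
    return OverlapTable(records=records, n_max=n_max, eps_area=0.0)
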