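"""Filtered simplicial complexes and persistent homology over GF(2).

An alpha-annotated overlap table defines a filtration: a subset of
individuals with entry value ``alpha`` becomes a simplex once the filtration
parameter reaches that value, and every face it implies is pulled down with
it (downward closure).  All vertices enter at ``alpha = 0``; the parameter
runs over ``[0, 5)``.  Persistence is computed by standard boundary-matrix
column reduction; :func:`betti_at` provides an independent rank-based check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .optimality import ALPHA_MAX
from .overlap import OverlapTable

__all__ = [
    "Simplex",
    "FilteredComplex",
    "PersistenceBar",
    "BettiCurve",
    "ClosureError",
    "assign_entry_values",
    "compute_persistence",
    "betti_curve",
    "betti_curves",
    "betti_at",
    "euler_characteristic",
]

#: A simplex is a canonical (sorted) tuple of vertex ids.
Simplex = tuple[str, ...]


class ClosureError(ValueError):
    """A complex violates downward closure; names the offending face."""


def _dim(simplex: Simplex) -> int:
    return len(simplex) - 1


def _facets(simplex: Simplex) -> Iterable[Simplex]:
    """The (dim-1)-faces of a simplex."""
    for i in range(len(simplex)):
        yield simplex[:i] + simplex[i + 1 :]


@dataclass
class FilteredComplex:
    """Simplices with entry values on ``[0, 5)``, downward-closed throughout.

    ``entries`` maps each canonical simplex to the alpha at which it enters.
    Invariants (checked by :meth:`validate`): every face of every simplex is
    present with an entry value no larger than its coface's; all vertices
    enter at 0; no simplex exceeds ``n_max`` vertices.
    """

    entries: dict[Simplex, float]
    n_max: int

    @property
    def vertices(self) -> tuple[str, ...]:
        return tuple(sorted(s[0] for s in self.entries if len(s) == 1))

    @property
    def dimension(self) -> int:
        """Dimension of the final complex (largest simplex, at alpha -> 5)."""
        return max(_dim(s) for s in self.entries)

    def validate(self) -> None:
        for simplex, entry in self.entries.items():
            if tuple(sorted(simplex)) != simplex or len(set(simplex)) != len(simplex):
                raise ValueError(f"simplex {simplex} is not canonical")
            if len(simplex) > self.n_max:
                raise ValueError(f"simplex {simplex} exceeds n_max={self.n_max}")
            if not 0.0 <= entry < ALPHA_MAX:
                raise ValueError(f"entry value {entry} of {simplex} outside [0, 5)")
            if len(simplex) == 1:
                if entry != 0.0:
                    raise ValueError(f"vertex {simplex} must enter at 0, not {entry}")
                continue
            for face in _facets(simplex):
                face_entry = self.entries.get(face)
                if face_entry is None:
                    raise ClosureError(
                        f"face {face} of {simplex} missing from the complex"
                    )
                if face_entry > entry + 1e-12:
                    raise ClosureError(
                        f"face {face} enters at {face_entry} after its coface "
                        f"{simplex} at {entry}"
                    )

    def sorted_simplices(self) -> list[Simplex]:
        """Filtration order: (entry, dimension, lexicographic) — faces first."""
        return sorted(self.entries, key=lambda s: (self.entries[s], len(s), s))

    def simplices_at(self, alpha: float) -> list[Simplex]:
        """Simplices of the subcomplex at ``alpha`` (closed inclusion, entry <= alpha)."""
        return [s for s, e in self.entries.items() if e <= alpha]

    def breakpoints(self) -> list[float]:
        """Sorted distinct entry values."""
        return sorted(set(self.entries.values()))


def assign_entry_values(
    table: OverlapTable,
    vertex_universe: Sequence[str] | None = None,
) -> FilteredComplex:
    """Build the downward-closed filtered complex from an overlap table.

    The entry value of a simplex is the minimum alpha over its own record
    (if any) and all recorded supersets — lower-order simplices are added as
    needed to satisfy downward closure.  Vertices (the whole universe, which
    may include individuals with no recorded overlap) enter at 0.
    """
    if vertex_universe is None:
        vertex_universe = table.member_ids
    universe = set(vertex_universe)
    if not set(table.member_ids) <= universe:
        missing = set(table.member_ids) - universe
        raise ValueError(f"vertex universe is missing ids {sorted(missing)}")

    entries: dict[Simplex, float] = {(v,): 0.0 for v in sorted(universe)}
    for rec in table.records:
        if rec.n > table.n_max:
            raise ValueError(
                f"record {rec.members} has {rec.n} members > n_max={table.n_max}"
            )
        for size in range(2, rec.n + 1):
            for face in itertools.combinations(rec.members, size):
                prev = entries.get(face)
                if prev is None or rec.alpha < prev:
                    entries[face] = rec.alpha
    return FilteredComplex(entries=entries, n_max=table.n_max)


@dataclass(frozen=True)
class PersistenceBar:
    """One persistence interval ``[birth, death)`` in a fixed dimension.

    Features alive at the end of the filtration are censored: they are
    reported with ``death = 5`` (the open end of the interval) and
    ``censored = True``.
    """

    dimension: int
    birth: float
    death: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.birth >= self.death:
            raise ValueError("bar must have birth < death")

    @property
    def length(self) -> float:
        return self.death - self.birth


def compute_persistence(
    complex: FilteredComplex, max_dim: int | None = None
) -> list[PersistenceBar]:
    """Persistence barcode of a filtered complex, coefficients in GF(2).

    Standard column reduction of the boundary matrix in filtration order,
    ties broken by (entry, dimension, lexicographic vertex tuple) so faces
    always precede cofaces.  Zero-length pairs (a feature filled at the same
    alpha it appears) are dropped.  One never-dying dimension-0 bar remains
    per connected component of the final complex — the final complex need
    not be connected, nor trivial.
    """
    if max_dim is None:
        max_dim = complex.n_max - 1
    complex.validate()

    simplices = [s for s in complex.sorted_simplices() if _dim(s) <= max_dim + 1]
    index = {s: i for i, s in enumerate(simplices)}

    # columns as GF(2) bit-vectors over row indices (python ints)
    columns: list[int] = []
    low_to_col: dict[int, int] = {}
    death_of: dict[int, int] = {}  # positive column -> killing column
    for s in simplices:
        if len(s) == 1:
            col = 0
        else:
            col = 0
            for face in _facets(s):
                col |= 1 << index[face]
        while col:
            low = col.bit_length() - 1
            if low not in low_to_col:
                break
            col ^= columns[low_to_col[low]]
        columns.append(col)
        if col:
            low = col.bit_length() - 1
            j = len(columns) - 1
            low_to_col[low] = j
            death_of[low] = j

    bars: list[PersistenceBar] = []
    for i, s in enumerate(simplices):
        if columns[i] != 0:
            continue  # negative column: kills a feature, creates none
        dim = _dim(s)
        if dim > max_dim:
            continue
        birth = complex.entries[s]
        j = death_of.get(i)
        if j is None:
            bars.append(PersistenceBar(dim, birth, ALPHA_MAX, censored=True))
        else:
            death = complex.entries[simplices[j]]
            if death > birth:
                bars.append(PersistenceBar(dim, birth, death))
    bars.sort(key=lambda b: (b.dimension, b.birth, b.death))
    return bars


@dataclass(frozen=True)
class BettiCurve:
    """Right-continuous step function: Betti number of one dimension over [0, 5).

    ``values[i]`` holds on ``[breakpoints[i], breakpoints[i+1])`` (the last
    value up to 5).
    """

    dimension: int
    breakpoints: tuple[float, ...]
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.values) or not self.breakpoints:
            raise ValueError("breakpoints and values must be non-empty and aligned")
        if self.breakpoints[0] != 0.0:
            raise ValueError("curve must start at alpha = 0")
        if any(b >= c for b, c in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    def at(self, alpha: float) -> int:
        if not 0.0 <= alpha < ALPHA_MAX:
            raise ValueError(f"alpha {alpha} outside [0, 5)")
        i = 0
        for j, b in enumerate(self.breakpoints):
            if b <= alpha:
                i = j
            else:
                break
        return self.values[i]

    def integral(self) -> float:
        """Exact integral over [0, 5) of the step function."""
        total = 0.0
        bps = list(self.breakpoints) + [ALPHA_MAX]
        for i, v in enumerate(self.values):
            total += v * (bps[i + 1] - bps[i])
        return total


def betti_curve(bars: Sequence[PersistenceBar], dimension: int) -> BettiCurve:
    """Betti curve of one dimension: bars alive at alpha (birth <= alpha < death)."""
    events: dict[float, int] = {0.0: 0}
    for bar in bars:
        if bar.dimension != dimension:
            continue
        events[bar.birth] = events.get(bar.birth, 0) + 1
        if not bar.censored and bar.death < ALPHA_MAX:
            events[bar.death] = events.get(bar.death, 0) - 1
    breakpoints = sorted(b for b in events if b < ALPHA_MAX)
    values, running = [], 0
    for b in breakpoints:
        running += events[b]
        values.append(running)
    return BettiCurve(dimension, tuple(breakpoints), tuple(values))


def betti_curves(
    bars: Sequence[PersistenceBar], max_dim: int
) -> list[BettiCurve]:
    """Betti curves for dimensions 0..max_dim (empty dimensions included)."""
    return [betti_curve(bars, d) for d in range(max_dim + 1)]


def _gf2_rank(columns: list[int]) -> int:
    """Rank of a GF(2) matrix given as bit-vector columns."""
    pivots: dict[int, int] = {}
    rank = 0
    for col in columns:
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                col ^= pivots[low]
            else:
                pivots[low] = col
                rank += 1
                break
    return rank


def betti_at(complex: FilteredComplex, alpha: float, dimension: int) -> int:
    """Betti number of the subcomplex at ``alpha`` via boundary-matrix ranks.

    ``beta_d = #C_d - rank(boundary_d) - rank(boundary_{d+1})`` over GF(2).
    Independent of the persistence reduction; serves as its oracle.
    """
    if not 0.0 <= alpha <= ALPHA_MAX:
        raise ValueError(f"alpha {alpha} outside [0, 5]")
    if dimension < 0:
        raise ValueError("dimension must be >= 0")
    present = [s for s, e in complex.entries.items() if e <= alpha]
    by_dim: dict[int, list[Simplex]] = {}
    for s in present:
        by_dim.setdefault(_dim(s), []).append(s)

    def boundary_rank(d: int) -> int:
        # rank of boundary map C_d -> C_{d-1}
        if d <= 0 or d not in by_dim or (d - 1) not in by_dim:
            return 0
        row_index = {s: i for i, s in enumerate(by_dim[d - 1])}
        cols = []
        for s in by_dim[d]:
            col = 0
            for face in _facets(s):
                col |= 1 << row_index[face]
            cols.append(col)
        return _gf2_rank(cols)

    n_d = len(by_dim.get(dimension, []))
    return n_d - boundary_rank(dimension) - boundary_rank(dimension + 1)


def euler_characteristic(complex: FilteredComplex, alpha: float) -> int:
    """Alternating sum of simplex counts of the subcomplex at ``alpha``."""
    chi = 0
    for s, e in complex.entries.items():
        if e <= alpha:
            chi += -1 if _dim(s) % 2 else 1
    return chi
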