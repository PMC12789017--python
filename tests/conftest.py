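"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the implementation paths they check:
homology ranks use dense numpy GF(2) elimination (the package uses bitset
columns), areas use Monte-Carlo point sampling, and subset enumeration is
unpruned brute force.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from shapely import contains_xy

from rangetopo.optimality import DEFAULT_MAPPING
from rangetopo.overlap import (
    CoreRange,
    OverlapRecord,
    OverlapTable,
    SQ_M_PER_HA,
    intersection_union_ratio,
)
from rangetopo.synthgen import gen_four_rectangle_fixture


def gf2_rank_dense(mat: np.ndarray) -> int:
    """Rank over GF(2) by dense Gaussian elimination (numpy, mod 2)."""
    a = (np.asarray(mat, dtype=np.int64) % 2).copy()
    rank = 0
    rows, cols = a.shape
    for c in range(cols):
        pivot = None
        for r in range(rank, rows):
            if a[r, c]:
                pivot = r
                break
        if pivot is None:
            continue
        a[[rank, pivot]] = a[[pivot, rank]]
        for r in range(rows):
            if r != rank and a[r, c]:
                a[r] ^= a[rank]
        rank += 1
    return rank


def betti_numbers_oracle(simplices: list[tuple[str, ...]]) -> dict[int, int]:
    """Betti numbers of an explicit simplex list, dense GF(2) ranks.

    Independent re-derivation: beta_d = #C_d - rank d_d - rank d_{d+1}.
    """
    by_dim: dict[int, list[tuple[str, ...]]] = {}
    for s in simplices:
        by_dim.setdefault(len(s) - 1, []).append(tuple(sorted(s)))

    def rank(d: int) -> int:
        if d <= 0 or d not in by_dim or (d - 1) not in by_dim:
            return 0
        rows = {s: i for i, s in enumerate(by_dim[d - 1])}
        mat = np.zeros((len(rows), len(by_dim[d])), dtype=np.int64)
        for j, s in enumerate(by_dim[d]):
            for i in range(len(s)):
                mat[rows[s[:i] + s[i + 1 :]], j] = 1
        return gf2_rank_dense(mat)

    max_d = max(by_dim) if by_dim else 0
    return {d: len(by_dim.get(d, [])) - rank(d) - rank(d + 1) for d in range(max_d + 1)}


def monte_carlo_area_ha(geometry, n_points: int, seed: int = 0) -> float:
    """Rasterised/point-sampling area estimate in hectares."""
    minx, miny, maxx, maxy = geometry.bounds
    rng = np.random.default_rng(seed)
    xs = rng.uniform(minx, maxx, n_points)
    ys = rng.uniform(miny, maxy, n_points)
    frac = contains_xy(geometry, xs, ys).mean()
    return frac * (maxx - minx) * (maxy - miny) / SQ_M_PER_HA


def brute_force_overlaps(
    ranges: list[CoreRange], n_max: int, eps_area: float
) -> OverlapTable:
    """Unpruned enumeration of every subset of size 2..n_max."""
    n_max = min(n_max, len(ranges))
    by_id = {r.individual_id: r.geometry for r in ranges}
    records = []
    for size in range(2, n_max + 1):
        for combo in itertools.combinations(sorted(by_id), size):
            inter_ha, union_ha, w = intersection_union_ratio([by_id[m] for m in combo])
            if inter_ha <= eps_area:
                continue
            records.append(
                OverlapRecord(
                    members=combo,
                    intersection_ha=inter_ha,
                    union_ha=union_ha,
                    w=w,
                    alpha=DEFAULT_MAPPING.alpha_from_w(w, size),
                )
            )
    return OverlapTable(records=records, n_max=n_max, eps_area=eps_area)


@pytest.fixture
def quartet_ranges() -> list[CoreRange]:
    return gen_four_rectangle_fixture()
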