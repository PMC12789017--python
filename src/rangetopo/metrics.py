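"""Barcode and complex summaries: complementarity index, simplicial centrality.

The filtration complementarity index (FCI) scores a barcode by averaging,
over the filtration interval [0, 5), the number of connected components per
individual plus the higher-dimensional Betti numbers weighted by ``d + 1``:

    FCI = < beta_0(alpha)/n  +  sum_{d>=1} (d+1) * beta_d(alpha) >_[0,5)

Maximal simplicial degree centrality generalises degree centrality to
simplicial complexes: the degree of a simplex is the number of facets
(maximal simplices) of which it is a face, a facet counting as a face of
itself.  With that convention a complex consisting of a single facet gives
every simplex degree 1 — downward closure introduces no bias towards higher
or lower order simplices.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .filtration import BettiCurve, FilteredComplex, Simplex
from .optimality import ALPHA_MAX

__all__ = [
    "FCIResult",
    "CentralityRecord",
    "SigmoidFit",
    "fci",
    "maximal_simplices",
    "maximal_degree_centrality",
    "centrality_by_size",
    "fit_sigmoid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FCIResult:
    value: float
    n_individuals: int
    season: str | None = None


def fci(
    betti_curves: Sequence[BettiCurve],
    n_individuals: int,
    season: str | None = None,
) -> FCIResult:
    """Filtration complementarity index from a set of Betti curves.

    Computed as the exact integral of the step functions divided by the
    interval length 5 — no numerical quadrature.  The dimension-0 curve must
    be present (components are scaled by ``n_individuals`` so larger groups
    do not score higher automatically); higher dimensions are weighted by
    ``d + 1``, dimensions without features contribute 0.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    dims = {c.dimension for c in betti_curves}
    if 0 not in dims:
        raise ValueError("a dimension-0 Betti curve is required")
    if len(dims) != len(betti_curves):
        raise ValueError("duplicate dimensions among Betti curves")
    total = 0.0
    for curve in betti_curves:
        if curve.dimension == 0:
            total += curve.integral() / n_individuals
        else:
            total += (curve.dimension + 1) * curve.integral()
    return FCIResult(value=total / ALPHA_MAX, n_individuals=n_individuals, season=season)


@dataclass(frozen=True)
class CentralityRecord:
    """Maximal simplicial degree of one simplex, with optional metadata."""

    simplex: Simplex
    size: int
    degree: int
    metadata: dict | None = None


def maximal_simplices(complex: FilteredComplex, alpha: float) -> list[Simplex]:
    """Facets of the subcomplex at ``alpha``: simplices not properly contained
    in any other included simplex."""
    present = [frozenset(s) for s in complex.simplices_at(alpha)]
    present_sets = sorted(present, key=len, reverse=True)
    facets: list[frozenset] = []
    for s in present_sets:
        if not any(s < f for f in facets):
            facets.append(s)
    return sorted(tuple(sorted(f)) for f in facets)


def maximal_degree_centrality(
    complex: FilteredComplex, alpha: float = 4.0
) -> list[CentralityRecord]:
    """Maximal simplicial degree of every simplex in the subcomplex at ``alpha``.

    ``degree(sigma)`` = number of facets of the subcomplex having ``sigma``
    as a face (self-inclusive).  The default ``alpha = 4`` keeps only subsets
    at least as redundant as the theoretical optimum.
    """
    simplices = complex.simplices_at(alpha)
    if not simplices:
        logger.warning("subcomplex at alpha=%s is empty; no centrality records", alpha)
        warnings.warn("empty subcomplex: no centrality records", stacklevel=2)
        return []
    facet_sets = [frozenset(f) for f in maximal_simplices(complex, alpha)]
    records = []
    for s in sorted(simplices, key=lambda s: (len(s), s)):
        sset = frozenset(s)
        degree = sum(1 for f in facet_sets if sset <= f)
        records.append(CentralityRecord(simplex=s, size=len(s), degree=degree))
    return records


def centrality_by_size(records: Sequence[CentralityRecord]) -> pd.DataFrame:
    """Per-size summary of centrality degrees: count, mean, sd, min, max."""
    if not records:
        raise ValueError("no centrality records to summarise")
    df = pd.DataFrame({"size": [r.size for r in records], "degree": [r.degree for r in records]})
    out = (
        df.groupby("size")["degree"]
        .agg(count="count", mean="mean", sd="std", min="min", max="max")
        .reset_index()
        .sort_values("size", ignore_index=True)
    )
    return out


@dataclass(frozen=True)
class SigmoidFit:
    """Descriptive logistic fit ``c(s) = L / (1 + exp(-k (s - s0)))``."""

    L: float
    k: float
    s0: float
    converged: bool
    sse: float

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.L, self.k, self.s0)


def _logistic(s: np.ndarray, L: float, k: float, s0: float) -> np.ndarray:
    return L / (1.0 + np.exp(-k * (s - s0)))


def fit_sigmoid(size_degree_pairs: Sequence[tuple[float, float]]) -> SigmoidFit:
    """Non-linear least-squares logistic fit of degree against simplex size.

    Requires at least 4 distinct sizes.  Non-convergence is reported in the
    result, never raised; a flat (k = 0) logistic reproducing the sample
    mean is always considered as a fallback candidate, so the returned fit
    is never worse than the best constant model.
    """
    pairs = [(float(s), float(d)) for s, d in size_degree_pairs]
    if len({s for s, _ in pairs}) < 4:
        raise ValueError("need at least 4 distinct sizes for a sigmoid fit")
    x = np.array([s for s, _ in pairs])
    y = np.array([d for _, d in pairs])

    mean = float(np.mean(y))
    # k = 0 makes the logistic the constant L/2: exact best constant model
    candidates = [SigmoidFit(2.0 * mean, 0.0, float(np.median(x)), False,
                             float(np.sum((y - mean) ** 2)))]
    starts = [
        (max(y.max(), 1e-6), 1.0, float(np.median(x))),
        (max(2.0 * y.max(), 1e-6), 0.5, float(np.mean(x))),
        (max(y.max(), 1e-6), 2.0, float(np.quantile(x, 0.75))),
    ]
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_logistic, x, y, p0=p0, maxfev=20_000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _logistic(x, *popt)) ** 2))
        if np.isfinite(sse):
            candidates.append(SigmoidFit(float(popt[0]), float(popt[1]), float(popt[2]), True, sse))
    best = min(candidates, key=lambda c: c.sse)
    return best
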