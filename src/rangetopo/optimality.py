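"""Optimal overlap theory and the mapping between overlap ratio and filtration index.

For a set of ``n`` individuals sharing space, the intersection/union ratio
that best balances redundant meeting opportunity against unique shareable
knowledge is ``w* = 1/(n + 1)``.  The filtration index ``alpha`` measures how
far an observed ratio ``w`` is from that optimum, via

    w = f(alpha) * w*_n = f(alpha) / (n + 1)

with ``f`` a positive, strictly decreasing function on ``[0, 5)``.  The
default is the linear ``f(alpha) = 5 - alpha``, so that every non-zero
overlap enters the filtration at some ``alpha > 0`` and zero overlaps sit at
the (excluded) endpoint ``alpha = 5``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ALPHA_MAX",
    "AlphaMapping",
    "DEFAULT_MAPPING",
    "optimal_overlap",
    "transfer_objective",
    "alpha_from_w",
    "w_from_alpha",
]

#: Upper end of the (half-open) filtration interval.
ALPHA_MAX = 5.0


def optimal_overlap(n: int) -> float:
    """Optimal intersection/union ratio ``1 / (n + 1)`` for ``n`` individuals.

    Strictly decreasing and convex in ``n``.

    Parameters
    ----------
    n
        Number of individuals in the subset, ``n >= 1``.
    """
    if n < 1:
        raise ValueError(f"subset size must be >= 1, got {n}")
    return 1.0 / (n + 1)


def transfer_objective(w: float, n: int) -> float:
    """Information-transfer score ``w * (1 - w)**n`` for an overlap ratio.

    The redundant fraction ``w`` is proportional to the opportunity the
    members have to meet; each member's unique fraction ``1 - w`` is
    proportional to what it can share once they do.  The product vanishes at
    both extremes and has a unique interior maximum at ``w = 1/(n + 1)``,
    i.e. at :func:`optimal_overlap`.

    This closed form is a stand-in consistent with the optimum; it is
    descriptive, not a fitted model.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"overlap ratio must lie in [0, 1], got {w}")
    if n < 1:
        raise ValueError(f"subset size must be >= 1, got {n}")
    return w * (1.0 - w) ** n


@dataclass(frozen=True)
class AlphaMapping:
    """Linear scaling function ``f(alpha) = f_intercept + f_slope * alpha``.

    The default ``f(alpha) = 5 - alpha`` is positive and strictly decreasing
    on ``[0, 5)`` with ``f(5) = 0``.  The function is carried explicitly so a
    different (still linear, decreasing) choice can be swapped in: this moves
    entry values along the axis but preserves their order, hence the
    topological features of any filtration built from them.
    """

    f_intercept: float = ALPHA_MAX
    f_slope: float = -1.0

    def __post_init__(self) -> None:
        if self.f_slope >= 0:
            raise ValueError("f must be strictly decreasing (f_slope < 0)")
        if self.f_intercept <= 0:
            raise ValueError("f must be positive at alpha = 0")

    @property
    def alpha_max(self) -> float:
        """The root of ``f``; upper end of the filtration interval."""
        return -self.f_intercept / self.f_slope

    def f(self, alpha: float) -> float:
        return self.f_intercept + self.f_slope * alpha

    def alpha_from_w(self, w: float, n: int) -> float:
        """Solve ``w = f(alpha) / (n + 1)`` for ``alpha``.

        The result must land in ``(0, alpha_max]``; ``alpha = alpha_max``
        only when ``w = 0``.  Inputs implying ``alpha <= 0`` are rejected:
        each simplex must enter the filtration at ``alpha > 0`` so that the
        filtration starts from a structure of vertices only.
        """
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"overlap ratio must lie in [0, 1], got {w}")
        if n < 1:
            raise ValueError(f"subset size must be >= 1, got {n}")
        alpha = (w * (n + 1) - self.f_intercept) / self.f_slope
        if alpha <= 0.0:
            raise ValueError(
                f"w={w} with n={n} implies alpha={alpha:.6g} <= 0; "
                "each simplex must have alpha > 0"
            )
        return alpha

    def w_from_alpha(self, alpha: float, n: int) -> float:
        """Inverse of :meth:`alpha_from_w`: ``w = f(alpha) / (n + 1)``.

        Clamped to ``[0, 1]``.
        """
        if not 0.0 <= alpha <= self.alpha_max:
            raise ValueError(
                f"alpha must lie in [0, {self.alpha_max}], got {alpha}"
            )
        if n < 1:
            raise ValueError(f"subset size must be >= 1, got {n}")
        w = self.f(alpha) / (n + 1)
        return min(max(w, 0.0), 1.0)


#: Module-wide default mapping, f(alpha) = 5 - alpha on [0, 5).
DEFAULT_MAPPING = AlphaMapping()


def alpha_from_w(w: float, n: int, mapping: AlphaMapping = DEFAULT_MAPPING) -> float:
    """Filtration index of a subset of size ``n`` with overlap ratio ``w``."""
    return mapping.alpha_from_w(w, n)


def w_from_alpha(alpha: float, n: int, mapping: AlphaMapping = DEFAULT_MAPPING) -> float:
    """Overlap ratio mapped to by filtration index ``alpha`` at subset size ``n``."""
    return mapping.w_from_alpha(alpha, n)
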