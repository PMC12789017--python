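import itertools

import numpy as np
import pytest

from rangetopo.filtration import (
    BettiCurve,
    FilteredComplex,
    PersistenceBar,
    assign_entry_values,
    betti_curve,
    betti_curves,
    compute_persistence,
)
from rangetopo.metrics import (
    centrality_by_size,
    fci,
    fit_sigmoid,
    maximal_degree_centrality,
    maximal_simplices,
)
from rangetopo.synthgen import gen_patch_table, gen_ring_fixture, overlap_table_from_fixture


def _complex_from_simplices(simplices, alpha=1.0, n_max=6):
    entries = {}
    for s in simplices:
        s = tuple(sorted(s))
        for size in range(1, len(s) + 1):
            for face in itertools.combinations(s, size):
                entry = 0.0 if size == 1 else alpha
                entries[face] = min(entries.get(face, 5.0 - 1e-9), entry)
    return FilteredComplex(entries=entries, n_max=n_max)


def _riemann_fci(bars, n_individuals, max_dim, step=1e-4):
    """Left-endpoint Riemann oracle; exact when breakpoints sit on the grid."""
    grid = np.arange(0.0, 5.0, step)
    total = np.zeros_like(grid)
    for d in range(max_dim + 1):
        alive = np.zeros_like(grid)
        for b in bars:
            if b.dimension != d:
                continue
            alive += (grid >= b.birth) & (grid < b.death)
        total += alive / n_individuals if d == 0 else (d + 1) * alive
    return float(total.sum() * step / 5.0)


class TestFCI:
    def test_constant_component(self):
        curves = [BettiCurve(0, (0.0,), (1,))]
        assert fci(curves, n_individuals=1).value == pytest.approx(1.0)

    def test_component_plus_loop(self):
        bars = [
            PersistenceBar(0, 0.0, 5.0, censored=True),
            PersistenceBar(1, 2.0, 4.0),
        ]
        curves = betti_curves(bars, max_dim=1)
        # beta0/4 contributes 1/4; the loop contributes 2 * (2/5)
        assert fci(curves, n_individuals=4).value == pytest.approx(1.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_riemann_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bars = []
        for _ in range(12):
            d = int(rng.integers(0, 4))
            # breakpoints on the 1e-4 grid make the Riemann sum exact
            birth = round(float(rng.uniform(0, 4.5)), 4)
            death = round(float(rng.uniform(birth + 0.01, 5.0)), 4)
            censored = death >= 5.0
            bars.append(PersistenceBar(d, birth, min(death, 5.0), censored=censored))
        curves = betti_curves(bars, max_dim=3)
        value = fci(curves, n_individuals=5).value
        assert value == pytest.approx(_riemann_fci(bars, 5, 3), abs=1e-6)

    def test_missing_dim0_curve_rejected(self):
        with pytest.raises(ValueError, match="dimension-0"):
            fci([BettiCurve(1, (0.0,), (0,))], n_individuals=3)

    def test_invariant_to_bar_order(self):
        bars = [
            PersistenceBar(0, 0.0, 5.0, censored=True),
            PersistenceBar(1, 1.0, 3.0),
            PersistenceBar(2, 2.0, 4.0),
        ]
        a = fci(betti_curves(bars, 2), 3).value
        b = fci(betti_curves(list(reversed(bars)), 2), 3).value
        assert a == pytest.approx(b)

    def test_additive_over_disjoint_bar_sets(self):
        base = [PersistenceBar(0, 0.0, 5.0, censored=True)]
        extra = [PersistenceBar(1, 1.0, 2.0), PersistenceBar(2, 0.5, 3.0)]
        v_base = fci(betti_curves(base, 2), 4).value
        v_extra_alone = fci(betti_curves(extra, 2), 4).value
        v_joint = fci(betti_curves(base + extra, 2), 4).value
        # dim >= 1 bars contribute independently of the components
        assert v_joint == pytest.approx(v_base + v_extra_alone)

    def test_removing_higher_bar_never_increases(self):
        bars = [
            PersistenceBar(0, 0.0, 5.0, censored=True),
            PersistenceBar(1, 1.0, 4.0),
            PersistenceBar(2, 2.0, 3.0),
        ]
        full = fci(betti_curves(bars, 2), 2).value
        for drop in (1, 2):
            reduced = fci(betti_curves(bars[:drop] + bars[drop + 1 :], 2), 2).value
            assert reduced <= full

    def test_lengthening_bar_never_decreases(self):
        short = [PersistenceBar(0, 0.0, 5.0, censored=True), PersistenceBar(1, 2.0, 3.0)]
        long = [PersistenceBar(0, 0.0, 5.0, censored=True), PersistenceBar(1, 2.0, 4.5)]
        assert fci(betti_curves(long, 1), 2).value >= fci(betti_curves(short, 1), 2).value


class TestMaximalSimplices:
    def test_single_triangle(self):
        cx = _complex_from_simplices([("A", "B", "C")])
        assert maximal_simplices(cx, 2.0) == [("A", "B", "C")]

    def test_triangle_plus_edge(self):
        cx = _complex_from_simplices([("A", "B", "C"), ("C", "D")])
        assert maximal_simplices(cx, 2.0) == [("A", "B", "C"), ("C", "D")]

    def test_respects_alpha(self):
        cx = _complex_from_simplices([("A", "B")], alpha=3.0)
        assert maximal_simplices(cx, 1.0) == [("A",), ("B",)]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_containment_scan(self, seed):
        table = gen_patch_table(n_vertices=6, n_max=4, seed=seed)
        cx = assign_entry_values(table)
        alpha = 4.5
        present = [frozenset(s) for s in cx.simplices_at(alpha)]
        oracle = sorted(
            tuple(sorted(s))
            for s in present
            if not any(s < t for t in present)  # O(m^2) scan
        )
        assert maximal_simplices(cx, alpha) == oracle


class TestMaximalDegreeCentrality:
    def test_triangle_plus_edge_degrees(self):
        cx = _complex_from_simplices([("A", "B", "C"), ("C", "D")])
        degree = {r.simplex: r.degree for r in maximal_degree_centrality(cx, 2.0)}
        assert degree[("C",)] == 2
        assert degree[("A", "B")] == 1
        assert degree[("C", "D")] == 1
        assert degree[("A", "B", "C")] == 1

    def test_single_facet_all_degrees_one(self):
        cx = _complex_from_simplices([("A", "B", "C", "D")])
        records = maximal_degree_centrality(cx, 2.0)
        assert len(records) == 15  # all nonempty faces
        assert all(r.degree == 1 for r in records)

    def test_disjoint_edges(self):
        cx = _complex_from_simplices([("A", "B"), ("C", "D")])
        records = maximal_degree_centrality(cx, 2.0)
        assert all(r.degree == 1 for r in records)

    def test_ring_fixture_degrees(self):
        table = overlap_table_from_fixture(gen_ring_fixture(4, 0.3))
        cx = assign_entry_values(table)
        records = maximal_degree_centrality(cx, alpha=4.99)
        degree = {r.simplex: r.degree for r in records}
        for r in records:
            assert r.degree == (2 if r.size == 1 else 1)
        assert sum(1 for s in degree if len(s) == 2) == 4

    def test_empty_complex_warns(self):
        cx = FilteredComplex(entries={}, n_max=3)
        with pytest.warns(UserWarning, match="empty"):
            assert maximal_degree_centrality(cx, 2.0) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_under_vertex_relabelling(self, seed):
        table = gen_patch_table(n_vertices=6, n_max=4, seed=seed)
        cx = assign_entry_values(table)
        rng = np.random.default_rng(seed)
        ids = cx.vertices
        relabel = dict(zip(ids, rng.permutation([f"x{i}" for i in range(len(ids))])))
        remapped = FilteredComplex(
            entries={
                tuple(sorted(relabel[v] for v in s)): e for s, e in cx.entries.items()
            },
            n_max=cx.n_max,
        )
        original = sorted(
            (r.size, r.degree) for r in maximal_degree_centrality(cx, 4.0)
        )
        permuted = sorted(
            (r.size, r.degree) for r in maximal_degree_centrality(remapped, 4.0)
        )
        assert original == permuted


class TestCentralityBySize:
    def test_single_facet_means_are_one(self):
        cx = _complex_from_simplices([("A", "B", "C", "D")])
        summary = centrality_by_size(maximal_degree_centrality(cx, 2.0))
        assert (summary["mean"] == 1.0).all()
        assert list(summary["size"]) == [1, 2, 3, 4]

    def test_counts_conserved(self):
        cx = _complex_from_simplices([("A", "B", "C"), ("C", "D"), ("D", "E")])
        records = maximal_degree_centrality(cx, 2.0)
        summary = centrality_by_size(records)
        assert summary["count"].sum() == len(records)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            centrality_by_size([])


class TestFitSigmoid:
    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(0)
        sizes = np.repeat(np.arange(1, 10), 8)
        true = 30.0 / (1.0 + np.exp(-1.2 * (sizes - 4.0)))
        degrees = true + rng.normal(0.0, 0.5, sizes.size)
        fit = fit_sigmoid(list(zip(sizes, degrees)))
        assert fit.converged
        assert fit.L == pytest.approx(30.0, rel=0.10)
        assert fit.k == pytest.approx(1.2, rel=0.10)
        assert fit.s0 == pytest.approx(4.0, rel=0.10)

    def test_constant_data_degenerate(self):
        pairs = [(s, 3.0) for s in range(1, 8)]
        fit = fit_sigmoid(pairs)
        # flat data: either the slope collapses or the fit is flagged
        assert abs(fit.k) < 1e-3 or not fit.converged
        assert fit.sse == pytest.approx(0.0, abs=1e-9)

    def test_never_worse_than_constant_model(self):
        rng = np.random.default_rng(5)
        pairs = [(s, float(rng.uniform(0, 10))) for s in range(1, 9)]
        fit = fit_sigmoid(pairs)
        y = np.array([d for _, d in pairs])
        sse_const = float(np.sum((y - y.mean()) ** 2))
        assert fit.sse <= sse_const + 1e-9

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([(1, 1.0), (2, 2.0), (3, 3.0)])
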