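"""Rips filtration construction and persistent-homology computation,
cross-checked between the boundary-matrix reduction and the MST shortcut."""

import math

import numpy as np
import pytest

from persnet import (
    Filtration,
    Simplex,
    betti_at,
    build_rips_filtration,
    h0_via_mst,
    reduce_boundary_matrix,
)
from persnet.distances import bottleneck_distance

from _oracles import random_dissimilarity


def h0_deaths(diagram):
    return np.sort(diagram.points(0)[:, 1])


class TestRipsFiltration:
    def test_triangle_value_is_max_of_edges(self):
        D = np.array([[0, 0.2, 0.4], [0.2, 0, 0.3], [0.4, 0.3, 0]])
        filt = build_rips_filtration(D, max_dim=2)
        (tri,) = [s for s in filt.simplices if s.dimension == 2]
        assert tri.value == pytest.approx(0.4)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_complex_counts(self, n):
        rng = np.random.default_rng(n)
        filt = build_rips_filtration(random_dissimilarity(rng, n), max_dim=2)
        counts = np.bincount([s.dimension for s in filt.simplices], minlength=3)
        assert counts[0] == n
        assert counts[1] == n * (n - 1) // 2
        assert counts[2] == n * (n - 1) * (n - 2) // 6

    def test_unit_square_enumeration(self, unit_square):
        filt = build_rips_filtration(unit_square, max_dim=2)
        values = {}
        for s in filt.simplices:
            values.setdefault(s.dimension, []).append(s.value)
        assert values[0] == [0.0] * 4
        assert sorted(values[1]) == pytest.approx([1, 1, 1, 1] + [math.sqrt(2)] * 2)
        assert values[2] == pytest.approx([math.sqrt(2)] * 4)
        filt.validate()  # ordering and face-precedence invariants hold

    def test_max_value_truncates(self, unit_square):
        filt = build_rips_filtration(unit_square, max_dim=2, max_value=1.0)
        assert all(s.value <= 1.0 for s in filt.simplices)
        assert sum(s.dimension == 2 for s in filt.simplices) == 0

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            build_rips_filtration(np.array([[0, 1.0], [0.5, 0]]))

    def test_simplex_vertices_must_increase(self):
        with pytest.raises(ValueError):
            Simplex((2, 1), 0.5)


class TestBoundaryReduction:
    def test_single_point(self):
        diagram = reduce_boundary_matrix(build_rips_filtration(np.zeros((1, 1))))
        assert len(diagram.pairs) == 1
        (pair,) = diagram.pairs
        assert pair.dimension == 0 and pair.essential

    def test_two_points_single_merge(self):
        D = np.array([[0, 0.3], [0.3, 0]])
        diagram = reduce_boundary_matrix(build_rips_filtration(D))
        assert h0_deaths(diagram).tolist() == [0.3]
        assert sum(p.essential for p in diagram.pairs) == 1
        assert diagram.points(1).size == 0

    def test_unit_square_diagram(self, unit_square):
        diagram = reduce_boundary_matrix(build_rips_filtration(unit_square, max_dim=2))
        h1 = diagram.points(1)
        assert h1.shape == (1, 2)
        assert h1[0].tolist() == pytest.approx([1.0, math.sqrt(2)])
        assert h0_deaths(diagram).tolist() == pytest.approx([1.0, 1.0, 1.0])
        assert sum(p.essential and p.dimension == 0 for p in diagram.pairs) == 1

    def test_face_order_violation_raises_not_reorders(self):
        bad = Filtration(
            simplices=[Simplex((0, 1), 0.5), Simplex((0,), 0.0), Simplex((1,), 0.0)],
            n_vertices=2,
        )
        with pytest.raises(ValueError):
            reduce_boundary_matrix(bad)

    def test_truncated_filtration_leaves_essential_loops(self, unit_square):
        # cutting the filtration below sqrt(2) removes the triangles that
        # would kill the square's loop, leaving an essential H1 class
        filt = build_rips_filtration(unit_square, max_dim=2, max_value=1.2)
        diagram = reduce_boundary_matrix(filt)
        h1 = diagram.in_dimension(1)
        assert len(h1) == 1 and h1[0].essential and h1[0].birth == pytest.approx(1.0)


class TestH0ViaMst:
    def test_kruskal_hand_example(self):
        D = np.array([[0, 0.2, 0.5], [0.2, 0, 0.4], [0.5, 0.4, 0]])
        assert h0_deaths(h0_via_mst(D)).tolist() == pytest.approx([0.2, 0.4])

    def test_equidistant_points_merge_simultaneously(self):
        n, c = 6, 0.7
        D = np.full((n, n), c)
        np.fill_diagonal(D, 0.0)
        deaths = h0_deaths(h0_via_mst(D))
        assert deaths.tolist() == pytest.approx([c] * (n - 1))

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_boundary_reduction_on_random_matrices(self, trial):
        rng = np.random.default_rng(1000 + trial)
        D = random_dissimilarity(rng, 12)
        fast = h0_via_mst(D)
        full = reduce_boundary_matrix(build_rips_filtration(D, max_dim=1))
        assert np.allclose(h0_deaths(fast), h0_deaths(full), atol=1e-12)
        assert sum(p.essential for p in fast.pairs) == sum(
            p.essential and p.dimension == 0 for p in full.pairs
        )


class TestBettiNumbers:
    def test_unit_square_profile(self, unit_square):
        diagram = reduce_boundary_matrix(build_rips_filtration(unit_square, max_dim=2))
        assert betti_at(diagram, 0.0) == (4, 0)
        assert betti_at(diagram, 1.2) == (1, 1)  # one component, one open loop
        assert betti_at(diagram, 2.0) == (1, 0)

    def test_threshold_zero_counts_all_components(self):
        rng = np.random.default_rng(5)
        D = random_dissimilarity(rng, 9) + 0.05  # strictly positive off-diagonal
        np.fill_diagonal(D, 0.0)
        assert betti_at(h0_via_mst(D), 0.0) == (9, 0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            betti_at(h0_via_mst(np.zeros((2, 2))), -0.1)


class TestDiagramInvariants:
    @pytest.mark.parametrize("trial", range(10))
    def test_monotone_relabeling_maps_births_and_deaths(self, trial):
        rng = np.random.default_rng(200 + trial)
        D = random_dissimilarity(rng, 8)
        base = reduce_boundary_matrix(build_rips_filtration(D, max_dim=2))
        mapped = reduce_boundary_matrix(build_rips_filtration(D**2, max_dim=2))
        for dim in (0, 1):
            assert np.allclose(
                np.sort(mapped.points(dim), axis=0),
                np.sort(base.points(dim) ** 2, axis=0),
                atol=1e-12,
            )

    @pytest.mark.parametrize("trial", range(10))
    def test_vertex_permutation_invariance(self, trial):
        rng = np.random.default_rng(300 + trial)
        D = random_dissimilarity(rng, 9)
        perm = rng.permutation(9)
        base = reduce_boundary_matrix(build_rips_filtration(D, max_dim=2))
        shuffled = reduce_boundary_matrix(
            build_rips_filtration(D[np.ix_(perm, perm)], max_dim=2)
        )
        for dim in (0, 1):
            assert np.allclose(
                np.sort(base.points(dim), axis=0),
                np.sort(shuffled.points(dim), axis=0),
                atol=1e-12,
            )

    def test_generic_matrix_has_full_h0_pairing(self):
        rng = np.random.default_rng(8)
        n = 11
        D = random_dissimilarity(rng, n)
        diagram = reduce_boundary_matrix(build_rips_filtration(D, max_dim=2))
        h0 = diagram.in_dimension(0)
        assert len(h0) == n  # n-1 finite merges plus one essential component
        assert sum(p.essential for p in h0) == 1
        assert all(p.birth == 0.0 for p in h0)

    @pytest.mark.parametrize("delta", [0.01, 0.05])
    def test_stability_under_entrywise_perturbation(self, delta):
        # perturbing D entrywise by <= delta moves each diagram by <= delta
        # in bottleneck distance (diagram stability for Rips filtrations)
        rng = np.random.default_rng(400)
        for _ in range(10):
            D = random_dissimilarity(rng, 8)
            noise = rng.uniform(-delta, delta, D.shape)
            noise = (noise + noise.T) / 2.0
            P = np.clip(D + noise, 0.0, None)
            np.fill_diagonal(P, 0.0)
            a = reduce_boundary_matrix(build_rips_filtration(D, max_dim=2))
            b = reduce_boundary_matrix(build_rips_filtration(P, max_dim=2))
            for dim in (0, 1):
                assert bottleneck_distance(a, b, dim) <= delta + 1e-9
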