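"""Vietoris-Rips construction, persistence reduction, Euler curves."""

import math

import numpy as np
import pytest

from helpers import betti_bruteforce, random_weight_matrix

from topoeeg import (FilteredComplex, VietorisRipsPersistence, betti_curves,
                     euler_curve, persistence, phase_transition_point,
                     vietoris_rips)


def hexagon_complex():
    """6-cycle with edge weights 0.1..0.6, chords at 0.9."""
    w = np.full((6, 6), 0.9)
    np.fill_diagonal(w, 0.0)
    for k in range(6):
        i, j = k, (k + 1) % 6
        w[i, j] = w[j, i] = 0.1 * (k + 1)
    return vietoris_rips(w)


class TestVietorisRips:
    def test_triangle_counts_and_entry_scale(self):
        w = np.full((3, 3), 0.4)
        np.fill_diagonal(w, 0.0)
        cx = vietoris_rips(w)
        assert cx.n_simplices == 7  # 3 vertices + 3 edges + 1 triangle
        assert cx.values[2][0] == pytest.approx(0.4)

    def test_simplex_count_for_19_vertices(self):
        w = random_weight_matrix(19, np.random.default_rng(0))
        cx = vietoris_rips(w, max_dim=3)
        assert cx.n_simplices == 19 + 171 + 969 + 3876  # == 5035

    def test_unit_weights_put_everything_at_one(self):
        w = np.ones((4, 4)) - np.eye(4)
        cx = vietoris_rips(w)
        assert np.all(cx.values[0] == 0.0)
        for d in (1, 2, 3):
            assert np.all(cx.values[d] == 1.0)

    def test_value_is_max_pairwise_weight(self, rng):
        w = random_weight_matrix(6, rng)
        cx = vietoris_rips(w)
        for row, val in zip(cx.simplices[2], cx.values[2]):
            i, j, k = row
            assert val == pytest.approx(max(w[i, j], w[i, k], w[j, k]))

    def test_face_closure_of_construction(self, rng):
        vietoris_rips(random_weight_matrix(7, rng)).validate_faces()

    def test_simplex_cap(self):
        w = random_weight_matrix(19, np.random.default_rng(0))
        with pytest.raises(ValueError, match="cap"):
            vietoris_rips(w, max_simplices=100)

    @pytest.mark.parametrize("bad", [
        np.ones((3, 3)),                        # nonzero diagonal
        np.array([[0.0, 1.0], [0.5, 0.0]]),     # asymmetric
    ])
    def test_invalid_matrix_rejected(self, bad):
        with pytest.raises(ValueError):
            vietoris_rips(bad)


class TestPersistenceFixtures:
    def test_hollow_triangle_is_a_circle(self):
        cx = FilteredComplex.from_simplices(
            [((0,), 0.0), ((1,), 0.0), ((2,), 0.0),
             ((0, 1), 0.3), ((1, 2), 0.3), ((0, 2), 0.3)])
        bc = persistence(cx)
        dim0 = sorted((b.birth, b.death) for b in bc.bars if b.dim == 0)
        assert dim0 == [(0.0, 0.3), (0.0, 0.3), (0.0, math.inf)]
        dim1 = [(b.birth, b.death) for b in bc.bars if b.dim == 1]
        assert dim1 == [(0.3, math.inf)]

    def test_tetrahedron_boundary_is_a_sphere(self):
        import itertools
        simp = [((i,), 0.0) for i in range(4)]
        simp += [(e, 0.2) for e in itertools.combinations(range(4), 2)]
        simp += [(t, 0.5) for t in itertools.combinations(range(4), 3)]
        bc = persistence(FilteredComplex.from_simplices(simp))
        assert bc.n_essential(0) == 1
        assert bc.n_essential(1) == 0
        assert bc.n_essential(2) == 1

    def test_non_face_closed_rejected(self):
        cx = FilteredComplex.from_simplices([((0,), 0.0), ((0, 1), 0.5)])
        with pytest.raises(ValueError, match="face"):
            persistence(cx)

    def test_face_entering_late_rejected(self):
        cx = FilteredComplex.from_simplices(
            [((0,), 0.0), ((1,), 0.0), ((0, 1), 0.2), ((2,), 0.0),
             ((0, 2), 0.9), ((1, 2), 0.9), ((0, 1, 2), 0.5)])
        with pytest.raises(ValueError, match="enters after"):
            persistence(cx)


class TestOracleEquivalence:
    """Reduction-derived Betti curves vs direct boundary-rank computation."""

    @pytest.mark.parametrize("seed", range(10))
    def test_random_complexes_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(4, 9))
        cx = vietoris_rips(random_weight_matrix(m, rng))
        bc = persistence(cx, check_faces=False)
        grid = np.unique(np.concatenate(list(cx.values.values())))
        curves = betti_curves(bc, grid)
        for i, eps in enumerate(grid):
            ref = betti_bruteforce(cx, eps)
            for d in (0, 1, 2):
                assert curves[d][i] == ref.get(d, 0), (seed, eps, d)

    @pytest.mark.parametrize("seed", range(10))
    def test_euler_poincare_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        cx = vietoris_rips(random_weight_matrix(int(rng.integers(4, 9)), rng))
        bc = persistence(cx, check_faces=False)
        ec = euler_curve(cx)
        curves = betti_curves(bc, ec.grid)
        alternating = curves[0] - curves[1] + curves[2] - curves[3]
        np.testing.assert_array_equal(ec.chi, alternating)

    def test_beta0_non_increasing(self, rng):
        cx = vietoris_rips(random_weight_matrix(8, rng))
        bc = persistence(cx, check_faces=False)
        grid = np.unique(np.concatenate(list(cx.values.values())))
        b0 = betti_curves(bc, grid)[0]
        assert np.all(np.diff(b0) <= 0)

    def test_barcode_invariant_under_vertex_relabeling(self, rng):
        w = random_weight_matrix(7, rng)
        perm = rng.permutation(7)
        bars = lambda wm: sorted(
            (b.dim, round(b.birth, 12), round(b.death, 12))
            for b in persistence(vietoris_rips(wm), check_faces=False).bars)
        assert bars(w) == bars(w[np.ix_(perm, perm)])


class TestBettiCurves:
    def test_essential_bar_counts_forever(self):
        from topoeeg.topology import Bar, BarcodeSet
        bc = BarcodeSet([Bar(0, 0.0, math.inf)], 1.0)
        np.testing.assert_array_equal(
            betti_curves(bc, [0.0, 0.5, 1.0])[0], [1, 1, 1])

    def test_half_open_convention(self):
        from topoeeg.topology import Bar, BarcodeSet
        bc = BarcodeSet([Bar(1, 0.2, 0.5)], 1.0)
        curve = betti_curves(bc, [0.1, 0.2, 0.4, 0.5])[1]
        np.testing.assert_array_equal(curve, [0, 1, 1, 0])


class TestEulerCurve:
    def test_hexagon_chi_decrements_to_zero(self):
        cx = hexagon_complex()
        ec = euler_curve(cx)
        # chi = 6 below the first edge, then 6 - k after k cycle edges
        assert ec.chi[np.searchsorted(ec.grid, 0.0)] == 6
        for k in range(1, 7):
            idx = np.searchsorted(ec.grid, 0.1 * k)
            assert ec.chi[idx] == 6 - k
        idx6 = np.searchsorted(ec.grid, 0.6)
        assert ec.entropy[idx6] == -np.inf
        assert ec.transition_point == pytest.approx(0.6)

    def test_isolated_vertices_entropy(self):
        cx = hexagon_complex()
        ec = euler_curve(cx, grid=np.array([0.0, 0.05]))
        assert ec.chi[0] == 6
        assert ec.entropy[0] == pytest.approx(math.log(6))

    def test_full_four_vertex_complex_chi_one(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        ec = euler_curve(vietoris_rips(w))
        assert ec.chi[-1] == 4 - 6 + 4 - 1 == 1


class TestPhaseTransition:
    def test_two_vertices_transition_at_edge_weight(self):
        w = np.array([[0.0, 0.7], [0.7, 0.0]])
        ec = euler_curve(vietoris_rips(w))
        # chi: 2 -> 1; S dips from ln 2 to 0 at the edge weight
        assert ec.transition_point == pytest.approx(0.7)

    def test_all_equal_weights_single_jump(self):
        # one jump at the common weight; S dips there (ln 3 -> ln 1)
        w = np.full((3, 3), 0.4)
        np.fill_diagonal(w, 0.0)
        ec = euler_curve(vietoris_rips(w))
        assert ec.transition_point == pytest.approx(0.4)

    def test_no_dip_returns_none(self):
        from topoeeg.topology import EulerCurve
        curve = EulerCurve(np.array([0.0, 0.5]), np.array([3, 5]))
        assert curve.transition_point is None

    def test_first_zero_rule(self):
        cx = hexagon_complex()
        assert euler_curve(cx, transition_rule="first-zero").transition_point \
            == pytest.approx(0.6)
        from topoeeg.topology import EulerCurve
        curve = EulerCurve(np.array([0.0, 0.5]), np.array([2, 1]),
                           transition_rule="first-zero")
        assert curve.transition_point is None

    def test_sign_change_without_exact_zero(self):
        from topoeeg.topology import EulerCurve
        curve = EulerCurve(np.array([0.0, 0.3, 0.6]), np.array([5, 2, -3]))
        assert curve.transition_point == pytest.approx(0.6)


def test_transformer_returns_barcode_per_trial(rng):
    x = np.stack([random_weight_matrix(5, rng) for _ in range(3)])
    out = VietorisRipsPersistence().fit_transform(x)
    assert len(out) == 3
    assert all(bc.max_filtration == 1.0 for bc in out)
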