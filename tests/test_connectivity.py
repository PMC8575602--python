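"""Instantaneous phase, PLV matrices, standardized distances, filtration maps."""

from fractions import Fraction

import numpy as np
import pytest
from sklearn.base import clone

from topoeeg import (PhaseLockingConnectivity, PhaseMatrix,
                     StandardizedDistanceConnectivity, distance_matrix,
                     instantaneous_phase, plv_matrix, to_filtration)


def two_tones(fs=250.0, dur=2.0, freq=10.0):
    t = np.arange(int(dur * fs)) / fs
    return t, np.vstack([np.cos(2 * np.pi * freq * t),
                         np.sin(2 * np.pi * freq * t)])


class TestInstantaneousPhase:
    def test_pure_tone_phase_advances_linearly(self):
        fs, freq = 250.0, 10.0
        t, x = two_tones(fs=fs, freq=freq)
        pm = instantaneous_phase(x[:1], fs)
        interior = slice(50, 450)
        slopes = np.diff(np.unwrap(pm.phases[0, interior]))
        expected = 2 * np.pi * freq / fs
        assert abs(np.mean(slopes) / expected - 1.0) < 0.01

    def test_identical_channels_identical_phases(self, rng):
        x = rng.normal(size=(1, 500)).repeat(2, axis=0)
        pm = instantaneous_phase(x, 250.0)
        np.testing.assert_array_equal(pm.phases[0], pm.phases[1])

    def test_quadrature_pair_offset_by_half_pi(self):
        _, x = two_tones()
        pm = instantaneous_phase(x, 250.0)
        interior = slice(50, 450)
        diff = np.angle(np.exp(1j * (pm.phases[0, interior]
                                     - pm.phases[1, interior])))
        np.testing.assert_allclose(diff, np.pi / 2, atol=0.02)

    def test_zero_channel_rejected(self):
        x = np.zeros((2, 500))
        x[0] = np.random.default_rng(0).normal(size=500)
        with pytest.raises(ValueError, match=r"\[1\]"):
            instantaneous_phase(x, 250.0)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="64"):
            instantaneous_phase(np.ones((2, 32)), 250.0)

    def test_edge_mask_flags_ten_percent_each_side(self):
        pm = PhaseMatrix(np.zeros((1, 100)), 250.0)
        assert pm.edge_mask.sum() == 20
        assert pm.edge_mask[0] and pm.edge_mask[-1] and not pm.edge_mask[50]


class TestPLV:
    def test_identical_phases_give_unit_plv_and_zero_diagonal(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=(1, 1000)).repeat(3, axis=0)
        c = plv_matrix(PhaseMatrix(phi, 250.0)).values
        assert np.allclose(np.diag(c), 0.0)
        off = c[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_independent_uniform_phases_near_zero(self, rng):
        # resultant length of 10,000 iid uniform phase differences
        for _ in range(20):
            phi = rng.uniform(-np.pi, np.pi, size=(2, 10_000))
            c = plv_matrix(PhaseMatrix(phi, 250.0)).values
            assert c[0, 1] < 0.1

    def test_common_phase_offset_invariance(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=(4, 500))
        shifted = np.angle(np.exp(1j * (phi + 1.234)))
        c1 = plv_matrix(PhaseMatrix(phi, 250.0)).values
        c2 = plv_matrix(PhaseMatrix(shifted, 250.0)).values
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_values_bounded_and_symmetric(self, rng):
        for _ in range(10):
            phi = rng.uniform(-np.pi, np.pi, size=(5, 300))
            c = plv_matrix(PhaseMatrix(phi, 250.0)).values
            assert c.min() >= 0.0 and c.max() <= 1.0
            np.testing.assert_array_equal(c, c.T)

    def test_trim_edges_changes_sample_count_used(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=(2, 500))
        c_full = plv_matrix(PhaseMatrix(phi, 250.0)).values
        c_trim = plv_matrix(PhaseMatrix(phi, 250.0), trim_edges=True).values
        assert not np.allclose(c_full, c_trim)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            plv_matrix(PhaseMatrix(np.zeros((1, 100)), 250.0))


class TestDistance:
    # 3 channels x 2 samples; exact expected values by hand from the
    # per-sample cross-channel standard deviations:
    #   column variances (ddof=1): 19/3 and 7/3
    #   d(0,1) = (1-3)^2/(19/3) + (2-5)^2/(7/3) = 12/19 + 27/7
    X = np.array([[1.0, 2.0], [3.0, 5.0], [6.0, 4.0]])

    def test_hand_computed_values(self):
        d = distance_matrix(self.X).values
        exact = {
            (0, 1): Fraction(12, 19) + Fraction(27, 7),
            (0, 2): Fraction(75, 19) + Fraction(12, 7),
            (1, 2): Fraction(27, 19) + Fraction(3, 7),
        }
        for (i, j), v in exact.items():
            assert d[i, j] == pytest.approx(float(v), rel=1e-12)
            assert d[j, i] == d[i, j]
        assert np.allclose(np.diag(d), 0.0)

    def test_sqrt_variant_is_monotone_transform(self):
        d2 = distance_matrix(self.X, squared=True).values
        d1 = distance_matrix(self.X, squared=False).values
        np.testing.assert_allclose(d1 ** 2, d2, rtol=1e-12)

    def test_identical_channels_distance_zero(self, rng):
        x = rng.normal(size=(3, 50))
        x[1] = x[0]
        d = distance_matrix(x).values
        assert d[0, 1] == 0.0

    def test_permutation_equivariance(self, rng):
        x = rng.normal(size=(5, 40))
        perm = rng.permutation(5)
        d = distance_matrix(x).values
        dp = distance_matrix(x[perm]).values
        np.testing.assert_allclose(dp, d[np.ix_(perm, perm)], rtol=1e-9)

    def test_degenerate_sample_position_rejected(self):
        x = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])  # s_0 = 0
        with pytest.raises(ValueError, match=r"\[0\]"):
            distance_matrix(x)


class TestToFiltration:
    def test_plv_complement_map(self):
        c = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.5], [0.0, 0.5, 0.0]])
        from topoeeg import ConnectivityMatrix
        w = to_filtration(ConnectivityMatrix(c, "C")).values
        assert w[0, 1] == 0.0 and w[0, 2] == 1.0 and w[1, 2] == 0.5
        assert np.allclose(np.diag(w), 0.0)

    def test_distance_minmax_map(self):
        from topoeeg import ConnectivityMatrix
        d = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 10.0], [6.0, 10.0, 0.0]])
        w = to_filtration(ConnectivityMatrix(d, "D")).values
        assert w[0, 1] == 0.0 and w[1, 2] == 1.0
        assert w[0, 2] == pytest.approx(0.5)

    def test_degenerate_distance_warns_uniform_half(self):
        from topoeeg import ConnectivityMatrix
        d = np.full((3, 3), 4.0)
        np.fill_diagonal(d, 0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            w = to_filtration(ConnectivityMatrix(d, "D")).values
        off = w[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.5)


class TestEstimators:
    def test_plv_transformer_shapes_and_range(self, rng):
        x = rng.normal(size=(4, 3, 200))
        est = PhaseLockingConnectivity(fs=250.0)
        w = clone(est).fit(x).transform(x)
        assert w.shape == (4, 3, 3)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_distance_transformer_shapes(self, rng):
        x = rng.normal(size=(4, 3, 200))
        w = StandardizedDistanceConnectivity().fit_transform(x)
        assert w.shape == (4, 3, 3)
        assert np.allclose(w, np.transpose(w, (0, 2, 1)))

    def test_bad_input_dimension_rejected(self):
        with pytest.raises(ValueError, match="n_trials"):
            PhaseLockingConnectivity().fit(np.zeros((3, 200)))
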