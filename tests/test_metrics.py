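"""Distance metrics: hand-derived values, symmetry/ordering properties, and
persistence decomposition against the filtration oracle."""

import numpy as np
import pytest

from dfcdist import (
    ConfigError,
    DataError,
    DFCSequence,
    MetricSpec,
    METRIC_NAMES,
    distance_series,
    elementwise_distance,
    nuclear_distance,
    persistence_decompose,
    spectral_distance,
    wasserstein_distance,
)

from conftest import random_connectivity
from oracles import filtration_birth_death


def sym(offdiag):
    """2x2 hollow symmetric matrix with the given off-diagonal entry."""
    return np.array([[0.0, offdiag], [offdiag, 0.0]])


def triangle(w12, w13, w23):
    return np.array([[0.0, w12, w13], [w12, 0.0, w23], [w13, w23, 0.0]])


class TestElementwiseAndSpectral:
    def test_hand_computed_two_region_distances(self):
        a, b = sym(0.8), sym(0.5)
        # full-matrix sums: both symmetric entries contribute
        assert elementwise_distance(a, b, "manhattan") == pytest.approx(0.6)
        assert elementwise_distance(a, b, "frobenius") == pytest.approx(np.sqrt(0.18))
        assert elementwise_distance(a, b, "chebyshev") == pytest.approx(0.3)

    def test_nuclear_two_region(self):
        # difference [[0, .3], [.3, 0]] has singular values {0.3, 0.3}
        assert nuclear_distance(sym(0.8), sym(0.5)) == pytest.approx(0.6)

    def test_spectral_two_region(self):
        # eigenvalues -+0.5 vs -+0.2, sorted ascending
        assert spectral_distance(sym(0.5), sym(0.2)) == pytest.approx(np.sqrt(0.18))

    def test_identity_gives_zero_for_all_metrics(self, rng):
        mat = random_connectivity(rng, 5)
        for kind in ("manhattan", "frobenius", "chebyshev"):
            assert elementwise_distance(mat, mat, kind) == 0
        assert nuclear_distance(mat, mat) == 0
        assert spectral_distance(mat, mat) == 0
        for dim in (0, 1):
            assert wasserstein_distance(mat, mat, dim=dim) == 0

    def test_argument_symmetry_and_nonnegativity(self, rng):
        for _ in range(10):
            a, b = random_connectivity(rng, 6), random_connectivity(rng, 6)
            for f in (
                lambda x, y: elementwise_distance(x, y, "manhattan"),
                lambda x, y: elementwise_distance(x, y, "frobenius"),
                lambda x, y: elementwise_distance(x, y, "chebyshev"),
                nuclear_distance,
                spectral_distance,
                lambda x, y: wasserstein_distance(x, y, 0),
                lambda x, y: wasserstein_distance(x, y, 1),
            ):
                d, dT = f(a, b), f(b, a)
                assert d >= 0
                assert d == pytest.approx(dT)

    def test_homogeneity_under_joint_scaling(self, rng):
        a, b = random_connectivity(rng, 5), random_connectivity(rng, 5)
        alpha = 0.37
        for f in (
            lambda x, y: elementwise_distance(x, y, "manhattan"),
            lambda x, y: elementwise_distance(x, y, "frobenius"),
            lambda x, y: elementwise_distance(x, y, "chebyshev"),
            nuclear_distance,
            spectral_distance,
        ):
            assert f(alpha * a, alpha * b) == pytest.approx(alpha * f(a, b))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(DataError, match="mismatch"):
            elementwise_distance(random_connectivity(rng, 4),
                                 random_connectivity(rng, 5), "manhattan")


class TestPersistence:
    def test_triangle_example(self):
        summary = persistence_decompose(triangle(0.9, 0.5, 0.3))
        assert np.allclose(summary.births, [0.5, 0.9])
        assert np.allclose(summary.deaths, [0.3])

    def test_cardinalities_at_aal_scale(self, rng):
        mat = random_connectivity(rng, 116)
        summary = persistence_decompose(mat)
        assert len(summary.births) == 115
        assert len(summary.deaths) == 6555
        assert len(summary.births) + len(summary.deaths) == 116 * 115 // 2

    def test_equal_weights_graph(self):
        m, w = 6, 0.42
        mat = np.full((m, m), w)
        np.fill_diagonal(mat, 0.0)
        summary = persistence_decompose(mat)
        assert np.allclose(summary.births, w)
        assert np.allclose(summary.deaths, w)
        assert len(summary.deaths) == 1 + m * (m - 3) // 2

    def test_tied_weights_give_tiebreak_invariant_multisets(self, rng):
        # duplicated weights: multiset must match the union-find oracle
        for _ in range(25):
            m = int(rng.integers(3, 8))
            vals = rng.choice([0.0, 0.2, 0.4, 0.6, 0.8], size=(m, m))
            mat = np.triu(vals, 1)
            mat = mat + mat.T
            summary = persistence_decompose(mat)
            births, deaths = filtration_birth_death(mat)
            assert np.array_equal(summary.births, births)
            assert np.array_equal(summary.deaths, deaths)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(DataError, match="M >= 3"):
            persistence_decompose(sym(0.5))


class TestWasserstein:
    def test_sorted_matching_births(self):
        a = triangle(0.9, 0.5, 0.3)   # births {0.5, 0.9}
        b = triangle(0.7, 0.4, 0.2)   # births {0.4, 0.7}, death {0.2}
        d = wasserstein_distance(a, b, dim=0, p=2)
        assert d == pytest.approx(np.sqrt(0.01 + 0.04))

    def test_single_pair_death_matching(self):
        a = triangle(0.9, 0.5, 0.3)     # death {0.3}
        b = triangle(0.95, 0.8, 0.6)    # death {0.6}
        assert wasserstein_distance(a, b, dim=1, p=2) == pytest.approx(0.3)
        # p=1 on singleton multisets is the absolute difference
        assert wasserstein_distance(a, b, dim=1, p=1) == pytest.approx(0.3)

    def test_invalid_order_rejected(self):
        with pytest.raises(ConfigError):
            wasserstein_distance(triangle(0.9, 0.5, 0.3),
                                 triangle(0.7, 0.4, 0.2), dim=0, p=0.5)
        with pytest.raises(ConfigError):
            wasserstein_distance(triangle(0.9, 0.5, 0.3),
                                 triangle(0.7, 0.4, 0.2), dim=2)


class TestDistanceSeries:
    def make_seq(self, rng, t, m=5):
        mats = np.stack([random_connectivity(rng, m) for _ in range(t)])
        return DFCSequence(mats, subject_id="s")

    def test_length_is_t_minus_one(self, rng):
        seq = self.make_seq(rng, 41)
        for name in METRIC_NAMES:
            assert len(distance_series(seq, name)) == 40

    def test_constant_sequence_gives_zero_series(self, rng):
        mat = random_connectivity(rng, 5)
        seq = DFCSequence(np.stack([mat] * 6), subject_id="s")
        for name in METRIC_NAMES:
            assert np.allclose(distance_series(seq, name).values, 0.0)

    def test_series_matches_pairwise_calls(self, rng):
        seq = self.make_seq(rng, 6)
        spec = MetricSpec("wasserstein1", wasserstein_order_p=2)
        series = distance_series(seq, spec)
        direct = [
            wasserstein_distance(seq.matrices[i], seq.matrices[i + 1], dim=1, p=2)
            for i in range(5)
        ]
        assert np.allclose(series.values, direct)

    def test_relabeling_invariance_for_every_metric(self, rng):
        seq = self.make_seq(rng, 5, m=6)
        perm = rng.permutation(6)
        permuted = DFCSequence(seq.matrices[:, perm][:, :, perm], subject_id="s")
        for name in METRIC_NAMES:
            a = distance_series(seq, name).values
            b = distance_series(permuted, name).values
            assert np.allclose(a, b, atol=1e-9), name

    def test_sequence_shorter_than_two_is_rejected(self, rng):
        with pytest.raises(DataError, match="at least 2"):
            DFCSequence(np.stack([random_connectivity(rng, 4)]), subject_id="s")
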