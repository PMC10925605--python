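"""Functional connectivity, affinity kernel, diffusion map embedding,
and the gradient markers."""

import numpy as np
import pytest

from eigenmarkers import (
    FunctionalConnectivity,
    ParcellatedTimeSeries,
    build_affinity,
    compute_fc,
    diffusion_map_embedding,
    gradient_dispersion,
    gradient_range,
    principal_eigenvalue_ratio,
)
from eigenmarkers.errors import DegenerateInputError, ParameterError


def _ts(data, tr=1.25):
    labels = [f"roi_{i:03d}" for i in range(data.shape[1])]
    return ParcellatedTimeSeries(data=data, tr=tr, region_labels=labels)


def _fc(matrix):
    labels = [f"roi_{i:03d}" for i in range(matrix.shape[0])]
    return FunctionalConnectivity(matrix=np.asarray(matrix, float), region_labels=labels)


class TestFunctionalConnectivity:
    def test_identical_and_negated_regions(self, rng):
        x = rng.normal(size=100)
        data = np.column_stack([x, x, -x])
        fc = compute_fc(_ts(data))
        assert fc.matrix[0, 1] == pytest.approx(1.0)
        assert fc.matrix[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        data = rng.normal(size=(100, 8))
        fc = compute_fc(_ts(data))
        centred = data - data.mean(axis=0)
        sd = data.std(axis=0)
        for i in range(8):
            for j in range(8):
                expected = (centred[:, i] * centred[:, j]).mean() / (sd[i] * sd[j])
                assert abs(fc.matrix[i, j] - expected) < 1e-12

    def test_zero_variance_region_named(self, rng):
        data = rng.normal(size=(50, 4))
        data[:, 2] = 7.0
        with pytest.raises(DegenerateInputError, match="roi_002"):
            compute_fc(_ts(data))


class TestAffinity:
    def test_near_identical_connectivity_profiles_have_high_affinity(self, rng):
        # 20 near-identical regions: thresholded rows differ only at the
        # excluded self-column, so normalized-angle similarity stays high
        x = rng.normal(size=200)
        data = np.column_stack([x + 0.01 * rng.normal(size=200) for _ in range(20)])
        aff = build_affinity(compute_fc(_ts(data)), density=1.0)
        assert np.all(aff > 0.85)
        np.testing.assert_allclose(np.diag(aff), 1.0)

    def test_kernel_closed_forms(self):
        # normalized angle: identical -> 1, orthogonal -> 0.5, antipodal -> 0
        from eigenmarkers.gradients import _cosine_rows

        rows = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        cos = _cosine_rows(rows)
        angle = 1 - np.arccos(np.clip(cos, -1, 1)) / np.pi
        assert angle[0, 0] == pytest.approx(1.0)
        assert angle[0, 1] == pytest.approx(0.5)
        assert angle[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_row_density_retains_expected_count(self, rng):
        from eigenmarkers.gradients import _row_threshold

        z = rng.normal(size=(82, 82))
        np.fill_diagonal(z, 0.0)
        out = _row_threshold(z, 0.10)
        # round(0.1 * 81) = 8 retained entries per row
        assert np.all((out != 0).sum(axis=1) == 8)

    def test_affinity_symmetric_nonnegative(self, rng):
        data = rng.normal(size=(120, 20))
        aff = build_affinity(compute_fc(_ts(data)), density=0.2)
        assert np.max(np.abs(aff - aff.T)) < 1e-12
        assert aff.min() >= 0.0

    def test_cosine_kernel_clipped_at_zero(self, rng):
        data = rng.normal(size=(120, 20))
        aff = build_affinity(compute_fc(_ts(data)), density=0.2, kernel="cosine")
        assert aff.min() >= 0.0

    def test_too_sparse_density_rejected(self, rng):
        data = rng.normal(size=(50, 10))
        with pytest.raises(ParameterError):
            build_affinity(compute_fc(_ts(data)), density=0.01)


def _reference_diffusion_map(w, alpha, n_components):
    """Independent dense implementation straight from the definition:
    alpha-normalise, build the Markov matrix, take its right eigenvectors
    directly with a general eigensolver, and normalise them in the
    stationary-weighted norm (the diffusion-map convention)."""
    d = w.sum(axis=1)
    w_alpha = w / np.outer(d**alpha, d**alpha)
    d2 = w_alpha.sum(axis=1)
    p = w_alpha / d2[:, None]
    evals, evecs = np.linalg.eig(p)
    order = np.argsort(-evals.real)
    evals = evals.real[order]
    evecs = evecs.real[:, order]
    # unit norm under the d2 weight, then scale so the trivial mode is 1
    norms = np.sqrt((d2[:, None] * evecs**2).sum(axis=0))
    psi = evecs / norms[None, :] * np.sqrt(d2.sum())
    psi *= np.sign(psi[0, 0])  # trivial mode is the all-ones vector
    lam = evals[1 : n_components + 1]
    return psi[:, 1 : n_components + 1] * (lam / (1 - lam)), lam


class TestDiffusionMapEmbedding:
    def test_two_block_affinity_separates_blocks_by_sign(self):
        n = 10
        w = np.full((n, n), 0.01)
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        np.fill_diagonal(w, 1.0)
        emb = diffusion_map_embedding(w, n_components=3)
        g1 = emb.gradients[:, 0]
        assert len(set(np.sign(g1[:5]))) == 1
        assert len(set(np.sign(g1[5:]))) == 1
        assert np.sign(g1[0]) != np.sign(g1[5])

    def test_permutation_equivariance(self, rng):
        w = rng.uniform(0.1, 1.0, size=(12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        perm = rng.permutation(12)
        emb = diffusion_map_embedding(w, n_components=3)
        emb_p = diffusion_map_embedding(w[np.ix_(perm, perm)], n_components=3)
        # same coordinates up to a global per-component sign
        for k in range(3):
            a = emb.gradients[perm, k]
            b = emb_p.gradients[:, k]
            assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-8

    def test_matches_independent_dense_oracle(self, rng):
        w = rng.uniform(0.05, 1.0, size=(20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        emb = diffusion_map_embedding(w, alpha=0.5, n_components=5)
        ref, ref_lam = _reference_diffusion_map(w, 0.5, 5)
        np.testing.assert_allclose(emb.eigenvalues, ref_lam, atol=1e-8)
        for k in range(5):
            a, b = emb.gradients[:, k], ref[:, k]
            assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-8

    def test_markov_eigenvalues_bounded(self, rng):
        w = rng.uniform(0.1, 1.0, size=(15, 15))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        emb = diffusion_map_embedding(w, n_components=14)
        assert np.all(emb.eigenvalues < 1.0)
        assert np.all(emb.eigenvalues > -1.0)

    def test_disconnected_affinity_rejected(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        from eigenmarkers.errors import DisconnectedGraphError

        with pytest.raises(DisconnectedGraphError):
            diffusion_map_embedding(w, n_components=2)


class TestGradientMarkers:
    def _emb(self, gradients, eigenvalues=None):
        from eigenmarkers import GradientEmbedding

        gradients = np.asarray(gradients, dtype=float)
        if eigenvalues is None:
            eigenvalues = np.linspace(0.5, 0.1, gradients.shape[1])
        return GradientEmbedding(
            gradients=gradients, eigenvalues=np.asarray(eigenvalues, float)
        )

    def test_range_arithmetic_and_sign_invariance(self):
        emb = self._emb(np.array([[-0.2], [0.1], [0.3]]))
        assert gradient_range(emb, 1) == pytest.approx(0.5)
        flipped = self._emb(-emb.gradients)
        assert gradient_range(flipped, 1) == pytest.approx(0.5)

    def test_range_homogeneity(self, rng):
        g = rng.normal(size=(30, 2))
        assert gradient_range(self._emb(0.5 * g), 1) == pytest.approx(
            0.5 * gradient_range(self._emb(g), 1)
        )

    def test_dispersion_closed_forms(self):
        assert gradient_dispersion(self._emb(np.zeros((5, 3)))) == 0.0
        two = np.zeros((2, 3))
        two[0, 0], two[1, 0] = 1.0, -1.0
        assert gradient_dispersion(self._emb(two)) == pytest.approx(2.0)

    def test_dispersion_equals_n_times_covariance_trace(self, rng):
        g = rng.normal(size=(40, 5))
        emb = self._emb(g)
        cov = np.cov(g[:, :3], rowvar=False, bias=True)
        assert gradient_dispersion(emb, 3) == pytest.approx(
            40 * np.trace(cov), rel=1e-12
        )

    def test_dispersion_rotation_invariance(self, rng):
        g = rng.normal(size=(25, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = gradient_dispersion(self._emb(g), 3)
        b = gradient_dispersion(self._emb(g @ q), 3)
        assert a == pytest.approx(b, rel=1e-10)

    @pytest.mark.parametrize(
        "eigenvalues, expected",
        [([0.7], 1.0), ([0.25, 0.25, 0.25, 0.25], 0.25), ([0.5, 0.3, 0.2], 0.5)],
    )
    def test_eigenvalue_ratio(self, eigenvalues, expected):
        emb = self._emb(np.zeros((4, len(eigenvalues))), eigenvalues)
        assert principal_eigenvalue_ratio(emb) == pytest.approx(expected)

    def test_out_of_range_requests_rejected(self):
        emb = self._emb(np.zeros((4, 2)))
        with pytest.raises(ParameterError):
            gradient_range(emb, 3)
        with pytest.raises(ParameterError):
            gradient_dispersion(emb, 5)
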