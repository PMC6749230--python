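import numpy as np
import pytest

import gaitid as g
from gaitid.errors import FitError
from gaitid.nlda import compute_scatters, nlda_fit

from conftest import small_sample_instance


def scatter_oracle(X, labels):
    """Naive double-loop evaluation of the scatter-matrix sums."""
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    mu = X.mean(axis=0)
    S_W, S_B = np.zeros((n, n)), np.zeros((n, n))
    for c in np.unique(labels):
        members = X[np.asarray(labels) == c]
        mu_c = members.mean(axis=0)
        for x in members:
            S_W += np.outer(x - mu_c, x - mu_c)
        S_B += len(members) * np.outer(mu_c - mu, mu_c - mu)
    return S_W, S_B


class TestScatters:
    def test_hand_instance(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 0.0], [12.0, 0.0]])
        labels = [1, 1, 2, 2]
        pair = compute_scatters(X, labels)
        assert np.allclose(pair.S_W, [[4.0, 0.0], [0.0, 0.0]])
        assert np.allclose(pair.S_B, [[100.0, 0.0], [0.0, 0.0]])

    def test_one_sample_per_class_has_zero_within_scatter(self, rng):
        X = rng.normal(size=(5, 7))
        pair = compute_scatters(X, np.arange(5))
        assert np.allclose(pair.S_W, 0.0)

    def test_identical_samples_zero_both(self):
        X = np.tile([1.0, 2.0, 3.0], (6, 1))
        pair = compute_scatters(X, [0, 0, 1, 1, 2, 2])
        assert np.allclose(pair.S_W, 0.0) and np.allclose(pair.S_B, 0.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        n_classes = int(rng.integers(2, 5))
        counts = rng.integers(1, 4, size=n_classes)
        N = min(int(counts.sum()), 12)
        labels = np.repeat(np.arange(n_classes), counts)[:N]
        if np.unique(labels).size < 2:
            labels[-1] = labels[0] + 1
        X = rng.normal(size=(len(labels), n))
        pair = compute_scatters(X, labels)
        S_W, S_B = scatter_oracle(X, labels)
        assert np.max(np.abs(pair.S_W - S_W)) < 1e-10
        assert np.max(np.abs(pair.S_B - S_B)) < 1e-10

    def test_symmetry_and_psd(self, rng):
        X, labels = small_sample_instance(rng)
        pair = compute_scatters(X, labels)
        for S in (pair.S_W, pair.S_B):
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() > -1e-8


class TestNldaFit:
    def test_default_dimension_is_classes_minus_one(self, rng):
        X, labels = small_sample_instance(rng, n_classes=5, per_class=3)
        model = nlda_fit(X, labels)
        assert model.n_components == 4
        assert model.transform(X[0]).shape == (4,)

    def test_null_space_and_orthonormality(self, rng):
        X, labels = small_sample_instance(rng)
        model = nlda_fit(X, labels)
        pair = compute_scatters(X, labels)
        projected_sw = model.W.T @ pair.S_W @ model.W
        assert np.max(np.abs(projected_sw)) <= 1e-8 * np.max(np.abs(pair.S_W))
        assert np.allclose(model.W.T @ model.W, np.eye(model.n_components), atol=1e-10)

    def test_classes_collapse_to_centroids(self, rng):
        X, labels = small_sample_instance(rng, jitter=2.0)
        model = nlda_fit(X, labels)
        Y = model.transform(X)
        centroid_gap = np.linalg.norm(
            model.centroids[:, None] - model.centroids[None], axis=-1
        )
        scale = centroid_gap[centroid_gap > 0].mean()
        for c in np.unique(labels):
            members = Y[labels == c]
            spread = np.linalg.norm(members - members.mean(axis=0), axis=1).max()
            assert spread <= 1e-8 * scale

    def test_jitter_confined_to_subspace(self, rng):
        # class offsets in 50-D plus within-class jitter confined to 2-D
        basis = rng.normal(size=(2, 50))
        means = rng.normal(scale=6.0, size=(3, 50))
        X = np.vstack(
            [means[i] + rng.normal(size=(3, 2)) @ basis for i in range(3)]
        )
        labels = np.repeat(np.arange(3), 3)
        model = nlda_fit(X, labels)
        pair = compute_scatters(X, labels)
        assert np.max(np.abs(model.W.T @ pair.S_W @ model.W)) < 1e-10 * np.max(np.abs(pair.S_W))
        gaps = np.linalg.norm(model.centroids[:, None] - model.centroids[None], axis=-1)
        assert gaps[np.triu_indices(3, 1)].min() > 1e-6

    def test_between_class_eigenvalues_non_increasing(self, rng):
        X, labels = small_sample_instance(rng, n_classes=5)
        model = nlda_fit(X, labels)
        assert (np.diff(model.between_eigvals) <= 1e-9).all()
        pair = compute_scatters(X, labels)
        projected = model.W.T @ pair.S_B @ model.W
        assert np.allclose(np.diag(projected), model.between_eigvals, rtol=1e-8)

    def test_first_component_beats_random_null_directions(self, rng):
        """Brute-force search in the explicit null space never finds a better direction."""
        X, labels = small_sample_instance(rng, n=30, n_classes=4, per_class=3)
        model = nlda_fit(X, labels)
        pair = compute_scatters(X, labels)
        best = model.W[:, 0] @ pair.S_B @ model.W[:, 0]
        vals, vecs = np.linalg.eigh(pair.S_W)
        null_basis = vecs[:, vals <= 1e-10 * vals.max()]
        coeffs = rng.normal(size=(500, null_basis.shape[1]))
        dirs = coeffs @ null_basis.T
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        variances = np.einsum("ij,jk,ik->i", dirs, pair.S_B, dirs)
        assert variances.max() <= best + 1e-6 * best

    def test_transform_is_linear_and_uncentered(self, rng):
        X, labels = small_sample_instance(rng)
        model = nlda_fit(X, labels)
        x1, x2 = X[0], X[4]
        lhs = model.transform(1.7 * x1 - 0.3 * x2)
        rhs = 1.7 * model.transform(x1) - 0.3 * model.transform(x2)
        assert np.max(np.abs(lhs - rhs)) < 1e-10
        assert np.allclose(model.transform(np.zeros(X.shape[1])), 0.0)

    def test_global_translation_leaves_distances_unchanged(self, rng):
        X, labels = small_sample_instance(rng)
        shift = rng.normal(scale=10.0, size=X.shape[1])
        p0 = compute_scatters(X, labels)
        p1 = compute_scatters(X + shift, labels)
        assert np.allclose(p0.S_W, p1.S_W, atol=1e-7)
        assert np.allclose(p0.S_B, p1.S_B, atol=1e-7)
        m0, m1 = nlda_fit(X, labels), nlda_fit(X + shift, labels)
        d0 = np.linalg.norm(m0.transform(X)[:, None] - m0.transform(X)[None], axis=-1)
        d1 = np.linalg.norm(m1.transform(X + shift)[:, None] - m1.transform(X + shift)[None], axis=-1)
        assert np.allclose(d0, d1, atol=1e-6)

    def test_training_sample_projects_to_class_mean(self, rng):
        X, labels = small_sample_instance(rng)
        model = nlda_fit(X, labels)
        mean0 = X[labels == 0].mean(axis=0)
        gap = model.transform(X[0]) - model.transform(mean0)
        assert np.linalg.norm(gap) < 1e-8 * max(np.linalg.norm(model.transform(mean0)), 1.0)

    def test_degenerate_regimes_raise(self, rng):
        # large-sample regime: within-class scatter has no null space in the span
        X = rng.normal(size=(40, 3))
        labels = np.arange(40) % 2
        with pytest.raises(FitError, match="small-sample"):
            nlda_fit(X, labels)
        with pytest.raises(FitError, match="n_components"):
            small = small_sample_instance(rng)
            nlda_fit(small[0], small[1], n_components=10)
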