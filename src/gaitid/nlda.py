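"""Null-space linear discriminant analysis (NLDA).

Classical LDA is ill posed in the small-sample-size regime (data dimension
n larger than sample count N), where the within-class scatter S_W is
singular. NLDA instead restricts attention to the null space of S_W inside
the span of the data: there every class collapses to a single point, and the
projection W is chosen to maximize the between-class scatter

    W_opt = argmax_{W^T S_W W = 0}  |W^T S_B W|,

yielding at most C - 1 discriminant features for C classes. The fit is
computed through the N x N Gram matrix of the centered data rather than the
n x n scatter matrices, which is the standard exact factorization for
N << n and keeps a 1008-dimensional fit on 42 samples instantaneous.

Scatter matrices follow the unnormalized-sum convention:

    S_W = sum_i sum_{x in c_i} (x - mu_i)(x - mu_i)^T
    S_B = sum_i N_i (mu_i - mu)(mu_i - mu)^T
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError

DEFAULT_TOL = 1e-10


@dataclass
class ScatterPair:
    """Explicit within/between-class scatter matrices and the class means."""

    S_W: np.ndarray  # (n, n)
    S_B: np.ndarray  # (n, n)
    class_means: np.ndarray  # (C, n)
    global_mean: np.ndarray  # (n,)
    classes: np.ndarray  # (C,)
    counts: np.ndarray  # (C,)


@dataclass
class NLDAModel:
    """A fitted null-space LDA projection.

    ``W`` has orthonormal columns spanning directions that annihilate the
    within-class scatter while maximizing between-class scatter, ordered by
    descending between-class eigenvalue. ``transform`` applies y = W^T x
    with no centering; 1-NN classification only uses pairwise feature
    distances, which are unaffected by a common shift.
    """

    W: np.ndarray  # (n, n_components)
    classes: np.ndarray  # (C,)
    centroids: np.ndarray  # (C, n_components) class-mean images in feature space
    between_eigvals: np.ndarray  # (n_components,) descending
    modality: str = ""

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project a sample (n,) or a stack of samples (N, n)."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.W.shape[0]:
            raise ValueError(f"expected dimension {self.W.shape[0]}, got {x.shape[-1]}")
        return x @ self.W


def _class_stats(X: np.ndarray, labels: np.ndarray):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match the number of rows of X")
    classes, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if classes.size < 2:
        raise FitError("need at least 2 classes")
    means = np.zeros((classes.size, X.shape[1]))
    np.add.at(means, inverse, X)
    means /= counts[:, None]
    return X, classes, inverse, counts, means


def compute_scatters(X: np.ndarray, labels: np.ndarray) -> ScatterPair:
    """Within- and between-class scatter matrices of a labeled sample matrix."""
    X, classes, inverse, counts, means = _class_stats(X, labels)
    mu = X.mean(axis=0)
    Hw = X - means[inverse]  # rows: x_j - mu_{c(j)}
    Hb = (means - mu) * np.sqrt(counts)[:, None]  # rows: sqrt(N_i) (mu_i - mu)
    return ScatterPair(
        S_W=Hw.T @ Hw,
        S_B=Hb.T @ Hb,
        class_means=means,
        global_mean=mu,
        classes=classes,
        counts=counts,
    )


def nlda_fit(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int | None = None,
    tol: float = DEFAULT_TOL,
    modality: str = "",
) -> NLDAModel:
    """Fit the null-space LDA projection.

    Three-stage algorithm, all stages exact:

    1. restrict to the span of the total scatter S_T = S_W + S_B (rank at
       most N - 1), obtained from the eigendecomposition of the N x N Gram
       matrix of the mean-centered data;
    2. within that span, keep the null space of S_W (eigenvalues at most
       ``tol`` times the largest);
    3. there, take the ``n_components`` leading eigenvectors of S_B.

    ``tol`` is a relative eigenvalue threshold separating numerical zeros
    from signal. The default ``n_components`` is C - 1, the maximal
    between-class rank.

    Raises
    ------
    FitError
        If the within-class null space inside the data span is empty (the
        data are not in the small-sample regime) or if ``n_components``
        exceeds the available between-class rank.
    """
    X, classes, inverse, counts, means = _class_stats(X, labels)
    C = classes.size
    if n_components is None:
        n_components = C - 1
    if not 1 <= n_components <= C - 1:
        raise FitError(f"n_components must be in [1, C-1] = [1, {C - 1}], got {n_components}")

    # Stage 1: orthonormal basis U of span(S_T) via the centered Gram matrix.
    Hc = X - X.mean(axis=0)
    gram = Hc @ Hc.T
    gram_vals, gram_vecs = np.linalg.eigh((gram + gram.T) / 2.0)
    keep = gram_vals > tol * max(gram_vals[-1], 0.0)
    if not keep.any():
        raise FitError("total scatter is zero: all samples identical")
    U = Hc.T @ (gram_vecs[:, keep] / np.sqrt(gram_vals[keep]))  # (n, r), orthonormal

    # Stage 2: null space of S_W restricted to span(U).
    Hw = X - means[inverse]
    Aw = Hw @ U  # (N, r); U^T S_W U = Aw^T Aw
    Sw_r = Aw.T @ Aw
    w_vals, w_vecs = np.linalg.eigh((Sw_r + Sw_r.T) / 2.0)
    w_max = max(w_vals[-1], 0.0)
    null = w_vals <= tol * w_max if w_max > 0 else np.ones_like(w_vals, dtype=bool)
    if not null.any():
        raise FitError(
            "within-class scatter has no null space inside the data span; "
            "the data are not in the small-sample regime (need n > N - C)"
        )
    Z = U @ w_vecs[:, null]  # (n, q), orthonormal

    # Stage 3: top between-class directions inside the null space.
    Hb = (means - X.mean(axis=0)) * np.sqrt(counts)[:, None]
    Ab = Hb @ Z  # (C, q); Z^T S_B Z = Ab^T Ab
    Sb_q = Ab.T @ Ab
    b_vals, b_vecs = np.linalg.eigh((Sb_q + Sb_q.T) / 2.0)
    order = np.argsort(b_vals)[::-1]
    b_vals, b_vecs = b_vals[order], b_vecs[:, order]
    available = int(np.sum(b_vals > tol * max(b_vals[0], 0.0))) if b_vals[0] > 0 else 0
    if n_components > available:
        raise FitError(
            f"requested {n_components} components but between-class rank in the "
            f"null space is {available}"
        )
    W = Z @ b_vecs[:, :n_components]  # orthonormal columns
    # deterministic sign convention: largest-magnitude entry of each column positive
    flip = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    flip[flip == 0] = 1.0
    W = W * flip

    return NLDAModel(
        W=W,
        classes=classes,
        centroids=means @ W,
        between_eigvals=b_vals[:n_components],
        modality=modality,
    )
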