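"""Multi-modal feature fusion via the supervised Laplacian score.

Pressure and acceleration NLDA features live in different feature spaces,
so their between-class eigenvalues are not directly comparable. The fusion
step therefore (1) concatenates the per-modality features into a candidate
vector (pressure first), (2) scores every candidate feature with a
supervised Laplacian score computed on a same-class similarity graph over
the training samples, and (3) keeps the d best-scoring features as the
multi-modal vector fed to the classifier.

The graph places an edge between training samples i != j exactly when they
share a class label, weighted by a Gaussian kernel exp(-||y_i - y_j||^2 / m)
with bandwidth m (default 2); self-weights are zero. With degree matrix
D = diag(W 1) and Laplacian L = D - W, the score of feature column f is

    LS = (f~^T L f~) / (f~^T D f~),   f~ = f - (f^T D 1 / 1^T D 1) 1.

Larger scores are selected by default. Note this inverts the usual
locality-preserving convention of the Laplacian score (where smaller is
better); the direction is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import FitError

DEFAULT_BANDWIDTH = 2.0
DEFAULT_DIRECTION = "larger"


@dataclass
class LaplacianGraph:
    """Supervised similarity graph over N training samples."""

    weights: np.ndarray  # (N, N) symmetric, zero diagonal, zero across classes
    degrees: np.ndarray  # (N,) row sums of weights
    laplacian: np.ndarray  # (N, N) D - W
    bandwidth: float


@dataclass
class MultiModalVector:
    """Selected candidate features, in selection order."""

    values: np.ndarray
    source_indices: np.ndarray


def build_candidate(y_pressure: np.ndarray, y_accel: np.ndarray) -> np.ndarray:
    """Concatenate per-modality feature vectors (or stacks), pressure first."""
    y_pressure = np.asarray(y_pressure, dtype=float)
    y_accel = np.asarray(y_accel, dtype=float)
    if y_pressure.ndim != y_accel.ndim:
        raise ValueError("inputs must both be vectors or both be sample stacks")
    if y_pressure.ndim == 1:
        if y_pressure.shape[0] != y_accel.shape[0]:
            raise ValueError(
                f"modalities must contribute equally many features "
                f"({y_pressure.shape[0]} vs {y_accel.shape[0]})"
            )
        return np.concatenate([y_pressure, y_accel])
    if y_pressure.shape[0] != y_accel.shape[0]:
        raise ValueError("pressure and acceleration feature stacks differ in sample count")
    if y_pressure.shape[1] != y_accel.shape[1]:
        raise ValueError(
            f"modalities must contribute equally many features "
            f"({y_pressure.shape[1]} vs {y_accel.shape[1]})"
        )
    return np.hstack([y_pressure, y_accel])


def build_graph(
    candidates: np.ndarray, labels: np.ndarray, bandwidth: float = DEFAULT_BANDWIDTH
) -> LaplacianGraph:
    """Same-class Gaussian-kernel graph over candidate vectors."""
    candidates = np.asarray(candidates, dtype=float)
    labels = np.asarray(labels)
    n = candidates.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to build a graph")
    sq = squareform(pdist(candidates, metric="sqeuclidean"))
    same = labels[:, None] == labels[None, :]
    weights = np.where(same, np.exp(-sq / bandwidth), 0.0)
    np.fill_diagonal(weights, 0.0)
    degrees = weights.sum(axis=1)
    laplacian = np.diag(degrees) - weights
    return LaplacianGraph(weights=weights, degrees=degrees, laplacian=laplacian, bandwidth=bandwidth)


def laplacian_scores(graph: LaplacianGraph, F: np.ndarray) -> np.ndarray:
    """Laplacian score of every feature column of F on the given graph.

    A column that is constant after D-weighted centering (zero denominator)
    scores 0 by convention.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    D = graph.degrees
    total = D.sum()
    if total <= 0:
        raise FitError("graph has no within-class edges; scores are undefined")
    centered = F - (F.T @ D / total)  # remove the D-weighted mean per column
    numerator = np.einsum("ir,ij,jr->r", centered, graph.laplacian, centered)
    denominator = np.einsum("ir,i,ir->r", centered, D, centered)
    scores = np.zeros(F.shape[1])
    ok = denominator > 1e-12 * max(denominator.max(), 1e-300)
    scores[ok] = numerator[ok] / denominator[ok]
    return scores


def select_features(scores: np.ndarray, d: int, direction: str = DEFAULT_DIRECTION) -> np.ndarray:
    """Indices of the d best-scoring candidate features.

    Ties are broken by the lower candidate index, so selection is
    deterministic across runs.
    """
    scores = np.asarray(scores, dtype=float)
    if direction not in ("larger", "smaller"):
        raise ValueError(f"direction must be 'larger' or 'smaller', got {direction!r}")
    if not 1 <= d <= scores.size:
        raise ValueError(f"d must be in [1, {scores.size}], got {d}")
    key = -scores if direction == "larger" else scores
    order = np.argsort(key, kind="stable")  # stable: ties keep lower index first
    return order[:d]


def build_multimodal(candidate: np.ndarray, selection: np.ndarray) -> MultiModalVector:
    """Gather the selected candidate features, in selection order.

    The same training-derived selection is applied unchanged to training and
    test candidates; nothing is recomputed on test data.
    """
    candidate = np.asarray(candidate, dtype=float)
    selection = np.asarray(selection, dtype=int)
    if selection.size != np.unique(selection).size:
        raise ValueError("selection indices must be distinct")
    if selection.size and (selection.min() < 0 or selection.max() >= candidate.shape[-1]):
        raise IndexError("selection index out of bounds for the candidate vector")
    return MultiModalVector(values=candidate[..., selection], source_indices=selection)
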