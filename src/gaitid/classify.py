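"""1-NN identification and the repeated random-split evaluation protocol.

One experiment repeat: preprocess all sessions into k-step gait samples,
draw a pool of at most ``n_total_samples`` samples, pick
``n_train_per_subject`` training samples per subject (3 by default — the
small-sample regime the method is designed for), fit one NLDA projection
per modality on the training rows, rank the concatenated features by
supervised Laplacian score, and classify every held-out sample with the
one-nearest-neighbour rule under Euclidean distance. The identification
rate is the fraction of held-out samples assigned their true subject,
averaged over ``n_repeats`` independent repeats.

Single-modality results use the per-modality NLDA features directly,
ordered by their between-class eigenvalues; the multi-modal result applies
the Laplacian-score selection. No information flows from held-out samples
into the fit: projections, graph, scores and selection are functions of the
training rows only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import fusion, nlda, preprocess
from .errors import ProtocolError
from .io import RecordingSession
from .preprocess import GaitSample, NormalizedStep

MODALITIES = ("pressure", "acceleration", "multimodal")


@dataclass
class ExperimentConfig:
    """Settings of the repeated random-split identification experiment."""

    n_total_samples: int = 700
    n_train_per_subject: int = 3
    n_repeats: int = 25
    k: int = 1
    feature_dims: tuple[int, ...] | None = None  # None -> the d = min(20, p) operating point
    modalities: tuple[str, ...] = MODALITIES
    cycle_length: int = preprocess.DEFAULT_CYCLE_LENGTH
    reference_foot: str = "left"
    noise_high: float = preprocess.DEFAULT_NOISE_HIGH
    min_cycle_frames: int = preprocess.DEFAULT_MIN_CYCLE_FRAMES
    laplacian_m: float = fusion.DEFAULT_BANDWIDTH
    direction: str = fusion.DEFAULT_DIRECTION
    seed: int = 0
    shuffle_labels: bool = False  # chance-level control: permute subject labels per repeat

    def __post_init__(self) -> None:
        if self.n_total_samples < 1 or self.n_train_per_subject < 1 or self.n_repeats < 1:
            raise ValueError("all experiment counts must be positive")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")


@dataclass
class ExperimentResult:
    """Per-repeat accuracies plus aggregate statistics.

    ``table`` is tidy with columns (repeat, k, d, modality, accuracy,
    n_train, n_test); ``confusion`` accumulates counts over repeats for the
    multi-modal operating point (rows true, columns predicted).
    """

    table: pd.DataFrame
    confusion: pd.DataFrame
    k: int
    config: ExperimentConfig

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of the identification rate per (modality, d)."""
        return (
            self.table.groupby(["modality", "d"], as_index=False)["accuracy"]
            .agg(mean_accuracy="mean", sd_accuracy="std")
            .fillna({"sd_accuracy": 0.0})
        )

    def mean_accuracy(self, modality: str = "multimodal", d: int | None = None) -> float:
        rows = self.table[self.table["modality"] == modality]
        if d is not None:
            rows = rows[rows["d"] == d]
        if rows.empty:
            raise KeyError(f"no rows for modality={modality!r}, d={d}")
        return float(rows.groupby("repeat")["accuracy"].mean().mean())


def knn_predict(train_features: np.ndarray, train_labels: np.ndarray, query: np.ndarray):
    """Label of the Euclidean-nearest training row; ties -> lowest row index."""
    train_features = np.asarray(train_features, dtype=float)
    train_labels = np.asarray(train_labels)
    if train_features.ndim != 2 or train_features.shape[0] < 1:
        raise ValueError("training set must be a non-empty 2-D matrix")
    query = np.asarray(query, dtype=float)
    if query.shape[-1] != train_features.shape[1]:
        raise ValueError("query dimension does not match training features")
    if query.ndim == 1:
        dists = np.linalg.norm(train_features - query, axis=1)
        return train_labels[int(np.argmin(dists))]
    dists = cdist(query, train_features)  # argmin returns the lowest index on ties
    return train_labels[np.argmin(dists, axis=1)]


def _steps_by_subject(
    cohort: list[RecordingSession], config: ExperimentConfig
) -> dict[str, list[NormalizedStep]]:
    steps: dict[str, list[NormalizedStep]] = {}
    for session in cohort:
        steps.setdefault(session.subject_id, []).extend(
            preprocess.session_to_steps(
                session, config.cycle_length, config.reference_foot, config.min_cycle_frames
            )
        )
    return steps


def _draw_samples(
    steps: dict[str, list[NormalizedStep]], config: ExperimentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group, regularize, pool-select and label all samples for one repeat."""
    samples: list[GaitSample] = []
    for subject in sorted(steps):
        samples.extend(preprocess.group_steps(steps[subject], config.k, rng, config.noise_high))
    if not samples:
        raise ProtocolError(f"no gait samples at k={config.k}")
    labels = np.array([s.subject_id for s in samples])
    if config.shuffle_labels:
        labels = rng.permutation(labels)
    if len(samples) > config.n_total_samples:
        pool = np.sort(rng.choice(len(samples), size=config.n_total_samples, replace=False))
    else:
        pool = np.arange(len(samples))
    X_p = np.stack([samples[i].feature_input_pressure for i in pool])
    X_a = np.stack([samples[i].feature_input_accel for i in pool])
    return X_p, X_a, labels[pool]


def _split_train_test(
    labels: np.ndarray, n_train: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx = []
    for subject in np.unique(labels):
        members = np.flatnonzero(labels == subject)
        if members.size < n_train + 1:
            raise ProtocolError(
                f"subject {subject!r} has only {members.size} pooled samples; "
                f"need at least {n_train + 1}"
            )
        train_idx.extend(rng.choice(members, size=n_train, replace=False))
    train_idx = np.sort(np.array(train_idx))
    test_idx = np.setdiff1d(np.arange(labels.size), train_idx)
    return train_idx, test_idx


def run_experiment(
    cohort: list[RecordingSession],
    config: ExperimentConfig,
    _steps: dict[str, list[NormalizedStep]] | None = None,
) -> ExperimentResult:
    """Run the full repeated random-split identification experiment."""
    steps = _steps if _steps is not None else _steps_by_subject(cohort, config)
    subjects = sorted(steps)
    C = len(subjects)
    p = 2 * (C - 1)
    if config.feature_dims is None:
        dims = (min(20, p),)
    else:
        dims = tuple(config.feature_dims)

    master = np.random.SeedSequence(config.seed)
    rows = []
    confusion = pd.DataFrame(0, index=subjects, columns=subjects)
    for repeat, child in enumerate(master.spawn(config.n_repeats)):
        rng = np.random.default_rng(child)
        X_p, X_a, labels = _draw_samples(steps, config, rng)
        train_idx, test_idx = _split_train_test(labels, config.n_train_per_subject, rng)
        y_true = labels[test_idx]

        models = {
            "pressure": nlda.nlda_fit(X_p[train_idx], labels[train_idx], modality="P"),
            "acceleration": nlda.nlda_fit(X_a[train_idx], labels[train_idx], modality="A"),
        }
        feats_train = {
            "pressure": models["pressure"].transform(X_p[train_idx]),
            "acceleration": models["acceleration"].transform(X_a[train_idx]),
        }
        feats_test = {
            "pressure": models["pressure"].transform(X_p[test_idx]),
            "acceleration": models["acceleration"].transform(X_a[test_idx]),
        }
        cand_train = fusion.build_candidate(feats_train["pressure"], feats_train["acceleration"])
        cand_test = fusion.build_candidate(feats_test["pressure"], feats_test["acceleration"])
        graph = fusion.build_graph(cand_train, labels[train_idx], config.laplacian_m)
        scores = fusion.laplacian_scores(graph, cand_train)

        common = dict(
            repeat=repeat,
            k=config.k,
            n_train=len(train_idx),
            n_test=len(test_idx),
        )
        for modality in config.modalities:
            seen: set[int] = set()
            for d in dims:
                if modality == "multimodal":
                    if d > p:
                        continue
                    selection = fusion.select_features(scores, d, config.direction)
                    tr = fusion.build_multimodal(cand_train, selection).values
                    te = fusion.build_multimodal(cand_test, selection).values
                else:
                    d = min(d, C - 1)  # single-modal spaces have at most C-1 features
                    if d in seen:
                        continue
                    tr = feats_train[modality][:, :d]  # columns already ordered by S_B eigenvalue
                    te = feats_test[modality][:, :d]
                seen.add(d)
                pred = knn_predict(tr, labels[train_idx], te)
                accuracy = float(np.mean(pred == y_true))
                rows.append(dict(common, modality=modality, d=d, accuracy=accuracy))
                if modality == "multimodal" and d == dims[-1] and not config.shuffle_labels:
                    for t, q in zip(y_true, pred):
                        confusion.loc[t, q] += 1
    table = pd.DataFrame(rows)
    return ExperimentResult(table=table, confusion=confusion, k=config.k, config=config)


def sweep_k(
    cohort: list[RecordingSession], config: ExperimentConfig, ks: list[int]
) -> dict[int, ExperimentResult]:
    """Run the experiment for several k, sharing the session preprocessing."""
    if not ks:
        raise ValueError("ks must be nonempty")
    steps = _steps_by_subject(cohort, config)
    return {k: run_experiment(cohort, replace(config, k=k), _steps=steps) for k in ks}


# ---------------------------------------------------------------------------
# Deployable fitted pipeline (used by the CLI `identify` command)


@dataclass
class FittedPipeline:
    """Training-derived artifacts needed to identify new sessions."""

    model_pressure: nlda.NLDAModel
    model_accel: nlda.NLDAModel
    selection: np.ndarray
    train_features: np.ndarray  # (M, d) multi-modal training features
    train_labels: np.ndarray
    config: ExperimentConfig

    def predict_samples(self, X_p: np.ndarray, X_a: np.ndarray) -> np.ndarray:
        cand = fusion.build_candidate(
            self.model_pressure.transform(X_p), self.model_accel.transform(X_a)
        )
        feats = fusion.build_multimodal(cand, self.selection).values
        return knn_predict(self.train_features, self.train_labels, np.atleast_2d(feats))

    def identify_session(self, session: RecordingSession) -> tuple[str, np.ndarray]:
        """Majority subject label and per-sample predictions for one session."""
        cfg = self.config
        steps = preprocess.session_to_steps(
            session, cfg.cycle_length, cfg.reference_foot, cfg.min_cycle_frames
        )
        rng = np.random.default_rng(cfg.seed)
        samples = preprocess.group_steps(steps, cfg.k, rng, cfg.noise_high)
        if not samples:
            raise ProtocolError("no steps detected: session contains no complete gait cycle")
        X_p = np.stack([s.feature_input_pressure for s in samples])
        X_a = np.stack([s.feature_input_accel for s in samples])
        pred = self.predict_samples(X_p, X_a)
        values, counts = np.unique(pred, return_counts=True)
        return str(values[np.argmax(counts)]), pred

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            W_p=self.model_pressure.W,
            W_a=self.model_accel.W,
            classes=self.model_pressure.classes,
            centroids_p=self.model_pressure.centroids,
            centroids_a=self.model_accel.centroids,
            eig_p=self.model_pressure.between_eigvals,
            eig_a=self.model_accel.between_eigvals,
            selection=self.selection,
            train_features=self.train_features,
            train_labels=self.train_labels,
            config_json=json.dumps(
                {k: v for k, v in vars(self.config).items() if not k.startswith("_")},
                default=list,
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FittedPipeline":
        with np.load(path, allow_pickle=False) as data:
            raw = json.loads(str(data["config_json"]))
            for key in ("feature_dims", "modalities"):
                if raw.get(key) is not None:
                    raw[key] = tuple(raw[key])
            config = ExperimentConfig(**raw)
            return cls(
                model_pressure=nlda.NLDAModel(
                    W=data["W_p"],
                    classes=data["classes"],
                    centroids=data["centroids_p"],
                    between_eigvals=data["eig_p"],
                    modality="P",
                ),
                model_accel=nlda.NLDAModel(
                    W=data["W_a"],
                    classes=data["classes"],
                    centroids=data["centroids_a"],
                    between_eigvals=data["eig_a"],
                    modality="A",
                ),
                selection=data["selection"],
                train_features=data["train_features"],
                train_labels=data["train_labels"],
                config=config,
            )


def fit_pipeline(cohort: list[RecordingSession], config: ExperimentConfig) -> FittedPipeline:
    """Fit one deployable pipeline on a training split drawn from the cohort."""
    steps = _steps_by_subject(cohort, config)
    subjects = sorted(steps)
    C = len(subjects)
    p = 2 * (C - 1)
    d = config.feature_dims[-1] if config.feature_dims else min(20, p)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    X_p, X_a, labels = _draw_samples(steps, config, rng)
    train_idx, _ = _split_train_test(labels, config.n_train_per_subject, rng)
    model_p = nlda.nlda_fit(X_p[train_idx], labels[train_idx], modality="P")
    model_a = nlda.nlda_fit(X_a[train_idx], labels[train_idx], modality="A")
    cand = fusion.build_candidate(
        model_p.transform(X_p[train_idx]), model_a.transform(X_a[train_idx])
    )
    graph = fusion.build_graph(cand, labels[train_idx], config.laplacian_m)
    scores = fusion.laplacian_scores(graph, cand)
    selection = fusion.select_features(scores, min(d, p), config.direction)
    features = fusion.build_multimodal(cand, selection).values
    return FittedPipeline(
        model_pressure=model_p,
        model_accel=model_a,
        selection=selection,
        train_features=features,
        train_labels=labels[train_idx],
        config=config,
    )
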