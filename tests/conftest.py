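import numpy as np
import pytest

import gaitid as g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_session(rng, n_frames=50, subject_id="subj"):
    """A structurally valid (not gait-like) random recording."""
    return g.RecordingSession(
        subject_id=subject_id,
        pressure=rng.integers(0, 3, size=(n_frames, 16)),
        acceleration=rng.normal(size=(n_frames, 6)),
    )


def small_sample_instance(rng, n=60, n_classes=4, per_class=3, spread=5.0, jitter=0.5):
    """Random labeled data in the small-sample regime (n > N - C)."""
    means = rng.normal(scale=spread, size=(n_classes, n))
    X = np.vstack([means[i] + rng.normal(scale=jitter, size=(per_class, n)) for i in range(n_classes)])
    labels = np.repeat(np.arange(n_classes), per_class)
    return X, labels


@pytest.fixture(scope="session")
def moderate_cohort():
    """14-subject cohort at the moderate preset, with ground truth."""
    spec = g.CohortSpec(n_subjects=14, separation=0.5, steps_per_subject=30, seed=42)
    return g.synth_cohort_sessions(spec)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    """A small on-disk cohort for CLI tests."""
    from gaitid import io as gio

    spec = g.CohortSpec(n_subjects=4, separation=1.0, steps_per_subject=20, seed=9)
    sessions, _ = g.synth_cohort_sessions(spec)
    root = tmp_path_factory.mktemp("cohort")
    gio.write_cohort(sessions, root)
    return root
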