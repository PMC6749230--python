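# Methods

## Data model

A recording session is a time-synchronous pair of matrices sampled at
100 Hz: `pressure` (frames × 16, left-foot sensors 1–8 then right-foot
sensors 1–8, each value in {0, 1, 2}; 0 means the foot is off the ground)
and `acceleration` (frames × 6, left x/y/z then right x/y/z, raw sensor
units). The physical sensor layout (3 forefoot-medial, 3 forefoot-lateral,
2 heel per foot) is documented but never used computationally — channel
order is purely positional. Acceleration units are left raw; every
downstream computation is unit-agnostic, and the 1-NN classifier only uses
distances within a fixed feature space.

On disk, one CSV per session with a `# subject_id=... sample_rate=...`
comment line, a fixed header, and one row per frame; cohorts are
`<root>/<subject>/<session>.csv` directories. Floats are written with
Python's shortest round-tripping `repr` and parsed with pandas'
`round_trip` float parser, so write → read → write is byte-identical —
this makes the determinism guarantees testable at the file level.

## Segmentation

The only unambiguous, hardware-level gait event in this data is the
swing-phase onset: the first frame at which all 8 pressure sensors of one
foot read zero. A cycle is the half-open frame interval
`[onset_i, onset_{i+1})` of a configurable reference foot (default left);
partial leading/trailing cycles are dropped. Both feet's channels travel
together inside every segment. Segments shorter than `min_cycle_frames`
(default 10 frames = 0.1 s, far below any plausible gait cycle) are
discarded as sensor glitches.

## Normalization and regularization

Each cycle is resampled channel-by-channel to `cycle_length` = 63 frames
by linear interpolation of the uniform grid mapping `[0, T−1]` onto
`[0, 62]`. Linear interpolation is monotone, preserves constants exactly,
and is the identity when T = 63, which gives clean oracle tests.
Pressure becomes real-valued after interpolation and is not re-quantized.
Matrices are flattened time-major (row-major), giving vectors of length
63·16 = 1008 and 63·6 = 378 per step.

Every vector element then receives i.i.d. uniform noise on
`[0, noise_high)` with `noise_high` = 0.1. This regularization exists for
rank reasons: the swing phase zeroes the same block of the pressure vector
in every sample, so without noise the total scatter loses rank and the
null-space construction becomes ill-conditioned. Noise is drawn fresh per
step, for training and test samples alike, from the experiment-level seed;
it is applied at grouping time, when k consecutive steps are concatenated
into one classifier sample (non-overlapping windows, leftovers dropped).
At 0–0.1 against pressure levels of 0–2 and acceleration amplitudes of
order 1, the noise is far too small to affect nearest-neighbour decisions.

## Null-space LDA

Scatters use the unnormalized-sum convention (`S_B` weighted by class
counts N_i). The fit runs in three exact stages: (1) restrict to the span
of the total scatter `S_T = S_W + S_B`, computed from the eigendecomposition
of the N × N Gram matrix of mean-centered data rather than the n × n
scatter (identical span, and the only tractable route at n = 1008 with
N = 42); (2) keep the null space of `S_W` inside that span (relative
eigenvalue threshold `tol` = 1e−10 × the largest eigenvalue); (3) take the
`n_components` (default C−1) leading eigenvectors of `S_B` there. Columns
of W are orthonormal by construction, ordered by descending between-class
eigenvalue, with a deterministic sign convention (largest-magnitude entry
positive) so fits are bit-for-bit reproducible.

`transform` is the uncentered linear map `y = Wᵀx`. Whether to subtract
the global mean is immaterial here: a common shift moves all features
equally and 1-NN only compares distances, which tests assert explicitly.

Degenerate inputs raise rather than warn: no within-class null space
inside the data span (the data are not in the small-sample regime,
n ≤ N − C), or `n_components` exceeding the available between-class rank.

## Fusion by supervised Laplacian score

Candidate vectors concatenate pressure features first, then acceleration
(p = 2(C−1) features). The graph over the N training samples connects
same-class pairs only, with Gaussian weights `exp(−‖y_i − y_j‖²/m)`;
`m` = 2 is a plain divisor (bandwidth). Self-weights are 0 (no self-loops)
— the Laplacian `L = D − W` is unaffected and the convention makes tests
exact. Scores follow `LS_r = f̃ᵀLf̃ / f̃ᵀDf̃` with the D-weighted mean
removed; a feature constant after centering scores 0 by convention.
Features with *larger* scores are selected (ties to the lower candidate
index), the selection being a pure function of the training split and
applied unchanged to test candidates.

Two caveats, flagged for users. First, larger-is-better inverts the
original locality-preserving semantics of the Laplacian score; the
`direction` option restores the conventional order if wanted. Second, on
NLDA training features the numerator is degenerate by construction — the
null-space projection collapses each training class to a point, so every
same-class difference, and hence every score, is numerically ≈ 0 and the
ranking resolves floating-point residue. The ranking is still
deterministic, and because all 2(C−1) candidate features carry
between-class signal, the d = min(20, p) operating point is insensitive to
which 6 of 26 features it drops; the sweep interface (`feature_dims`)
exposes the full d = 1..p curve for anyone studying this.

## Evaluation protocol

Per repeat: regularize and group steps at the configured k, draw a pool of
at most `n_total_samples` = 700 samples uniformly (all samples if fewer),
pick `n_train_per_subject` = 3 training samples per subject, fit both NLDA
models, graph, scores and selection on the 42 training rows only, and
classify the held-out rows by 1-NN (ties to the lowest training index).
Repeats (default 25) re-draw both pool and split from per-repeat seeds
spawned off one master seed, so a whole experiment is reproducible from a
single integer. Single-modal results use the per-modality NLDA features
directly, ordered by between-class eigenvalue and capped at C−1
dimensions; the pool draw is not stratified by subject, and a repeat
aborts with an explicit error naming the subject if any subject has fewer
than 4 pooled samples. A `shuffle_labels` switch permutes subject labels
per repeat as a chance-level control. Confusion counts are accumulated
across repeats at the multi-modal operating point for diagnostics.

## Synthetic cohorts

The generator is a test harness emulating the statistical structure the
method assumes, not a biomechanical model. Each subject template holds:
per-sensor contact windows within the stance phase plus a peak level in
{1, 2}; a 3-harmonic sinusoid per acceleration channel; and a preferred
cycle length. Cycles alternate ~60% stance / 40% swing with the feet half
a cycle out of phase; two designated sensors per foot (one heel, one
forefoot) have their windows clipped so the union of active windows always
covers the stance phase — every stance frame is loaded, every swing frame
is all-zero, and swing-onset segmentation is exact by construction (the
generator emits ground-truth boundaries under the same convention the
segmenter uses).

Defaults emulate ordinary adult walking at 100 Hz: mean cycle ≈ 115
frames (≈ 1.15 s, clipped to 100–130), within-subject cycle-length CV
0.05, per-step contact-window jitter 0.02 stance fractions, accelerometer
noise s.d. 0.3 against harmonic amplitudes of 0.15–1.2. Between-subject
differences are scaled by `separation` (presets: easy 1.0, moderate 0.5,
hard 0.15); at 0 all templates coincide and identification collapses to
chance, which tests use as a negative control. What the generator does
*not* emulate: sensor dropout, cross-day drift, footwear changes, surface
or speed regimes, pathological gaits. Passing tests therefore demonstrate
the correctness and small-sample behaviour of the pipeline, not field
performance on real insole data.

## Problem sizes

The shipped experiments use 14 subjects × 60 steps (≈ 3 minutes of
walking each), giving 840/418/280 samples at k = 1/2/3, a 700-sample pool
and a 42-train / 658-test split at k = 1, with 5 repeats — the package's
default desk-scale configuration; all sizes are configuration, not code.

## Known limitations

* The Laplacian-score degeneracy on null-space features described above.
* Identification is closed-set: every probe is assigned to some training
  subject; there is no rejection of unknown walkers.
* Pressure quantization to 3 levels is assumed by the validator; richer
  insoles would need a relaxed data model.
* Cross-session generalization (enrol one day, identify another) is out
  of scope of the evaluation protocol.
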