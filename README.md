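# gaitid

Identify *who is walking* from smart-insole sensor data.

A dual-foot smart insole streams, at 100 Hz, 16 plantar-pressure channels
(8 per foot, quantized to levels {0, 1, 2}) and 6 acceleration channels
(triaxial per foot). Gait patterns are individual enough to serve as a
biometric, but the usable training data per person is tiny (a few labeled
steps), while each step, once unrolled over time, is a high-dimensional
vector — the classic small-sample-size regime where ordinary LDA breaks
down. `gaitid` implements an identification pipeline built for exactly
that regime, plus a synthetic insole-cohort generator with ground truth
for every stage.

## Method

1. **Segmentation.** A gait cycle runs from one swing-phase onset of a
   reference foot to the next, where the swing onset is the first frame at
   which all 8 pressure sensors of that foot read 0.
2. **Normalization.** Each cycle is linearly resampled to a fixed length
   l = 63 frames, removing walking-speed variability, and flattened
   time-major into per-modality vectors `x^P ∈ R^1008` (pressure) and
   `x^A ∈ R^378` (acceleration). Uniform noise on [0, 0.1) is added to
   every element: swing phases zero whole blocks of `x^P` in every sample,
   which would otherwise make the scatter matrices rank deficient.
3. **Null-space LDA (per modality).** With within- and between-class
   scatters `S_W = Σ_i Σ_{x∈c_i} (x−μ_i)(x−μ_i)^T` and
   `S_B = Σ_i N_i (μ_i−μ)(μ_i−μ)^T`, the projection solves

       W_opt = argmax_{W^T S_W W = 0} |W^T S_B W|,

   i.e. it maximizes between-class scatter inside the null space of `S_W`,
   where every class collapses to a point. Features are `y = W^T x`, at
   most C−1 of them for C subjects.
4. **Fusion.** Pressure and acceleration features are concatenated into a
   candidate vector of length 2(C−1) and each feature is scored with a
   supervised Laplacian score `LS_r = (f̃_r^T L f̃_r)/(f̃_r^T D f̃_r)` on a
   same-class graph with Gaussian weights `exp(−‖y_i−y_j‖²/m)`, m = 2. The
   d best-scoring features (d = min(20, 2(C−1)) by default) form the
   multi-modal vector.
5. **Classification.** One-nearest-neighbour under Euclidean distance.
   Evaluation follows a repeated random-split protocol: draw a pool of
   700 samples, train on 3 samples per subject (42 for C = 14), test on
   the rest, repeat 25 times, report the mean identification rate. Samples
   may bundle k = 1, 2, 3 consecutive steps.

## Worked example

```python
import gaitid as g

spec = g.CohortSpec(n_subjects=14, separation=0.5, steps_per_subject=60, seed=7)
sessions, _ = g.synth_cohort_sessions(spec)
result = g.run_experiment(sessions, g.ExperimentConfig(n_repeats=5, seed=11))
print(result.summary())
```

prints

```
       modality   d  mean_accuracy  sd_accuracy
0  acceleration  13       1.000000      0.00000
1    multimodal  20       1.000000      0.00000
2      pressure  13       0.999696      0.00068
```

Each row is one feature configuration: the per-modality null-space LDA
features alone (13 = C−1 dimensions each) and the fused multi-modal vector
(top 20 of 26 candidate features). `mean_accuracy` is the identification
rate over held-out samples, averaged over the 5 random splits — with 14
moderately distinct synthetic walkers and only 3 training steps per
subject, essentially every held-out step is attributed to the right
person. A label-shuffled control (`ExperimentConfig(shuffle_labels=True)`)
drops to ≈ 1/14 ≈ 0.07, confirming the rate is driven by subject identity
and not protocol leakage.

The same pipeline is scriptable from the shell:

```sh
gaitid simulate --out cohort/ --preset moderate --seed 1
gaitid evaluate --cohort cohort/ --out results/ --ks 1,2,3 --seed 1 --save-model model.npz
gaitid identify --model model.npz --session cohort/S03/session01.csv
```

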