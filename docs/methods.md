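# Methods

## Problem

`ecgverify` performs **identity verification** from single-lead ECG: given a
probe heartbeat and a claimed identity, decide whether the probe belongs to
that person. Verification (1:1) is deliberately distinct from identification
(1:N search), which is out of scope. The design goals are the ones that make
metric learning attractive for biometrics: enrollment of new users **without
retraining**, robustness to imbalanced per-subject sample counts (pairs are
constructed, not inherited from the raw class distribution), and storage of
**embeddings rather than raw signals** in the template repository.

## Pipeline

1. **Segmentation.** R peaks are located with a Pan–Tompkins-style detector:
   5–15 Hz Butterworth band-pass, squared derivative, 150 ms moving-window
   integration, adaptive threshold at 30 % of the maximum integrated energy,
   refinement to the raw-signal apex within ±50 ms, and a 200 ms refractory
   period. Each beat is windowed to L samples with the R peak at
   `floor(0.4·L)` — 40 % of the window before R (capturing P/Q) and 60 %
   after (capturing S/T) — and z-scored per segment. Windows crossing a
   record boundary, and constant windows, are discarded.

2. **Spectral channel.** Each L-sample segment x[n] is augmented with the
   z-scored magnitude of its length-L DFT,
   `X[k] = Σ_{n=0}^{L−1} x[n] e^{−j2πkn/L}`, giving an L×2 feature matrix
   (time channel + |X[k]| channel). The full-length magnitude sequence is
   used (rather than a half-spectrum or a real/imaginary pair) so that one
   added channel preserves the segment length exactly; the redundancy from
   conjugate symmetry is accepted. Magnitude was chosen over phase because it
   is shift-tolerant, which suits beats whose window alignment carries ±1–2
   samples of anchor jitter.

3. **Encoder.** A shared-weight 1D CNN: eight convolutional layers
   (kernel 3, same padding, ReLU) with 32, 32, 64, 64, 128, 128, 256, 256
   filters, each followed by a ceil-mode max-pool of size 2 / stride 2, then
   a linear dense layer to a 512-dimensional embedding. Ceil-mode pooling is
   what lets odd intermediate lengths survive: 200 → 100 → 50 → 25 → 13 → 7
   → 4 → 2 → 1 and 256 → … → 1, so the flattened pre-dense dimension is
   256 (channels) × 1 for both presets. One parameter set serves every
   branch of the Siamese comparison; "which branch" an input takes is
   immaterial by construction.

4. **Similarity and ensemble score.** Two embeddings are compared by a
   logistic head on their elementwise absolute difference,
   `s(a,b) = σ(w·|a−b| + b₀)` — symmetric in (a, b), strictly inside (0, 1),
   and collapsing to the constant `σ(b₀)` when a = b. A bundle
   (n_ref references + 1 probe) scores as the arithmetic mean of the probe's
   similarity to each reference, which is permutation-invariant in the
   references. Averaging pairwise similarities was preferred over comparing
   against the mean reference embedding because it degrades gracefully when
   the references themselves are heterogeneous (different sessions or
   conditions of the same person).

5. **Training.** Binary cross-entropy of the bundle score against the
   match/mismatch label, plus an L2 penalty on weight matrices, minimized
   with Adam. The loss attaches to the aggregated bundle score, so the
   ensemble comparison is trained exactly as it is used. Forward, backward
   and optimizer are plain NumPy (im2col convolutions on BLAS matmuls);
   gradients were verified against central finite differences. Inference is
   bit-deterministic; training is deterministic for a fixed seed and BLAS.

6. **Enrollment / authentication.** Enrolling stores the embeddings of the
   first n_ref usable segments (deterministic by design, for reproducible
   repositories) in a versioned JSON repository; floats are serialized with
   shortest-round-trip `repr`, so save/load is bit-exact. Authentication
   encodes the probe, averages its similarity to the claimed user's n_ref
   templates, and accepts iff score ≥ threshold (default 0.7; a score
   exactly at the threshold accepts). An unknown claimed identity raises an
   error rather than rejecting: a reject asserts a mismatch against known
   templates, which is unverifiable for unknown users.

## Evaluation

FAR = % of impostor scores accepted, FRR = % of genuine scores rejected,
accuracy = % of correct decisions, all under the single accept-iff-≥τ
convention. Accuracy is reported at the τ = 0.5 classification cutoff, with
the τ = 0.7 policy variant emitted alongside. The EER is read off a sweep
over midpoints between consecutive distinct scores; when no exact FAR = FRR
crossing exists, the crossing is linearly interpolated between adjacent
sweep points. Because the sweep depends only on the score ordering, the EER
is invariant under strictly monotone transforms of the scores. K-fold
cross-validation is stratified at the bundle level by round-robin dealing
within shuffled label classes, which guarantees fold sizes differ by at most
one while keeping each fold's label mix near the global mix; per-fold models
are trained from scratch with fold-derived seeds.

## Synthetic data generator

Each subject is a parameter set: per-wave (P, Q, R, S, T) Gaussian-bump
amplitude (mV), offset relative to R (s) and width (s); mean RR interval
and RR jitter SD; baseline-wander amplitude (mV) and frequency (Hz); and
white-noise SD (mV). Defaults are uniform draws from ranges typical of
clean adult resting ECG (R amplitude 0.9–1.6 mV, mean RR 0.7–1.0 s ≈
60–85 bpm, noise SD 0.01–0.03 mV, baseline wander 0.05–0.15 mV at
0.2–0.4 Hz — respiratory range). R amplitudes are placed on a shuffled,
jittered grid so any two subjects in a cohort differ by ≥ 0.015 mV,
guaranteeing distinct morphologies. RR intervals are mean_rr plus Gaussian
jitter floored at 0.2·mean_rr, so beats never overlap and each window holds
one beat. Presets mirror two common acquisition setups: `ecgid-like`
(500 Hz, L = 256) and `ptb-like` (1000 Hz, L = 200).

The generator emulates per-subject-distinct PQRST morphology, RR jitter,
baseline wander and additive noise — enough to exercise every pipeline
stage with closed-form R-peak ground truth. It does **not** model U waves,
pathological morphologies (arrhythmia, ST deviation), electrode motion
artifacts, inter-session drift, or multi-lead acquisition. Passing tests on
this data therefore demonstrate the pipeline's correctness and its ability
to separate genuinely distinct morphologies; they do not by themselves
establish field performance on clinical recordings, where within-subject
variability is larger and between-subject gaps are not guaranteed.

## Problem sizes and numerical choices

The built-in experiments are sized for a single CPU: the end-to-end run
uses 20 subjects × ~30 beats, 400 balanced bundles (n_ref = 3), 2-fold
cross-validation and 20 training epochs; the separability sanity task uses
2 zero-noise subjects and 200 bundles. Default training hyperparameters:
learning rate 1e−3, L2 coefficient 1e−4, batch size 32, up to 50 epochs.
Probabilities are clipped to [1e−7, 1−1e−7] inside the cross-entropy;
z-scoring rejects sequences with SD < 1e−12; the inverse DFT rejects
spectra whose imaginary residue exceeds 1e−9 of the signal scale. He
initialization seeds all parameters from the config seed; the head weight
starts near zero so initial scores sit near 0.5.

## Known limitations

- The WFDB reader supports format 16 only (the format used by the target
  PhysioNet archives); other formats raise explicitly.
- The R-peak detector is tuned for clean, R-dominant leads; it is adequate
  for the simulator and clean recordings, not for heavily artifacted data.
- Training determinism is per-platform (it depends on the BLAS build).
- Bundle-level fold splitting allows the same underlying segment to appear
  in both train and test folds; a stricter subject-disjoint protocol would
  lower measured performance and is a natural extension.
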