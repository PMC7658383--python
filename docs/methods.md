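# Methods

`copgait` predicts the stance-phase center-of-pressure (COP) trajectory of
walking from wearable inertial measurement units (IMUs), and evaluates how
the choice of sensor placement affects that prediction.  This note records
the models, the numerical choices, and what the synthetic data do and do not
establish.

## Problem and pipeline

During stance, the COP travels from heel to toe under the foot; its
trajectory carries balance-relevant information that is normally measured
with force plates or instrumented insoles.  The package's pipeline replaces
the insole at *prediction* time with IMUs at up to four sites — heel (H),
lateral midfoot (L), toe (T) on the shoe, and waist (W) — each providing a
tri-axial accelerometer (g) and gyroscope (deg/s), 6 channels per site.

Stages, in order:

1. **Synchronization.**  All streams are aligned on the insole clock using
   the first prominent peak produced by a deliberate floor stomp at session
   start, visible both in the heel accelerometer magnitude and in the
   vertical ground-reaction force (GRF).  The peak finder restricts itself
   to the opening seconds and requires height ≥ ½ of the window maximum, so
   ordinary step peaks (≈1.1 × body weight) cannot shadow the stomp
   (3 × the normal GRF peak by default).
2. **Swing cleaning.**  Insole pressure during swing is noise by
   definition; frames with GRF below 10 N are zeroed and their COP marked
   undefined (NaN).  The sentinel is NaN, not 0, so downstream code must
   mask stance explicitly.
3. **Event detection.**  Heel strike = first frame of a loaded epoch with
   GRF ≥ 10 N; toe off = first post-peak frame with GRF < 25 N.  The
   thresholds are the conventional insole gait-event values; the crossing
   directions (rising for heel strike, falling for toe off) follow loading
   and push-off physiology.  Epochs shorter than 0.3 s are rejected as
   artifacts — this also removes the stomp itself (~0.05 s).
4. **Step handling.**  The first and last 3 steps of each corridor trip can
   be trimmed (`trim_steps`) to drop gait initiation/termination; the
   train/test split is a 70/30 random partition *at step level*, because
   lookback windows of neighbouring frames overlap almost entirely and a
   frame-level split would leak.
5. **Windowing.**  The lookback `P` is the mean heel-strike-to-heel-strike
   cycle length of the training steps (≈163 frames ≈ 1.1 s at 148 Hz).  For
   every stance frame `t`, the sample is (IMU frames `[t−P, t)`, COP(`t`)),
   advanced frame by frame; windows that would reach before the recording
   start are skipped, not padded.  Channels are z-scored with moments from
   the training windows only.
6. **Regression.**  A stacked LSTM (64/128/64 units), dropout 0.2 between
   the last recurrent layer and a single linear output, trained with
   RMSprop (lr 1e-3, ρ 0.9) for 20 epochs at batch size 148 under a
   root-mean-square-error loss.  One model per direction (AP and ML are
   separate single-output regressors).
7. **Evaluation.**  Per test step, over the stance frames:
   - NRMSE(%) = 100 · RMSE(measured, predicted) / (max measured − min
     measured), with N the actual stance sample count of that step (the
     ≈120-frame stance of the default calibration is incidental, not wired
     in);
   - Jaccard = ∫ min(A, B) / ∫ max(A, B) after shifting each curve to start
     at zero and offsetting both by their common minimum (the ML curve can
     go negative; a *common* offset preserves the inter-curve geometry).
     Trapezoidal integration on the shared frame grid; two identically-zero
     curves give 1 by convention.
8. **Placement sweep.**  All 15 non-empty subsets of {H, L, T, W} × both
   directions, each through stages 5–7; one split per seed is shared across
   subsets so placements are compared on identical test steps; mean ± SD
   tables and per-step archives are written as CSV/JSON.

## The LSTM implementation

The regressor is implemented directly in numpy (time-major layout,
contiguous gate blocks, full backpropagation through time, float32).  Gate
pre-activations are clipped at ±30 before the sigmoid exponential purely as
a float32 overflow guard (sigmoid is already saturated there).  Weight
initialization is Glorot-uniform for input kernels, per-gate orthogonal for
recurrent kernels, forget-gate bias 1.  One seed drives initialization,
batch shuffling, and dropout masks, making training bit-reproducible on a
single machine; gradients were verified against directional finite
differences.

Targets are z-scored internally during training and mapped back to cm at
prediction time.  This is a deliberate design choice: the RMSE loss has a
scale-free gradient (a unit vector divided by the batch size), so the
number of optimizer updates needed to traverse the target's mean is
proportional to the target's scale — raw AP targets (~0–18 cm) cannot be
fit in 20 epochs at the configured learning rate, standardized ones can.

Causality holds by construction (the window for frame `t` ends at `t−1`)
and is asserted by a perturbation test: modifying IMU input at frames ≥ t
leaves predictions at frames ≤ t bit-identical.

## Synthetic data: what it emulates

No public recording accompanies the protocol, so the package ships a
generator whose defaults *are* the study conditions: 148 Hz sampling, 74
steps per session, stance frames ~ round(N(120, 6)), cycle 163 frames, body
weight 541 N, AP COP path 17.48 cm, ML excursion 1.48 cm, a session-opening
stomp at 3 × the normal GRF peak, and an IMU-vs-insole clock offset drawn
uniformly in [−30, 30] frames.

Waveforms are phenomenological functions of a latent gait phase, not
rigid-body physics:

- **GRF**: the classic double bump (peaks ≈ 1.1 × body weight at 27 % and
  73 % of stance) over a small plateau, exactly zero on swing frames.  The
  shape keeps every stance frame above ~35 N so that the 10 N/25 N
  detection rules recover the generator's own annotations exactly at zero
  noise, and the nominal peak ratio (≈1.10) leaves the per-step ±3 SD
  amplitude jitter inside the 0.9–1.3 × body-weight band.
- **COP**: AP is a monotone, slightly S-shaped heel→toe progression scaled
  to 17.48 cm; ML is a single smooth arc with 1.48 cm excursion.  Both are
  exact functions of phase times the per-step amplitude factor.
- **IMU**: per-site sums of phase-locked Gaussian bumps plus low-frequency
  sinusoids — heel spikes at impact and heel-off but is quiet mid-stance,
  the lateral site is active early and late, the toe is active through the
  whole stance with a large push-off burst, and the waist carries only a
  low-amplitude stride-frequency oscillation.  Additive Gaussian noise is
  5 % of each channel's reference amplitude by default.

Per-step variability enters as stance-length jitter plus one shared
amplitude factor ~ N(1, 0.05) multiplying GRF, COP and IMU alike, so the
IMU→COP mapping remains learnable while successive steps differ.

What the generator does **not** emulate: soft-tissue and footwear
artifacts, sensor drift and bias instability, left/right asymmetry,
fatigue-related drift over a session, between-subject anthropometric
variation, and any genuinely nonlinear IMU↔COP physics.  Passing the
end-to-end tests therefore shows that the pipeline's machinery —
synchronization, segmentation, windowing, training, scoring — is correct
and that the regressor can exploit phase information of the kind real foot
sensors carry; it does not certify accuracy on real recordings.

## Numerical and design details

- Resampling is linear interpolation onto a uniform grid (gait content is
  < 20 Hz); the NaN COP sentinel is propagated, never interpolated across.
  Worst-case interpolation error for a 5 Hz component sampled at 100 Hz is
  h²·max|f″|/8 ≈ 1.2 % of amplitude.
- Frames are 0-based and slices half-open; time is float seconds.
- The split uses |train| = round(0.7 · n) (74 steps → 52/22).
- `trim_steps` on an 80-step trip with 3-step edges retains 74 — the
  arithmetic behind the "74 steps per subject" session structure.
- Synthetic sessions are generated post-trim (steady-state steps only), so
  the sweep's default `edge_trim` is 0; real corridor recordings should use
  `edge_trim=3` with trip boundaries.
- The stomp epoch never reaches event detection: it is shorter than the
  0.3 s minimum stance and additionally masked via `ignore_before_frame`.
- Sweep seeds are derived per (subject, combination, direction) from the
  base model seed, so any sub-run is reproducible in isolation.
- The capacity and learnability thresholds in the model tests (training
  RMSE < 10 % of range on 200 samples; < 5 % on a noise-free linear
  functional) were frozen from pilot runs of the released configurations.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
data sized to a desk machine: calibration statistics use three 74-step
sessions (222 steps); the end-to-end placement demonstration trains the
full-width model on one subject (74 steps, ≈6,200 windows of 163 frames)
for the toe-only AP combination, matching the single-combination study
protocol.  A full 15-combination × 2-direction sweep at that scale is a
few hours of CPU time and is left to the user (`copgait sweep`).

## Known limitations

- The ML direction is intrinsically harder (1.48 cm excursion vs 17.48 cm
  AP path); with the default generator the ML Jaccard is markedly lower
  than AP, mirroring the qualitative AP/ML gap expected from walking
  mechanics.
- Jaccard compares time-parameterized curves of equal length; comparing
  curves of different lengths (e.g. predicted vs measured stance of
  different duration) is out of scope because the pipeline predicts on the
  measured stance grid.
- The trainer is single-machine deterministic; determinism across BLAS
  implementations is not guaranteed.
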