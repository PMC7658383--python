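"""Train a toe-only COP regressor and score one held-out step.

A deliberately small run (16 steps, 8 epochs, one sensor) that still
shows the full chain: windowing with the mean-cycle lookback,
standardization from training data only, LSTM training, frame-by-frame
trajectory prediction, and NRMSE / Jaccard scoring.  Takes about a
minute on a laptop CPU.
"""

import numpy as np

from copgait import (
    CurvePair,
    GaitParams,
    ModelConfig,
    WindowSpec,
    build_samples,
    clean_swing_noise,
    compute_stats,
    detect_gait_events,
    generate_session,
    jaccard,
    mean_step_period,
    nrmse,
    predict_trajectory,
    split_steps,
    standardize,
    synchronize,
    train,
)

session = generate_session(GaitParams(n_steps=16, seed=3))
sensors, plantar, lag = synchronize(session.sensors, session.plantar)
cleaned = clean_swing_noise(plantar, 10.0)
steps = detect_gait_events(cleaned)

plan = split_steps(steps, fraction=0.7, seed=3)
train_steps = [steps[i] for i in plan.train_steps]
test_steps = [steps[i] for i in plan.test_steps]

P = mean_step_period(train_steps)
print(f"lookback P = {P} frames (mean heel-strike-to-heel-strike cycle)")

spec = WindowSpec(lookback_frames=P, sites=("T",), direction="AP")
ds = build_samples(sensors, cleaned, train_steps, spec)
stats = compute_stats(ds)
model = train(standardize(ds, stats), ModelConfig(epochs=8, seed=1), channel_stats=stats)
print(f"training RMSE by epoch (cm): {[round(h, 2) for h in model.training_history]}")

step = test_steps[0]
frames, pred = predict_trajectory(model, sensors, cleaned, step)
measured = cleaned.cop_ap_cm[frames]
pair = CurvePair(measured=measured, predicted=pred)
print(f"test step: {len(pred)} stance frames, "
      f"NRMSE {nrmse(pair):.2f} %, Jaccard {jaccard(pair):.3f}")
# NRMSE is the error relative to the measured AP range (~17.5 cm);
# Jaccard near 1 means the predicted profile overlaps the measured one.
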