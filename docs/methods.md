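# Methods

## Signal model and units

All glucose values are handled internally in mmol/L (1 mmol/L = 18.0182
mg/dl; the conversion factor is frozen at the molar-mass value because 18.0
and 18.016 also circulate and the error-grid boundaries are unit-sensitive).
A `GlucoseSeries` is a strictly uniform 5-minute grid — 288 samples/day —
with finite, positive values; every pipeline stage consumes and produces
this type. Raw sensor records with dropouts are cut into uniform segments
wherever consecutive timestamps differ by more than `max_gap` (default
2 × the sampling period: one missed reading is tolerated, two are not,
because a longer hole corrupts the 20-tap history). Segments shorter than
40 samples — one training window — are discarded rather than padded;
padding would fabricate data. Gaps are never interpolated.

## Preprocessing

Each segment is smoothed once, before the test/train split, with a centred
moving average of span 11 samples (55 minutes). Endpoints use the
shrinking-symmetric-window convention: point *i* averages the
`2·min(i, n−1−i)+1` values centred on it, so the first and last samples
pass through unchanged. Smoothing therefore never widens the value range
and is exact on constants and linear ramps. Both training windows and the
evaluation references use the smoothed signal by default (a
`raw_reference` flag scores against the unsmoothed sensor values instead).

The test set is the *leading* `n_test = 500` samples, walked across
segments in order; the remainder trains the network. The input scaler
(affine map of the training min/max onto [−1, 1], required by the tanh
hidden units) is fitted on training data only — fitting it on test data
would leak.

## Network and training

Architecture: 20 delay taps → 20 tanh → 13 tanh → 1 linear. Weights are
initialised uniformly in ±1/√fan_in from a seeded PCG64 generator; biases
start at zero. Training is teacher-forced (series-parallel): every
40-sample window contributes 20 (taps → next value) pairs whose taps are
always true measurements, and the mean-squared one-step error in scaled
units is minimised with full-batch L-BFGS using an analytic backprop
gradient. Everything is deterministic given the seeds.

Two design choices were genuinely open and deserve justification:

* **Model selection is closed-loop.** 15 % of windows are held out; at
  every optimiser iteration each held-out window's 20 inputs seed a
  20-step closed-loop recursion that is scored against the 20 true
  targets. Training stops when this multi-step error has not improved for
  `patience` (30) iterations, and the best-validation snapshot is
  returned. Selecting on *one-step* validation error instead retains
  iterates that memorise one-step residuals and whose recursive rollouts
  compound error badly — the one-step optimum is not the multi-step
  optimum. The closed-loop criterion matches what the trained model is
  used for.
* **Validation-selected weight decay.** An L2 penalty on the weights (not
  biases) is added to the objective; one fit is run per value of a fixed
  grid (0, 10⁻³, 10⁻², 10⁻¹) and the fit with the best closed-loop
  validation score is kept. On noiseless, fully learnable signals the
  unpenalised fit wins and the network converges to the stopping
  tolerance; on noisy CGM the damped fit wins because an over-fitted
  one-step map is locally too steep and its 20-step rollout amplifies
  noise. With a single training series there is no basis for a fixed
  penalty; per-fit selection is the standard remedy.

A `direct` objective (regress the value 20 steps past the taps in one
shot) is available behind `TrainConfig.objective` for comparison; the
default recursive scheme is the one whose intermediate steps populate the
full 5–100-minute horizon sweep.

## Forecasting

`close_loop` flips the mode flag without touching parameters, so the first
recursive prediction is bit-identical to the open-loop one-step prediction.
Recursion step k replaces the k−1 newest taps with the model's own
predictions. The horizon is capped at 20 steps (= n_taps) by default:
beyond that the tap buffer contains no measurement at all, and the 100-minute
horizon is the longest the 20-tap architecture can meaningfully serve. With
tanh hidden units and a linear output the prediction is bounded by
±(‖w_out‖₁ + |b_out|) in scaled units regardless of the input, so closed-loop
rollouts cannot diverge.

## Evaluation

For each horizon PH = 5·k in the sweep (default 15, 30, 45, 60, 90, 100
minutes), a window slides over the test segment with stride 1; at each
position the 20 true smoothed values seed the recursion and prediction k is
paired with the measurement k steps ahead. The paired series feed RMSE, FIT
and NPE (Euclidean norms; FIT may be negative and is not clipped — 0 %
means "no better than predicting the mean") and the Clarke error grid.

Error-grid boundaries are the classic 1987 rule set, evaluated in the fixed
precedence A, E, C, D, else B; sloped boundaries are compared in
integer-scaled form (e.g. 5·P ≥ 6·R rather than P ≥ 1.2·R) so points
exactly on a boundary resolve deterministically to the earlier zone instead
of depending on binary rounding.

The persistence baseline (repeat the last observed value) is implemented
with the identical sliding alignment and serves as the reference any
predictor must beat at long horizons.

## Synthetic CGM generator

The generator emulates home-use CGM records of controlled type-1 diabetic
subjects: baseline 7.0 mmol/L; a circadian sinusoid of amplitude 1.0 mmol/L
and period 24 h; 3 meals/day at random times with gamma-like pulses
m·(Δt/τ)·e^(1−Δt/τ) (magnitude 2–6 mmol/L, rise time τ = 30–60 min — the
pulse peaks at exactly m at Δt = τ); and stationary AR(1) sensor noise
(lag-1 correlation ρ = 0.8, sd σ = 0.15 mmol/L), applied before a hard
clamp to [2.2, 22.2] mmol/L. Under these defaults ≥ 99 % of samples fall in
the 3.5–15.5 mmol/L envelope typical of controlled subjects. The generator
claims statistical resemblance only: there is no insulin–glucose feedback,
no sensor drift or calibration jumps, and meal timing is independent of
glucose state. Tests passing on this data therefore demonstrate the
pipeline's correctness and the network's ability to learn smooth
autoregressive dynamics, not clinical performance on real patients.

## Problem sizes and numerical choices

The test suite and the worked example train on ~3 simulated days
(864 samples, ≈ 820 windows, ≈ 16,000 teacher-forced pairs) with a
500-sample test split — large enough for the network to beat persistence at
the 100-minute horizon on every seed tried, small enough that a full train +
evaluate cycle takes seconds. Stopping tolerance is an MSE of 10⁻⁷ in
scaled units; L-BFGS runs at most 500 iterations. Model files are JSON with
`repr`-round-trip floats, so save/load reproduces every parameter bit for
bit and a schema tag guards against loading files from other versions.

## Known limitations

* Trained per-record; no transfer across subjects or population priors.
* No exogenous covariates (insulin doses, meals, activity) — the predictor
  sees glucose only, which is exactly its intended niche (patients without
  logged covariates) but limits accuracy around unannounced meals.
* The synthetic generator's meals are memoryless; real post-prandial
  dynamics depend on insulin timing.
* Horizons beyond 100 minutes require widening the delay line; the
  architecture caps PH at n_taps sampling periods.
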