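# glynarx

Blood-glucose forecasting for continuous glucose monitoring (CGM) streams
with a closed-loop NARX neural network, evaluated with the field's standard
numerical metrics (RMSE, FIT, NPE) and the clinical Clarke error grid.

Forecasting glucose 45–100 minutes ahead gives insulin-pump controllers and
hypo-/hyperglycemia alarms time to act before an excursion happens. The
package is aimed at researchers prototyping such predictors on CGM data
sampled every 5 minutes (288 readings/day, values in mmol/L).

## The model

A nonlinear autoregressive network with exogenous input (NARX) predicts the
next glucose value from delayed past values. Glucose readings serve as both
the series and the exogenous input, so the inputs reduce to a tapped delay
line of the 20 most recent readings (100 minutes of history):

```
ŷ(t+1) = F( y(t), y(t−1), …, y(t−19) )
```

where F is a fully connected 20 → 20 → 13 → 1 network with tanh hidden
units and a linear output. Two architectures share the same weights:

* **series-parallel (open loop)** — the taps hold true measurements;
  used for training. Each 40-sample window (20 inputs + 20 targets) is
  unrolled into 20 teacher-forced one-step pairs, and the mean-squared
  one-step error is minimised with L-BFGS in [−1, 1]-scaled units.
* **parallel (closed loop)** — the model's own predictions are fed back
  into the taps, giving recursive forecasts k = 1…20 steps ahead, i.e.
  prediction horizons PH = 5·k = 5–100 minutes.

Before training, series are smoothed with a centred moving average
(span 11) and cut at sensor gaps; the first 500 samples are held out as the
test set. Accuracy at horizon PH is reported as RMSE (mmol/L),
FIT = (1 − ‖G−Ĝ‖/‖G−Ḡ‖)·100 % and NPE = (‖G−Ĝ‖/‖G‖)·100 %, plus the
percentage of (measured, predicted) pairs in Clarke error-grid zones A–E.

A seeded synthetic CGM generator (circadian rhythm + meal excursions +
autocorrelated sensor noise) makes the whole pipeline testable without any
data download.

## Worked example

```sh
cat > run.yaml <<'EOF'
simulation:
  n_samples: 1364      # 500 test + 3 simulated days of training data
split:
  n_test: 500
EOF
glynarx simulate --config run.yaml --seed 1 --out sim_out
glynarx train    --config run.yaml --seed 1 --out train_out \
                 --input sim_out/simulated_cgm.csv
glynarx evaluate --config run.yaml --seed 1 --out eval_out \
                 --model train_out/model.json --input sim_out/simulated_cgm.csv
```

prints (abridged):

```
 ph_min  npe_percent  rmse_mmol_per_l  fit_percent
     15     6.079004         0.513262    69.793303
     45    13.135349         1.110609    34.951510
    100    19.355961         1.640245     4.884393
 ph_min  percent_A  percent_B  percent_C  percent_D  percent_E
     15 100.000000   0.000000        0.0        0.0        0.0
     45  90.254237   9.745763        0.0        0.0        0.0
    100  68.763557  31.236443        0.0        0.0        0.0
```

Reading the output: at a 15-minute horizon the forecast tracks the signal
closely (RMSE ≈ 0.5 mmol/L, every point clinically accurate, zone A); as
the horizon stretches to 100 minutes the recursive feedback accumulates
error (RMSE ≈ 1.6 mmol/L, FIT approaching 0 %), yet every prediction stays
in the clinically acceptable zones A and B — no overcorrections (C), missed
events (D) or hypo/hyper confusions (E). Exact numbers depend only on the
seed. Equivalent library calls: `generate_profile`, `run_train`,
`evaluate_sweep` — see `docs/methods.md`.

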