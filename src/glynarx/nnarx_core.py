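"""The NNARX network: construction, open-loop training, closed-loop forecasting.

The model is a nonlinear autoregressive network with exogenous input where
the glucose series itself serves as the exogenous signal, so the delayed
outputs and delayed inputs collapse into a single tapped delay line of the
20 most recent glucose values. Those taps feed a fully connected
20 -> 20 -> 13 -> 1 network with tanh hidden units and a linear output.

Two modes share the same parameters:

* **open loop** (series-parallel): the taps hold true measurements — used
  for teacher-forced training, where every 40-sample training window is
  unrolled into 20 one-step (taps -> next value) pairs;
* **closed loop** (parallel): the taps are progressively filled with the
  model's own predictions, giving recursive multi-step forecasts; step ``k``
  of the recursion is the prediction at horizon ``k`` sampling periods
  (5*k minutes for standard CGM).

Training minimises the mean-squared one-step error in scaled units with a
deterministic quasi-Newton optimiser (L-BFGS) and early stopping on a
held-out fraction of windows; identical seeds reproduce the fitted weights
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .preprocess import Scaler, TrainingWindow, apply_scaler, fit_scaler, invert_scaler

MODEL_SCHEMA = "glynarx-nnarx-1"

OPEN_LOOP = "open_loop"
CLOSED_LOOP = "closed_loop"


class TrainingError(RuntimeError):
    """Training produced a non-finite loss or had nothing to train on."""


def horizon_steps(ph_minutes: float, sampling_period: float = 5.0) -> int:
    """Number of recursive steps for a prediction horizon in minutes.

    A horizon of 100 minutes at the standard 5-minute CGM period is 20
    recursive steps. Raises if the horizon is not a positive multiple of
    the sampling period.
    """
    k = ph_minutes / sampling_period
    if k < 1 or abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"horizon {ph_minutes} min is not a positive multiple of the "
            f"{sampling_period}-min sampling period"
        )
    return int(round(k))


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture of the NNARX network.

    ``n_taps`` delayed glucose values feed ``hidden_sizes`` tanh layers and
    a single linear output. The default 20 taps at 5-minute sampling give
    the network 100 minutes of history — and cap the useful forecast
    horizon at 100 minutes, beyond which the tap buffer would hold only
    self-predictions.
    """

    n_taps: int = 20
    hidden_sizes: tuple[int, ...] = (20, 13)
    activation_hidden: str = "tanh"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        if self.n_taps < 1:
            raise ValueError("n_taps must be >= 1")
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must all be >= 1")
        if self.activation_hidden != "tanh":
            raise ValueError("only tanh hidden units are supported")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_taps, *self.hidden_sizes, 1)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Stopping and reproducibility settings for open-loop training.

    ``validation_fraction`` of the windows is held out; training stops when
    the held-out MSE has not improved for ``patience`` optimiser iterations,
    when the training MSE (scaled units) drops below ``mse_tolerance``, or
    at ``max_epochs`` iterations. ``weight_decay`` is the L2 penalty on the
    weights (not biases) added to the scaled-units MSE; it damps the
    closed-loop error compounding of an over-fitted one-step map. Given a
    tuple of penalties, one full fit is run per value and the model with
    the best closed-loop validation score is kept — noiseless, fully
    learnable data selects no penalty, noisy data selects damping.
    ``objective`` selects teacher-forced one-step training (default) or
    direct regression of the value 20 steps past the taps.
    """

    max_epochs: int = 500
    mse_tolerance: float = 1e-7
    validation_fraction: float = 0.15
    patience: int = 30
    weight_decay: float | tuple[float, ...] = (0.0, 1e-3, 1e-2, 1e-1)
    seed: int = 0
    objective: str = "teacher_forcing"

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")
        if isinstance(self.weight_decay, (tuple, list)):
            object.__setattr__(self, "weight_decay", tuple(float(w) for w in self.weight_decay))
            if not self.weight_decay or any(w < 0 for w in self.weight_decay):
                raise ValueError("weight_decay values must be >= 0")
        elif self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.objective not in ("teacher_forcing", "direct"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclasses.dataclass(frozen=True)
class TrainReport:
    epochs_run: int
    final_train_mse: float
    final_val_mse: float
    converged: bool


@dataclasses.dataclass(frozen=True)
class NNARXModel:
    """Weights, biases, scaler and mode of the NNARX network.

    ``weights[i]`` has shape (layer_sizes[i+1], layer_sizes[i]); the scaler
    maps mmol/L to the [-1, 1] range the tanh layers work in. The same
    parameters serve both modes; only the mode flag differs.
    """

    config: ModelConfig
    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]
    scaler: Scaler | None = None
    mode: str = OPEN_LOOP

    def __post_init__(self) -> None:
        sizes = self.config.layer_sizes
        ws = tuple(np.asarray(w, dtype=float) for w in self.weights)
        bs = tuple(np.asarray(b, dtype=float) for b in self.biases)
        object.__setattr__(self, "weights", ws)
        object.__setattr__(self, "biases", bs)
        if len(ws) != len(sizes) - 1 or len(bs) != len(sizes) - 1:
            raise ValueError("wrong number of layers for config")
        for i, (w, b) in enumerate(zip(ws, bs)):
            if w.shape != (sizes[i + 1], sizes[i]) or b.shape != (sizes[i + 1],):
                raise ValueError(
                    f"layer {i}: expected weight {(sizes[i + 1], sizes[i])} "
                    f"bias {(sizes[i + 1],)}, got {w.shape} / {b.shape}"
                )
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {i}: non-finite parameters")
        if self.mode not in (OPEN_LOOP, CLOSED_LOOP):
            raise ValueError(f"unknown mode {self.mode!r}")


def init_network(config: ModelConfig) -> NNARXModel:
    """Seeded symmetric small-magnitude initialisation (uniform +-1/sqrt(fan_in))."""
    rng = np.random.default_rng(config.seed)
    sizes = config.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        r = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-r, r, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return NNARXModel(config=config, weights=tuple(weights), biases=tuple(biases))


def _forward_scaled(weights, biases, X: np.ndarray) -> np.ndarray:
    """Batch forward pass in scaled units: X (n, taps) -> outputs (n,)."""
    a = X
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ w.T + b)
    return (a @ weights[-1].T + biases[-1])[:, 0]


def _recursive_scaled(weights, biases, X0: np.ndarray, n_steps: int) -> np.ndarray:
    """Batched closed-loop recursion in scaled units.

    X0 (n, taps) holds seed windows; returns (n, n_steps) predictions where
    each step feeds the previous predictions back into the tap buffers.
    """
    buf = np.array(X0, copy=True)
    out = np.empty((len(X0), n_steps))
    for k in range(n_steps):
        p = _forward_scaled(weights, biases, buf)
        out[:, k] = p
        buf[:, :-1] = buf[:, 1:]
        buf[:, -1] = p
    return out


def forward_one_step(model: NNARXModel, taps: np.ndarray) -> float:
    """One-step prediction from the ``n_taps`` most recent glucose values
    (mmol/L, newest last). Works in either mode: this is the shared map F."""
    taps = np.asarray(taps, dtype=float)
    if taps.shape != (model.config.n_taps,):
        raise ValueError(
            f"expected {model.config.n_taps} taps, got shape {taps.shape}"
        )
    if model.scaler is None:
        raise ValueError("model has no fitted scaler")
    x = apply_scaler(model.scaler, taps)[None, :]
    y = _forward_scaled(model.weights, model.biases, x)[0]
    return float(invert_scaler(model.scaler, y))


def _pack(weights, biases) -> np.ndarray:
    return np.concatenate([w.ravel() for w in weights] + [b.ravel() for b in biases])


def _unpack(theta: np.ndarray, sizes):
    weights, biases, k = [], [], 0
    for i in range(len(sizes) - 1):
        n = sizes[i + 1] * sizes[i]
        weights.append(theta[k : k + n].reshape(sizes[i + 1], sizes[i]))
        k += n
    for i in range(len(sizes) - 1):
        biases.append(theta[k : k + sizes[i + 1]])
        k += sizes[i + 1]
    return weights, biases


def _mse_and_grad(theta, sizes, X, y, weight_decay=0.0):
    """Mean-squared error (plus L2 weight penalty) and its gradient."""
    weights, biases = _unpack(theta, sizes)
    acts = [X]
    a = X
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ w.T + b)
        acts.append(a)
    out = (a @ weights[-1].T + biases[-1])[:, 0]
    resid = out - y
    n = len(y)
    loss = float(np.mean(resid**2))

    gw = [np.empty_like(w) for w in weights]
    gb = [np.empty_like(b) for b in biases]
    delta = (2.0 / n) * resid[:, None]          # d loss / d out, (n, 1)
    gw[-1] = delta.T @ acts[-1]
    gb[-1] = delta.sum(axis=0)
    for i in range(len(weights) - 2, -1, -1):
        delta = (delta @ weights[i + 1]) * (1.0 - acts[i + 1] ** 2)
        gw[i] = delta.T @ acts[i]
        gb[i] = delta.sum(axis=0)
    if weight_decay:
        # penalise weights only, never biases
        loss += weight_decay * sum(float(np.sum(w**2)) for w in weights)
        for i, w in enumerate(weights):
            gw[i] += 2.0 * weight_decay * w
    grad = _pack(gw, gb)
    if not np.isfinite(loss) or not np.all(np.isfinite(grad)):
        raise TrainingError("non-finite loss or gradient during training")
    return loss, grad


def _unroll_pairs(windows, n_taps, objective):
    """Teacher-forced pairs: window samples [k, k+n_taps) as taps, sample
    k+n_taps as target, for k = 0..n_out-1 — true values always in the taps."""
    X, y = [], []
    for w in windows:
        seq = np.concatenate([w.inputs, w.targets])
        if objective == "direct":
            X.append(seq[:n_taps])
            y.append(seq[-1])
            continue
        for k in range(len(w.targets)):
            X.append(seq[k : k + n_taps])
            y.append(seq[k + n_taps])
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def train_open_loop(
    model: NNARXModel, windows: list[TrainingWindow], tc: TrainConfig
) -> tuple[NNARXModel, TrainReport]:
    """Teacher-forced (series-parallel) training of the open-loop network.

    Minimises the mean-squared one-step error over all pairs unrolled from
    the windows, in scaled units, with L-BFGS. A ``validation_fraction`` of
    whole windows is held out and scored *closed-loop*: each held-out
    window's 20 inputs seed a 20-step recursion whose predictions are
    compared with the 20 true targets. Training stops when that multi-step
    validation error has not improved for ``patience`` iterations, and the
    parameters returned are the best-validation snapshot — the iterate that
    actually forecasts best, not the one that memorises one-step residuals.
    Deterministic given ``tc.seed``; the input model is not modified.
    """
    if model.mode != OPEN_LOOP:
        raise ValueError("training requires an open-loop model")
    if not windows:
        raise ValueError("no training windows")
    n_taps = model.config.n_taps
    if any(len(w.inputs) != n_taps for w in windows):
        raise ValueError("window input length does not match n_taps")

    scaler = model.scaler
    if scaler is None:
        scaler = fit_scaler(
            np.concatenate([np.concatenate([w.inputs, w.targets]) for w in windows])
        )

    rng = np.random.default_rng(tc.seed)
    order = rng.permutation(len(windows))
    n_val = int(round(tc.validation_fraction * len(windows)))
    val_windows = [windows[i] for i in order[:n_val]]
    train_windows = [windows[i] for i in order[n_val:]]
    if not train_windows:
        raise ValueError("validation_fraction leaves no training windows")

    Xt, yt = _unroll_pairs(train_windows, n_taps, tc.objective)
    Xt = apply_scaler(scaler, Xt)
    yt = apply_scaler(scaler, yt)
    if val_windows:
        # validation is scored closed-loop: seed each held-out window with
        # its 20 true inputs and compare the 20 recursive predictions with
        # the true targets — the quantity the trained model is used for
        Xv = apply_scaler(scaler, np.array([w.inputs for w in val_windows]))
        Yv = apply_scaler(scaler, np.array([w.targets for w in val_windows]))
    else:
        Xv = Yv = None

    sizes = model.config.layer_sizes
    theta0 = _pack(model.weights, model.biases)
    n_out = len(windows[0].targets) if tc.objective == "teacher_forcing" else 1

    def score(theta):
        w, b = _unpack(theta, sizes)
        if Xv is None:
            out = _forward_scaled(w, b, Xt)
            return float(np.mean((out - yt) ** 2))
        if tc.objective == "direct":
            out = _forward_scaled(w, b, Xv)
            return float(np.mean((out - Yv[:, -1]) ** 2))
        preds = _recursive_scaled(w, b, Xv, n_out)
        return float(np.mean((preds - Yv) ** 2))

    def fit_one(weight_decay):
        state = {
            "iters": 0,
            "best_theta": theta0.copy(),
            "best_val": np.inf,
            "since_best": 0,
            "early": False,
            "tol_hit": False,
        }

        def callback(theta):
            state["iters"] += 1
            val = score(theta)
            if val < state["best_val"] - 1e-15:
                state["best_val"] = val
                state["best_theta"] = np.array(theta, copy=True)
                state["since_best"] = 0
            else:
                state["since_best"] += 1
            train_mse = _mse_and_grad(theta, sizes, Xt, yt)[0]
            if train_mse <= tc.mse_tolerance:
                state["tol_hit"] = True
                raise StopIteration
            if Xv is not None and state["since_best"] >= tc.patience:
                state["early"] = True
                raise StopIteration

        minimize(
            _mse_and_grad,
            theta0,
            args=(sizes, Xt, yt, weight_decay),
            jac=True,
            method="L-BFGS-B",
            callback=callback,
            options={"maxiter": tc.max_epochs, "ftol": 1e-15, "gtol": 1e-12},
        )
        state["best_val"] = score(state["best_theta"])
        return state

    decays = (
        tc.weight_decay
        if isinstance(tc.weight_decay, (tuple, list))
        else (tc.weight_decay,)
    )
    if Xv is None and len(decays) > 1:
        # no validation windows -> no basis for selecting a penalty
        decays = decays[:1]
    state = min((fit_one(wd) for wd in decays), key=lambda s: s["best_val"])

    best = state["best_theta"]
    final_train = _mse_and_grad(best, sizes, Xt, yt)[0]
    final_val = score(best) if Xv is not None else final_train
    weights, biases = _unpack(best, sizes)
    trained = NNARXModel(
        config=model.config,
        weights=tuple(np.array(w) for w in weights),
        biases=tuple(np.array(b) for b in biases),
        scaler=scaler,
        mode=OPEN_LOOP,
    )
    report = TrainReport(
        epochs_run=state["iters"],
        final_train_mse=final_train,
        final_val_mse=final_val,
        converged=state["tol_hit"] or state["early"],
    )
    return trained, report


def close_loop(model: NNARXModel) -> NNARXModel:
    """Switch the trained network to the parallel (closed-loop) mode.

    Parameters are untouched; only the mode flag changes, enabling
    :func:`predict_recursive`."""
    if model.mode == CLOSED_LOOP:
        raise ValueError("loop is already closed")
    return dataclasses.replace(model, mode=CLOSED_LOOP)


def predict_recursive(
    model: NNARXModel, seed_window: np.ndarray, n_steps: int, max_steps: int | None = None
) -> np.ndarray:
    """Recursive multi-step forecast from 20 true glucose values.

    Step 1 applies F to the seed window; step ``k`` applies F to a tap
    vector whose ``k-1`` newest entries are the model's own previous
    predictions. Returns all ``n_steps`` intermediate predictions, so the
    forecast at horizon ``5*k`` minutes is element ``k-1``. The horizon is
    capped at ``n_taps`` steps by default: past that the taps hold only
    self-predictions.
    """
    if model.mode != CLOSED_LOOP:
        raise ValueError("recursive prediction requires a closed-loop model")
    cap = model.config.n_taps if max_steps is None else max_steps
    if not 1 <= n_steps <= cap:
        raise ValueError(f"n_steps must be in [1, {cap}], got {n_steps}")
    buf = np.array(seed_window, dtype=float)
    if buf.shape != (model.config.n_taps,):
        raise ValueError(f"seed window must hold {model.config.n_taps} values")
    preds = np.empty(n_steps)
    for k in range(n_steps):
        p = forward_one_step(model, buf)
        preds[k] = p
        buf = np.roll(buf, -1)
        buf[-1] = p
    return preds


def save_model(model: NNARXModel, path: str | Path) -> None:
    """Versioned text serialisation; floats round-trip exactly via repr."""
    if model.scaler is None:
        raise ValueError("refusing to save a model without a fitted scaler")
    doc = {
        "schema": MODEL_SCHEMA,
        "config": {
            "n_taps": model.config.n_taps,
            "hidden_sizes": list(model.config.hidden_sizes),
            "activation_hidden": model.config.activation_hidden,
            "seed": model.config.seed,
        },
        "scaler": {"lo": model.scaler.lo, "hi": model.scaler.hi},
        "mode": model.mode,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


class ModelLoadError(ValueError):
    """Model file is missing fields, corrupted, or from an unknown schema."""


def load_model(path: str | Path) -> NNARXModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelLoadError(f"{path}: not valid model JSON ({exc})") from exc
    schema = doc.get("schema")
    if schema != MODEL_SCHEMA:
        raise ModelLoadError(f"{path}: unsupported schema {schema!r}")
    for field in ("config", "scaler", "mode", "weights", "biases"):
        if field not in doc:
            raise ModelLoadError(f"{path}: missing field {field!r}")
    cfg = doc["config"]
    try:
        config = ModelConfig(
            n_taps=cfg["n_taps"],
            hidden_sizes=tuple(cfg["hidden_sizes"]),
            activation_hidden=cfg["activation_hidden"],
            seed=cfg["seed"],
        )
        scaler = Scaler(lo=doc["scaler"]["lo"], hi=doc["scaler"]["hi"])
        return NNARXModel(
            config=config,
            weights=tuple(np.array(w, dtype=float) for w in doc["weights"]),
            biases=tuple(np.array(b, dtype=float) for b in doc["biases"]),
            scaler=scaler,
            mode=doc["mode"],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelLoadError(f"{path}: {exc}") from exc
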