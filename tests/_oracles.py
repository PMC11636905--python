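"""Independent brute-force re-implementations used as oracles.

Everything here is written as plain per-index Python loops, deliberately
sharing no code with the package, so agreement is evidence of correctness
rather than of calling the same routine twice.
"""

import math

import numpy as np


def smooth_oracle(values, span):
    """Shrinking-symmetric-window moving average, one index at a time."""
    n = len(values)
    half = (span - 1) // 2
    out = []
    for i in range(n):
        h = min(i, n - 1 - i, half)
        window = values[i - h : i + h + 1]
        out.append(sum(window) / len(window))
    return out


def forward_oracle(model, taps):
    """Explicit-loop evaluation of the network on one tap vector (mmol/L)."""
    lo, hi = model.scaler.lo, model.scaler.hi
    a = [2.0 * (t - lo) / (hi - lo) - 1.0 for t in taps]
    n_layers = len(model.weights)
    for li in range(n_layers):
        w, b = model.weights[li], model.biases[li]
        nxt = []
        for j in range(w.shape[0]):
            s = b[j]
            for i in range(w.shape[1]):
                s += w[j, i] * a[i]
            nxt.append(math.tanh(s) if li < n_layers - 1 else s)
        a = nxt
    return (a[0] + 1.0) * (hi - lo) / 2.0 + lo


def recursion_oracle(model, seed_window, n_steps):
    """Explicit shifting-buffer recursion built on forward_oracle."""
    buf = list(seed_window)
    preds = []
    for _ in range(n_steps):
        p = forward_oracle(model, buf)
        preds.append(p)
        buf = buf[1:] + [p]
    return preds


def rmse_oracle(measured, predicted):
    s = 0.0
    for g, p in zip(measured, predicted):
        s += (g - p) ** 2
    return math.sqrt(s / len(measured))


def fit_oracle(measured, predicted):
    mean = sum(measured) / len(measured)
    num = math.sqrt(sum((g - p) ** 2 for g, p in zip(measured, predicted)))
    den = math.sqrt(sum((g - mean) ** 2 for g in measured))
    return (1.0 - num / den) * 100.0


def npe_oracle(measured, predicted):
    num = sum((g - p) ** 2 for g, p in zip(measured, predicted))
    den = sum(g**2 for g in measured)
    return math.sqrt(num / den) * 100.0


def clarke_oracle(r, p):
    """Independent statement of the error-grid rules, same precedence.

    Exact rational arithmetic keeps boundary points unambiguous."""
    from fractions import Fraction as F

    r, p = F(r), F(p)
    if (r <= 70 and p <= 70) or (p >= F(4, 5) * r and p <= F(6, 5) * r):
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    in_upper_c = 70 <= r <= 290 and p - r >= 110
    in_lower_c = 130 <= r <= 180 and p <= F(7, 5) * r - 182
    if in_upper_c or in_lower_c:
        return "C"
    in_right_d = r >= 240 and 70 <= p <= 180
    in_left_d = r <= F(175, 3) and 70 <= p <= 180
    in_wedge_d = F(175, 3) <= r <= 70 and p >= F(6, 5) * r
    if in_right_d or in_left_d or in_wedge_d:
        return "D"
    return "B"


def window_count_oracle(length, n_in, n_out, stride):
    """Count window start positions by explicit enumeration."""
    count = 0
    start = 0
    while start + n_in + n_out <= length:
        count += 1
        start += stride
    return count


def random_model(seed, n_taps=6, hidden=(5, 4)):
    """A small random network with a fitted scaler, for oracle tests."""
    from glynarx import ModelConfig, NNARXModel, Scaler

    rng = np.random.default_rng(seed)
    cfg = ModelConfig(n_taps=n_taps, hidden_sizes=hidden, seed=seed)
    sizes = cfg.layer_sizes
    weights = tuple(
        rng.normal(0, 0.7, size=(sizes[i + 1], sizes[i])) for i in range(len(sizes) - 1)
    )
    biases = tuple(rng.normal(0, 0.3, size=sizes[i + 1]) for i in range(len(sizes) - 1))
    return NNARXModel(
        config=cfg, weights=weights, biases=biases, scaler=Scaler(lo=3.0, hi=16.0)
    )
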