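"""Clarke error-grid analysis (EGA) for clinical accuracy of glucose forecasts.

Each (reference, predicted) glucose pair is assigned to one of five zones:

* **A** — clinically accurate (within 20% of reference, or both hypo <= 70);
* **B** — benign errors outside A that would not alter treatment;
* **C** — overcorrection: a normal reading predicted as hypo/hyper;
* **D** — dangerous failure to detect actual hypo- or hyperglycemia;
* **E** — hypo and hyper confused, treatment would be opposite to need.

Boundaries are the classic 1987 grid, defined in mg/dl; glucose in mmol/L
is converted with the molar-mass factor 18.0182 mg/dl per mmol/L (18.0 and
18.016 also circulate; the value is frozen here for reproducibility). Rules
are evaluated in the fixed precedence A, E, C, D, else B so that boundary
ties resolve deterministically to the earlier zone.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .metrics import PredictionResult
from .timeseries_io import MGDL_PER_MMOL

ZONES = ("A", "B", "C", "D", "E")


def mmol_to_mgdl(v):
    """Glucose mmol/L -> mg/dl (factor 18.0182)."""
    return np.multiply(v, MGDL_PER_MMOL)


def mgdl_to_mmol(v):
    """Exact inverse of :func:`mmol_to_mgdl`."""
    return np.divide(v, MGDL_PER_MMOL)


def classify_point(ref: float, pred: float) -> str:
    """Classify one (reference, predicted) pair in mg/dl into a zone A-E.

    Rules (R = reference, P = prediction), checked in order:

    * A: (R <= 70 and P <= 70) or (0.8 R <= P <= 1.2 R)
    * E: (R >= 180 and P <= 70) or (R <= 70 and P >= 180)
    * C: (70 <= R <= 290 and P >= R + 110) or
         (130 <= R <= 180 and P <= (7/5) R - 182)
    * D: (R >= 240 and 70 <= P <= 180) or (R <= 175/3 and 70 <= P <= 180) or
         (175/3 <= R <= 70 and P >= (6/5) R)
    * B: otherwise.
    """
    if not (np.isfinite(ref) and np.isfinite(pred)) or ref < 0 or pred < 0:
        raise ValueError(f"glucose must be finite and non-negative, got ({ref}, {pred})")
    r, p = float(ref), float(pred)
    # sloped boundaries are compared in integer-scaled form (5p vs 4r etc.)
    # so that points exactly on a boundary resolve to the earlier zone
    # regardless of binary rounding of 0.8, 1.2, 7/5, 6/5, 175/3
    if (r <= 70 and p <= 70) or (4 * r <= 5 * p <= 6 * r):
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and 5 * p <= 7 * r - 910):
        return "C"
    if (
        (r >= 240 and 70 <= p <= 180)
        or (3 * r <= 175 and 70 <= p <= 180)
        or (175 <= 3 * r <= 210 and 5 * p >= 6 * r)
    ):
        return "D"
    return "B"


@dataclasses.dataclass(frozen=True)
class ZoneSummary:
    """Per-zone percentages of prediction points (sum to 100)."""

    percent_A: float
    percent_B: float
    percent_C: float
    percent_D: float
    percent_E: float
    n_points: int

    def as_dict(self) -> dict[str, float]:
        return {z: getattr(self, f"percent_{z}") for z in ZONES}


def zone_summary(r: PredictionResult) -> ZoneSummary:
    """Classify every pair of a result (given in mmol/L) and tabulate
    zone percentages."""
    refs = mmol_to_mgdl(r.measured)
    preds = mmol_to_mgdl(r.predicted)
    counts = dict.fromkeys(ZONES, 0)
    for ref, pred in zip(refs, preds):
        counts[classify_point(ref, pred)] += 1
    n = len(r.measured)
    pct = {z: 100.0 * counts[z] / n for z in ZONES}
    return ZoneSummary(
        percent_A=pct["A"],
        percent_B=pct["B"],
        percent_C=pct["C"],
        percent_D=pct["D"],
        percent_E=pct["E"],
        n_points=n,
    )
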