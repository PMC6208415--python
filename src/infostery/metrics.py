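"""Confusion-matrix metrics reported as integer percentages.

Sensitivity, specificity, precision (PPV), accuracy, F1 and the Matthews
correlation coefficient, all rounded half-up to the nearest integer percent
(MCC included: an MCC of 0.40 is reported as 40).  A metric with a zero
denominator is reported as None (undefined), never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["Confusion", "confusion", "metrics_from_confusion"]


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: set, ref: set, universe: set) -> Confusion:
    """Standard confusion counts of a predicted set against a reference set."""
    pred, ref, universe = set(pred), set(ref), set(universe)
    if not pred <= universe:
        raise ValueError("predictions must lie within the universe")
    if not ref <= universe:
        raise ValueError("reference must lie within the universe")
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    tn = len(universe) - tp - fp - fn
    return Confusion(tp=tp, fp=fp, tn=tn, fn=fn)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _pct(num: float, den: float) -> int | None:
    if den == 0:
        return None
    return _round_half_up(100.0 * num / den)


def metrics_from_confusion(c: Confusion) -> dict[str, int | None]:
    """Six textbook metrics as integer percentages (half-up rounding)."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    out: dict[str, int | None] = {
        "sens": _pct(tp, tp + fn),
        "spe": _pct(tn, tn + fp),
        "ppv": _pct(tp, tp + fp),
        "acc": _pct(tp + tn, c.total),
        "f1": _pct(2 * tp, 2 * tp + fp + fn),
    }
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        out["mcc"] = None
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
        out["mcc"] = _round_half_up(100.0 * mcc)
    return out
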