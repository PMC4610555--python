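"""Transition-event evaluation against the footswitch reference.

The positive event is a phase *transition*. A predicted transition counts
as a true positive when a reference transition with the same (from, to)
phase pair lies within a tolerance window (default 60 ms, centred);
matching is greedy nearest-first and one-to-one. Sensitivity (TPR) and
specificity (TNR) feed the goodness index

    G = sqrt((1 - TPR)^2 + (1 - TNR)^2),

the Euclidean distance from the operating point to the perfect corner of
ROC space: G <= 0.25 is optimum, a chance-level classifier sits at
sqrt(2)/2 ~= 0.70, and larger values are bad.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .phases import PhaseSequence, transitions

RANDOM_G = math.sqrt(2.0) / 2.0


@dataclass
class EvalResult:
    """Confusion counts and derived indices for one classification."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def tnr(self) -> Optional[float]:
        d = self.fp + self.tn
        return self.tn / d if d else None

    @property
    def g(self) -> Optional[float]:
        if self.tpr is None or self.tnr is None:
            return None
        return goodness(self.tpr, self.tnr)

    @property
    def category(self) -> Optional[str]:
        return None if self.g is None else categorize(self.g)


def tolerance_halfwidth_samples(tol_ms: float, fs_hz: float,
                                rounding: str = "floor") -> int:
    """Half-width of the centred tolerance window, in samples.

    At 50 Hz a 60 ms centred window gives 1.5 samples, rounded down to
    +-1 sample by default; the rounding rule is configurable.
    """
    half = tol_ms / 2.0 * fs_hz / 1000.0
    if rounding == "floor":
        return int(math.floor(half))
    if rounding == "nearest":
        return int(round(half))
    if rounding == "ceil":
        return int(math.ceil(half))
    raise ValueError(f"unknown rounding rule {rounding!r}")


def transition_confusion(
    pred: PhaseSequence,
    ref: PhaseSequence,
    tol_ms: float = 60.0,
    rounding: str = "floor",
) -> EvalResult:
    """Confusion counts between predicted and reference transitions.

    Reference transitions matched one-to-one (greedy nearest-first, same
    phase pair, within the window) are TP; unmatched reference transitions
    are FN; unmatched predicted transitions are FP; the remaining
    non-transition samples are TN.
    """
    if pred.model_id != ref.model_id:
        raise ValueError("predicted and reference sequences use different models")
    if len(pred) != len(ref) or not math.isclose(pred.fs_hz, ref.fs_hz,
                                                 rel_tol=1e-6):
        raise ValueError("sequences must share length and sampling rate")

    half_w = tolerance_halfwidth_samples(tol_ms, ref.fs_hz, rounding)
    ref_ev = transitions(ref)
    pred_ev = transitions(pred)

    pairs = []
    for ri, r in enumerate(ref_ev):
        for pi, p in enumerate(pred_ev):
            if (p.from_phase, p.to_phase) != (r.from_phase, r.to_phase):
                continue
            dist = abs(p.sample_index - r.sample_index)
            if dist <= half_w:
                pairs.append((dist, ri, pi))
    pairs.sort()
    used_r: set[int] = set()
    used_p: set[int] = set()
    tp = 0
    for dist, ri, pi in pairs:
        if ri in used_r or pi in used_p:
            continue
        used_r.add(ri)
        used_p.add(pi)
        tp += 1

    fn = len(ref_ev) - tp
    fp = len(pred_ev) - tp
    tn = max(len(ref) - len(ref_ev) - fp, 0)
    return EvalResult(tp=tp, fp=fp, tn=tn, fn=fn)


def goodness(tpr: float, tnr: float) -> float:
    """Euclidean distance to the perfect-classifier corner of ROC space."""
    if not (0.0 <= tpr <= 1.0 and 0.0 <= tnr <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    return math.hypot(1.0 - tpr, 1.0 - tnr)


def categorize(g: float) -> str:
    """ROC quality band: optimum / good / random / bad."""
    if g < 0:
        raise ValueError("g must be nonnegative")
    if g <= 0.25:
        return "optimum"
    if abs(g - 0.70) <= 1e-9:
        return "random"
    if g < 0.70:
        return "good"
    return "bad"


def aggregate_study(
    results: pd.DataFrame,
    group_by: Sequence[str] = ("group", "condition", "model", "signal", "procedure"),
) -> pd.DataFrame:
    """Mean and SD (n-1 denominator) of G per cell of the study design.

    Rows with a missing G (degenerate confusion counts) are dropped with a
    warning; cells reduce to ``mean_G``, ``sd_G`` (0 flagged via ``n`` = 1)
    and the subject count ``n``.
    """
    if results.empty:
        raise ValueError("empty results table")
    df = results.copy()
    missing = df["G"].isna()
    if missing.any():
        import warnings

        warnings.warn(f"dropping {int(missing.sum())} rows with undefined G",
                      stacklevel=2)
        df = df[~missing]
    agg = (
        df.groupby(list(group_by), observed=True)["G"]
        .agg(mean_G="mean", sd_G=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    return agg
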