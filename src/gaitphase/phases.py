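"""Gait-phase vocabularies and footswitch-based reference partitioning.

Three partitioning granularities of the gait cycle are supported:

* 2P — stance (SP) / swing (SW);
* 4P — flat foot (FF), heel off (HO), swing (SW), heel strike (HS);
* 6P — initial contact (IC), loading response (LR), mid stance (MS),
  terminal stance (TS), pre swing (PS), swing (SW).

Each phase is recognised from the combination of active footswitches
(heel, 5th metatarsus, 1st metatarsus, toe). A phase rule consists of a
*required-active* set (all must be pressed, every other switch released)
and, for some phases, an *any-of* set (at least one pressed). Combinations
not covered by any rule are resolved by a most-specific-subset tier and,
failing that, by holding the previous phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Optional

import numpy as np
import pandas as pd

from .signals import FOOTSWITCH_CHANNELS, FootswitchSignal, align_footswitch

Switches = FrozenSet[str]
_ALL = frozenset(FOOTSWITCH_CHANNELS)


@dataclass(frozen=True)
class PhaseRule:
    """Footswitch rule for one phase.

    ``required`` switches must all be pressed; switches outside
    ``required | any_of`` must be released; when ``any_of`` is non-empty at
    least one of its switches must be pressed.
    """

    required: Switches = frozenset()
    any_of: Switches = frozenset()

    def matches(self, active: Switches) -> bool:
        if not self.required <= active:
            return False
        if active - self.required - self.any_of:
            return False
        if self.any_of and not (active & self.any_of):
            return False
        if not self.any_of and active != self.required:
            return False
        return True


@dataclass(frozen=True)
class PhaseModel:
    """One of the 2P/4P/6P gait-phase vocabularies."""

    model_id: str
    phases: tuple[str, ...]
    rules: dict[str, PhaseRule] = field(compare=False)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def index(self, label: str) -> int:
        return self.phases.index(label)

    def next_phase(self, label: str) -> str:
        return self.phases[(self.index(label) + 1) % self.n_phases]

    @property
    def cycle_start_phase(self) -> str:
        """Phase that cyclically follows swing — the heel-contact phase."""
        return self.next_phase("SW")


PHASE_MODELS: dict[str, PhaseModel] = {
    "2P": PhaseModel(
        "2P",
        ("SP", "SW"),
        {
            "SP": PhaseRule(any_of=_ALL),
            "SW": PhaseRule(),
        },
    ),
    "4P": PhaseModel(
        "4P",
        ("FF", "HO", "SW", "HS"),
        {
            "FF": PhaseRule(required=_ALL),
            "HO": PhaseRule(any_of=frozenset({"m5", "m1", "toe"})),
            "SW": PhaseRule(),
            "HS": PhaseRule(required=frozenset({"heel"})),
        },
    ),
    "6P": PhaseModel(
        "6P",
        ("IC", "LR", "MS", "TS", "PS", "SW"),
        {
            "IC": PhaseRule(required=frozenset({"heel"})),
            "LR": PhaseRule(required=frozenset({"heel", "m5"})),
            "MS": PhaseRule(required=frozenset({"heel", "m5", "m1"})),
            "TS": PhaseRule(required=frozenset({"m5", "m1"})),
            "PS": PhaseRule(required=frozenset({"toe"})),
            "SW": PhaseRule(),
        },
    ),
}

MODEL_IDS = tuple(PHASE_MODELS)


def get_model(model_id: str) -> PhaseModel:
    try:
        return PHASE_MODELS[model_id]
    except KeyError:
        raise ValueError(f"unknown phase model {model_id!r}") from None


@dataclass
class PhaseSequence:
    """Per-sample phase labelling of a trial."""

    model_id: str
    fs_hz: float
    labels: np.ndarray  # integer phase indices
    source: str = "reference"  # or "predicted"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size < 1:
            raise ValueError("phase sequence length >= 1 violated")
        n = get_model(self.model_id).n_phases
        if self.labels.min() < 0 or self.labels.max() >= n:
            raise ValueError("labels index phases outside the model")
        if self.source not in ("reference", "predicted"):
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def model(self) -> PhaseModel:
        return get_model(self.model_id)

    @property
    def label_names(self) -> list[str]:
        phases = self.model.phases
        return [phases[i] for i in self.labels]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.labels.size) / self.fs_hz

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "phase_label": self.label_names}).to_csv(
            path, index=False, float_format="%.12g"
        )

    @classmethod
    def from_csv(cls, path: str | Path, model_id: str, source: str = "reference") -> "PhaseSequence":
        df = pd.read_csv(path)
        model = get_model(model_id)
        labels = [model.index(lbl) for lbl in df["phase_label"]]
        t = df["time_s"].to_numpy(dtype=float)
        fs = 1.0 / np.median(np.diff(t)) if t.size >= 2 else 50.0
        return cls(model_id, float(fs), np.array(labels), source=source, t0=float(t[0]))


@dataclass(frozen=True)
class TransitionEvent:
    """A phase change, indexed at the first sample of the new phase."""

    sample_index: int
    from_phase: str
    to_phase: str


def classify_combo(
    active_switches: Switches | set[str],
    model: PhaseModel | str,
    previous_phase: Optional[str] = None,
) -> str:
    """Map a footswitch combination to a phase label.

    Resolution order:

    1. exact rule match (required switches pressed, all others released,
       any-of satisfied where defined);
    2. most-specific subset match — the phase whose (non-empty) required set
       is the largest subset of the active set, provided the maximum is
       unique; a tie is broken toward the immediate successor of
       ``previous_phase`` when that successor is among the tied phases;
    3. otherwise hold ``previous_phase``;
    4. with no previous phase, the model's heel-contact phase.

    Total and deterministic over all 16 combinations.
    """
    if isinstance(model, str):
        model = get_model(model)
    active = frozenset(active_switches)
    if not active <= _ALL:
        raise ValueError(f"unknown switches {set(active) - _ALL}")

    for phase in model.phases:
        if model.rules[phase].matches(active):
            return phase

    candidates = [
        p for p in model.phases
        if model.rules[p].required and model.rules[p].required <= active
    ]
    if candidates:
        best = max(len(model.rules[p].required) for p in candidates)
        tied = [p for p in candidates if len(model.rules[p].required) == best]
        if len(tied) == 1:
            return tied[0]
        if previous_phase is not None and model.next_phase(previous_phase) in tied:
            return model.next_phase(previous_phase)
        if previous_phase is None:
            return tied[0]

    if previous_phase is not None:
        return previous_phase
    return model.cycle_start_phase


def _combo_at(row: np.ndarray) -> Switches:
    return frozenset(c for c, v in zip(FOOTSWITCH_CHANNELS, row) if v)


def partition_trial(
    fs_sig: FootswitchSignal,
    model: PhaseModel | str,
    target_fs_hz: float = 50.0,
    times: Optional[np.ndarray] = None,
) -> PhaseSequence:
    """Convert a footswitch trace into a reference phase sequence.

    The trace is aligned onto the target rate (nearest original sample),
    then each sample's switch combination is classified with a running
    previous phase.
    """
    if isinstance(model, str):
        model = get_model(model)
    if fs_sig.channels.shape[0] == 0:
        raise ValueError("empty footswitch trace")
    if times is None:
        lo, hi = fs_sig.span
        n = int(np.floor((hi - lo) * target_fs_hz)) + 1
        times = lo + np.arange(n) / target_fs_hz
    else:
        times = np.asarray(times, dtype=float)
        target_fs_hz = 1.0 / np.median(np.diff(times)) if times.size >= 2 else target_fs_hz
    states = align_footswitch(fs_sig, times)

    labels = np.empty(states.shape[0], dtype=np.int64)
    prev: Optional[str] = None
    # cache: (combo bits, prev) -> label, to keep long trials cheap
    cache: dict[tuple[bytes, Optional[str]], str] = {}
    for i, row in enumerate(states):
        key = (row.tobytes(), prev)
        lbl = cache.get(key)
        if lbl is None:
            lbl = classify_combo(_combo_at(row), model, prev)
            cache[key] = lbl
        labels[i] = model.index(lbl)
        prev = lbl
    return PhaseSequence(model.model_id, float(target_fs_hz), labels,
                         source="reference", t0=float(times[0]))


def transitions(seq: PhaseSequence) -> list[TransitionEvent]:
    """All label changes, each at the first sample of the new phase."""
    phases = seq.model.phases
    idx = np.flatnonzero(np.diff(seq.labels)) + 1
    return [
        TransitionEvent(int(i), phases[seq.labels[i - 1]], phases[seq.labels[i]])
        for i in idx
    ]


def segment_cycles(seq: PhaseSequence) -> list[int]:
    """Cycle start indices: every transition into the heel-contact phase."""
    start = seq.model.cycle_start_phase
    starts = [
        ev.sample_index for ev in transitions(seq) if ev.to_phase == start
    ]
    if len(starts) < 2:
        import warnings

        warnings.warn("fewer than 2 cycle boundaries found", stacklevel=2)
        return []
    return starts
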