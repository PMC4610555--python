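"""Scalar and distributed gait-phase classifiers.

A scalar classifier decodes one segment's angular velocity through its own
HMM. A distributed classifier fuses the state posteriors of a foot and a
shank scalar classifier by a weighted (convex) combination and decodes the
fused scores through a "right-left-right" transition matrix that also allows
a one-step backward move, so a premature transition committed by one member
can be corrected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .hmm import (
    DecodeResult,
    HmmParams,
    LOG_FLOOR,
    fixed_lag_viterbi,
    log_emission_matrix,
    uniform_pi,
    viterbi,
    _log_mask,
    _viterbi_trellis,
    _backtrack,
)
from .phases import PhaseSequence, get_model
from .signals import GyroSignal

SIGNAL_SEGMENT = {"ft": "foot", "sh": "shank"}


@dataclass
class ScalarClassifier:
    """One HMM over one segment's sagittal angular velocity."""

    signal_source: str  # "ft" or "sh"
    model_id: str
    params: HmmParams
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal_source not in SIGNAL_SEGMENT:
            raise ValueError(f"unknown signal source {self.signal_source!r}")
        if self.params.n_states != get_model(self.model_id).n_phases:
            raise ValueError("params.n_states must equal the model phase count")


def classify_scalar(
    clf: ScalarClassifier,
    gyro: GyroSignal,
    decoder: str = "viterbi",
    lag_samples: Optional[int] = None,
) -> tuple[PhaseSequence, np.ndarray]:
    """Decode a gyro signal into a predicted phase sequence plus posteriors.

    ``decoder`` selects exact offline Viterbi (default) or ``"fixed_lag"``
    with the given lag.
    """
    if gyro.segment != SIGNAL_SEGMENT[clf.signal_source]:
        raise ValueError(
            f"classifier expects {SIGNAL_SEGMENT[clf.signal_source]} signal, "
            f"got {gyro.segment}"
        )
    if decoder == "viterbi":
        res = viterbi(clf.params, gyro.values)
    elif decoder == "fixed_lag":
        if lag_samples is None:
            raise ValueError("fixed_lag decoder requires lag_samples")
        res = fixed_lag_viterbi(clf.params, gyro.values, lag_samples)
    else:
        raise ValueError(f"unknown decoder {decoder!r}")
    seq = PhaseSequence(clf.model_id, gyro.fs_hz, res.states,
                        source="predicted", t0=gyro.t0)
    return seq, res.gamma


def build_A_dc(n_states: int, stay_prob: float = 0.9) -> np.ndarray:
    """Fusion transition matrix: self, next and previous phase only.

    ``a_ii = stay_prob`` and the two cyclic neighbours share the rest
    equally; every other entry is exactly zero.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if not 0 < stay_prob < 1:
        raise ValueError("stay_prob must lie in (0, 1)")
    A = np.zeros((n_states, n_states))
    off = (1.0 - stay_prob) / 2.0
    for i in range(n_states):
        A[i, i] = stay_prob
        A[i, (i + 1) % n_states] = off
        A[i, (i - 1) % n_states] += off
    return A


@dataclass
class DistributedClassifier:
    """Weighted hierarchical fusion of a foot and a shank scalar classifier."""

    members: tuple[ScalarClassifier, ScalarClassifier]
    weights: np.ndarray
    A_dc: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) != 2:
            raise ValueError("distributed classifier takes exactly two members")
        if self.members[0].model_id != self.members[1].model_id:
            raise ValueError("members must share the phase model")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (2,) or (self.weights < 0).any():
            raise ValueError("weights must be two nonnegative numbers")
        if not math.isclose(self.weights.sum(), 1.0, abs_tol=1e-10):
            raise ValueError("weights must sum to 1")
        self.A_dc = np.asarray(self.A_dc, dtype=float)
        n = get_model(self.model_id).n_phases
        if self.A_dc.shape != (n, n):
            raise ValueError("A_dc has the wrong shape")
        if not np.allclose(self.A_dc.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("A_dc rows must sum to 1")
        allowed = np.zeros((n, n), dtype=bool)
        for i in range(n):
            allowed[i, [i, (i + 1) % n, (i - 1) % n]] = True
        if (self.A_dc[~allowed] != 0).any():
            raise ValueError("A_dc must allow only self/next/previous moves")

    @property
    def model_id(self) -> str:
        return self.members[0].model_id


def fuse_posteriors(gammas: Sequence[np.ndarray], weights: np.ndarray) -> np.ndarray:
    """Convex combination of member posteriors, renormalised per sample."""
    s = sum(w * g for w, g in zip(weights, gammas))
    return s / s.sum(axis=1, keepdims=True)


def decode_scores(scores: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Viterbi path through ``A`` using per-sample scores as emission likelihoods."""
    logB = np.log(np.maximum(scores, 1e-300))
    logB = np.maximum(logB, LOG_FLOOR)
    logA = _log_mask(A)
    logpi = _log_mask(uniform_pi(A.shape[0]))
    delta, psi = _viterbi_trellis(logpi, logA, logB)
    T = logB.shape[0]
    last = int(np.argmax(delta[-1]))
    return _backtrack(psi, last, T - 1, 0)


def classify_distributed(
    dc: DistributedClassifier,
    gyro_ft: GyroSignal,
    gyro_sh: GyroSignal,
    member_gammas: Optional[Sequence[np.ndarray]] = None,
) -> PhaseSequence:
    """Fused phase sequence from foot and shank signals.

    Precomputed member posteriors may be supplied (e.g. when the scalar
    classifications are reused elsewhere in a study).
    """
    if gyro_ft.values.size != gyro_sh.values.size:
        raise ValueError("foot and shank signals must have equal length")
    if gyro_ft.fs_hz != gyro_sh.fs_hz:
        raise ValueError("foot and shank signals must share the sampling rate")
    if member_gammas is None:
        member_gammas = []
        for clf, gyro in zip(dc.members, (gyro_ft, gyro_sh)):
            gamma, _ = _forward_backward_for(clf, gyro)
            member_gammas.append(gamma)
    fused = fuse_posteriors(member_gammas, dc.weights)
    states = decode_scores(fused, dc.A_dc)
    return PhaseSequence(dc.model_id, gyro_ft.fs_hz, states,
                         source="predicted", t0=gyro_ft.t0)


def _forward_backward_for(clf: ScalarClassifier, gyro: GyroSignal):
    from .hmm import forward_backward

    if gyro.segment != SIGNAL_SEGMENT[clf.signal_source]:
        raise ValueError("segment mismatch")
    return forward_backward(clf.params, gyro.values)


def weights_from_goodness(g_values: Sequence[float]) -> np.ndarray:
    """Performance weights ``w_k`` proportional to ``sqrt(2) - G_k``."""
    w = np.sqrt(2.0) - np.asarray(g_values, dtype=float)
    w = np.clip(w, 1e-12, None)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Serialization

def save_classifier(clf: ScalarClassifier | DistributedClassifier,
                    path: str | Path) -> None:
    if isinstance(clf, ScalarClassifier):
        payload = {
            "kind": "SC",
            "signal_source": clf.signal_source,
            "model_id": clf.model_id,
            "phase_labels": list(get_model(clf.model_id).phases),
            **clf.params.to_dict(),
            "metadata": clf.meta,
        }
    else:
        payload = {
            "kind": "DC",
            "model_id": clf.model_id,
            "weights": clf.weights.tolist(),
            "A_dc": clf.A_dc.tolist(),
            "members": [
                {
                    "signal_source": m.signal_source,
                    **m.params.to_dict(),
                    "metadata": m.meta,
                }
                for m in clf.members
            ],
            "metadata": clf.meta,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_classifier(path: str | Path) -> ScalarClassifier | DistributedClassifier:
    d = json.loads(Path(path).read_text())
    if d["kind"] == "SC":
        return ScalarClassifier(
            d["signal_source"], d["model_id"], HmmParams.from_dict(d),
            meta=d.get("metadata", {}),
        )
    members = tuple(
        ScalarClassifier(m["signal_source"], d["model_id"],
                         HmmParams.from_dict(m), meta=m.get("metadata", {}))
        for m in d["members"]
    )
    return DistributedClassifier(members, np.array(d["weights"]),
                                 np.array(d["A_dc"]), meta=d.get("metadata", {}))
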