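"""Trial data model, CSV/YAML ingestion, filtering and resampling.

A trial couples the sagittal angular velocity of foot and shank (gyroscope,
nominally 50 Hz, deg/s) with a four-channel binary footswitch trace
(nominally 200 Hz; heel, 5th metatarsus, 1st metatarsus, toe) that serves as
the gait-phase reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

FOOTSWITCH_CHANNELS = ("heel", "m5", "m1", "toe")
GROUPS = ("TD", "HC")
CONDITIONS = ("L1.0", "L1.5", "I1.0", "I1.5")
SEGMENTS = ("foot", "shank")

#: minimum overlapping time span (s) required of the three signals of a trial
MIN_TRIAL_SPAN_S = 10.0


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class AlignmentError(ValueError):
    """Signals do not share a usable common time span."""


@dataclass
class GyroSignal:
    """Sagittal angular velocity of one body segment.

    Parameters
    ----------
    segment : {"foot", "shank"}
    values : ndarray of float
        Angular velocity in deg/s, one entry per sample.
    fs_hz : float
        Sampling rate, default 50 Hz.
    t0 : float
        Absolute time of the first sample, seconds.
    """

    segment: str
    values: np.ndarray
    fs_hz: float = 50.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("gyro signal length >= 2 violated")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gyro signal contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs_hz

    @property
    def span(self) -> tuple[float, float]:
        return self.t0, self.t0 + (self.values.size - 1) / self.fs_hz


@dataclass
class FootswitchSignal:
    """Four binary contact channels (heel, m5, m1, toe)."""

    channels: np.ndarray  # shape (T, 4), values in {0, 1}
    fs_hz: float = 200.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 2 or self.channels.shape[1] != 4:
            raise ValueError("footswitch channels must have shape (T, 4)")
        bad = ~np.isin(self.channels, (0, 1))
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise ValueError(f"non-binary footswitch value at row {row}")
        self.channels = self.channels.astype(np.int8)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.channels.shape[0]) / self.fs_hz

    @property
    def span(self) -> tuple[float, float]:
        return self.t0, self.t0 + (self.channels.shape[0] - 1) / self.fs_hz


@dataclass
class Trial:
    """One subject / walking-condition / repetition recording."""

    subject_id: str
    group: str
    condition: str
    repetition: int
    gyro_foot: GyroSignal
    gyro_shank: GyroSignal
    footswitch: FootswitchSignal
    # optional off-sagittal angular velocity, shape (T, 2): (frontal, transverse)
    offsag_foot: Optional[np.ndarray] = None
    offsag_shank: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.repetition not in (1, 2):
            raise ValueError("repetition must be 1 or 2")
        if self.gyro_foot.segment != "foot" or self.gyro_shank.segment != "shank":
            raise ValueError("gyro segments do not match their slots")
        lo = max(self.gyro_foot.span[0], self.gyro_shank.span[0], self.footswitch.span[0])
        hi = min(self.gyro_foot.span[1], self.gyro_shank.span[1], self.footswitch.span[1])
        if hi - lo < MIN_TRIAL_SPAN_S:
            raise ValueError(
                f"overlapping time span {hi - lo:.2f} s < {MIN_TRIAL_SPAN_S} s"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.condition, self.repetition)

    def gyro(self, segment: str) -> GyroSignal:
        if segment == "foot":
            return self.gyro_foot
        if segment == "shank":
            return self.gyro_shank
        raise ValueError(f"unknown segment {segment!r}")


class CohortDataset:
    """Collection of trials indexed by (subject_id, condition, repetition)."""

    def __init__(self, trials: Optional[list[Trial]] = None) -> None:
        self._trials: dict[tuple[str, str, int], Trial] = {}
        self._groups: dict[str, str] = {}
        for t in trials or []:
            self.add(t)

    def add(self, trial: Trial) -> None:
        if trial.key in self._trials:
            raise ValueError(f"duplicate trial key {trial.key}")
        prev = self._groups.get(trial.subject_id)
        if prev is not None and prev != trial.group:
            raise ValueError(
                f"subject {trial.subject_id} carries inconsistent group tags"
            )
        self._groups[trial.subject_id] = trial.group
        self._trials[trial.key] = trial

    def get(self, subject_id: str, condition: str, repetition: int) -> Trial:
        return self._trials[(subject_id, condition, repetition)]

    def __contains__(self, key: tuple[str, str, int]) -> bool:
        return key in self._trials

    def __len__(self) -> int:
        return len(self._trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self._trials.values())

    def subjects(self, group: Optional[str] = None) -> list[str]:
        subs = sorted(self._groups)
        if group is None:
            return subs
        return [s for s in subs if self._groups[s] == group]

    def group_of(self, subject_id: str) -> str:
        return self._groups[subject_id]

    @property
    def conditions(self) -> list[str]:
        return sorted({k[1] for k in self._trials}, key=CONDITIONS.index)


# ---------------------------------------------------------------------------
# CSV / YAML ingestion

def read_gyro_csv(path: str | Path, segment: str, fs_hz: float = 50.0) -> GyroSignal:
    """Read a gyro CSV with header ``time_s,gyro_sagittal_dps``."""
    df = pd.read_csv(path)
    for col in ("time_s", "gyro_sagittal_dps"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    fs = 1.0 / np.median(np.diff(t)) if t.size >= 2 else fs_hz
    return GyroSignal(
        segment=segment,
        values=df["gyro_sagittal_dps"].to_numpy(dtype=float),
        fs_hz=float(fs),
        t0=float(t[0]) if t.size else 0.0,
    )


def read_footswitch_csv(path: str | Path) -> FootswitchSignal:
    """Read a footswitch CSV with header ``time_s,heel,m5,m1,toe``."""
    df = pd.read_csv(path)
    for col in ("time_s",) + FOOTSWITCH_CHANNELS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    ch = df[list(FOOTSWITCH_CHANNELS)].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return FootswitchSignal(channels=ch, fs_hz=float(fs), t0=float(t[0]))


def read_trial(
    gyro_foot_path: str | Path,
    gyro_shank_path: str | Path,
    footswitch_path: str | Path,
    metadata: Mapping[str, object],
) -> Trial:
    """Assemble a validated :class:`Trial` from three CSV files.

    ``metadata`` must provide ``subject_id``, ``group``, ``condition`` and
    ``repetition``.
    """
    return Trial(
        subject_id=str(metadata["subject_id"]),
        group=str(metadata["group"]),
        condition=str(metadata["condition"]),
        repetition=int(metadata["repetition"]),  # type: ignore[arg-type]
        gyro_foot=read_gyro_csv(gyro_foot_path, "foot"),
        gyro_shank=read_gyro_csv(gyro_shank_path, "shank"),
        footswitch=read_footswitch_csv(footswitch_path),
    )


def write_gyro_csv(sig: GyroSignal, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": sig.times, "gyro_sagittal_dps": sig.values})
    df.to_csv(path, index=False, float_format="%.12g")


def write_footswitch_csv(sig: FootswitchSignal, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": sig.times})
    for i, name in enumerate(FOOTSWITCH_CHANNELS):
        df[name] = sig.channels[:, i]
    df.to_csv(path, index=False, float_format="%.12g")


def write_trial(trial: Trial, directory: str | Path) -> dict[str, str]:
    """Write a trial's three CSVs; returns relative file names."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{trial.condition}_r{trial.repetition}"
    names = {
        "gyro_foot": f"{stem}_gyro_foot.csv",
        "gyro_shank": f"{stem}_gyro_shank.csv",
        "footswitch": f"{stem}_footswitch.csv",
    }
    write_gyro_csv(trial.gyro_foot, directory / names["gyro_foot"])
    write_gyro_csv(trial.gyro_shank, directory / names["gyro_shank"])
    write_footswitch_csv(trial.footswitch, directory / names["footswitch"])
    return names


def write_cohort(cohort: CohortDataset, directory: str | Path) -> Path:
    """Write every trial plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": []}
    for sid in cohort.subjects():
        entry = {"subject_id": sid, "group": cohort.group_of(sid), "trials": []}
        for trial in sorted(
            (t for t in cohort if t.subject_id == sid),
            key=lambda t: (CONDITIONS.index(t.condition), t.repetition),
        ):
            names = write_trial(trial, directory / sid)
            entry["trials"].append(
                {
                    "condition": trial.condition,
                    "repetition": trial.repetition,
                    **{k: f"{sid}/{v}" for k, v in names.items()},
                }
            )
        manifest["subjects"].append(entry)
    out = directory / "manifest.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out


def read_cohort(manifest_path: str | Path) -> CohortDataset:
    """Load a cohort from a YAML manifest produced by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    root = manifest_path.parent
    cohort = CohortDataset()
    for entry in manifest["subjects"]:
        for tr in entry["trials"]:
            cohort.add(
                read_trial(
                    root / tr["gyro_foot"],
                    root / tr["gyro_shank"],
                    root / tr["footswitch"],
                    {
                        "subject_id": entry["subject_id"],
                        "group": entry["group"],
                        "condition": tr["condition"],
                        "repetition": tr["repetition"],
                    },
                )
            )
    return cohort


# ---------------------------------------------------------------------------
# Preprocessing

def lowpass_filter(sig: GyroSignal, cutoff_hz: float = 15.0, order: int = 4) -> GyroSignal:
    """Zero-phase Butterworth low-pass filter.

    Applied forward-backward (``filtfilt``) so phase transitions are not
    delayed; the effective magnitude response is the squared Butterworth
    response of the given order.
    """
    if not 0 < cutoff_hz < sig.fs_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz outside (0, Nyquist={sig.fs_hz / 2} Hz)"
        )
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=sig.fs_hz)
    filtered = sps.filtfilt(b, a, sig.values)
    return replace(sig, values=filtered)


def align_footswitch(fs_sig: FootswitchSignal, times: np.ndarray) -> np.ndarray:
    """Footswitch state at each requested time, taken at the nearest sample.

    Returns an integer array of shape (len(times), 4).
    """
    times = np.asarray(times, dtype=float)
    lo, hi = fs_sig.span
    half = 0.5 / fs_sig.fs_hz
    if times.size == 0 or times[0] < lo - half or times[-1] > hi + half:
        raise AlignmentError(
            "requested times fall outside the footswitch time span"
        )
    idx = np.rint((times - fs_sig.t0) * fs_sig.fs_hz).astype(int)
    idx = np.clip(idx, 0, fs_sig.channels.shape[0] - 1)
    return fs_sig.channels[idx]


def align_footswitch_to_gyro(
    fs_sig: FootswitchSignal, target_fs_hz: float, t0: Optional[float] = None,
    n_samples: Optional[int] = None,
) -> FootswitchSignal:
    """Resample a footswitch trace onto a gyro-rate grid (nearest sample).

    The grid starts at ``t0`` (default: the footswitch start) and covers the
    footswitch span, or exactly ``n_samples`` ticks when given.
    """
    if t0 is None:
        t0 = fs_sig.t0
    if n_samples is None:
        lo, hi = fs_sig.span
        if t0 > hi:
            raise AlignmentError("target grid starts after the footswitch ends")
        n_samples = int(np.floor((hi - t0) * target_fs_hz)) + 1
    times = t0 + np.arange(n_samples) / target_fs_hz
    ch = align_footswitch(fs_sig, times)
    return FootswitchSignal(channels=ch, fs_hz=target_fs_hz, t0=t0)


def overlap_grid(trial: Trial, fs_hz: float = 50.0) -> np.ndarray:
    """Common time grid of a trial's three signals at the gyro rate.

    Uses the intersecting span when the signals disagree in length, warning
    once per trial.
    """
    lo = max(trial.gyro_foot.span[0], trial.gyro_shank.span[0], trial.footswitch.span[0])
    hi = min(trial.gyro_foot.span[1], trial.gyro_shank.span[1], trial.footswitch.span[1])
    full = (
        min(trial.gyro_foot.span[0], trial.gyro_shank.span[0], trial.footswitch.span[0]),
        max(trial.gyro_foot.span[1], trial.gyro_shank.span[1], trial.footswitch.span[1]),
    )
    if (lo, hi) != full:
        warnings.warn(
            f"trial {trial.key}: signals disagree in span; using [{lo:.3f}, {hi:.3f}] s",
            stacklevel=2,
        )
    n = int(np.floor((hi - lo) * fs_hz)) + 1
    return lo + np.arange(n) / fs_hz
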