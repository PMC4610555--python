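"""Synthetic pediatric-gait cohorts: phase-structured gyro + footswitch data.

The generator emulates treadmill walking recorded by a sagittal gyroscope on
foot and shank (50 Hz) and a four-channel footswitch insole (200 Hz). Each
stride follows a six-phase script (IC, LR, MS, TS, PS, SW) whose footswitch
combination progression is, by default,

    {heel} -> {heel,m5} -> {heel,m5,m1} -> {heel,m5,m1,toe}
           -> {m5,m1,toe} -> {toe} -> {}

so that partitioning the generated footswitch trace reproduces the emitted
phase script exactly on noise-free trials (the all-four and three-forefoot
combinations resolve through the specificity tier to MS and TS). A "strict"
progression restricted to the tabulated combinations is available for
exact-rule tests; it contains no all-four segment, hence no flat-foot phase
in the 4P reference, and is not suitable for 4P training.

Waveforms are piecewise-smooth per-phase segments (linear trend plus one or
two sinusoidal harmonics, continuous at phase boundaries) whose amplitudes
are free template parameters — plausible in shape and separation, but not
biomechanically validated recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .phases import PHASE_MODELS, PhaseSequence
from .signals import CohortDataset, FootswitchSignal, GyroSignal, Trial, CONDITIONS

PHASES_6P = PHASE_MODELS["6P"].phases  # IC, LR, MS, TS, PS, SW

# combo progression: (switch tuple, 6P phase it maps to)
_DEFAULT_COMBOS = (
    (("heel",), "IC"),
    (("heel", "m5"), "LR"),
    (("heel", "m5", "m1"), "MS"),
    (("heel", "m5", "m1", "toe"), "MS"),
    (("m5", "m1", "toe"), "TS"),
    (("toe",), "PS"),
    ((), "SW"),
)
_STRICT_COMBOS = (
    (("heel",), "IC"),
    (("heel", "m5"), "LR"),
    (("heel", "m5", "m1"), "MS"),
    (("m5", "m1"), "TS"),
    (("toe",), "PS"),
    ((), "SW"),
)

_CHANNEL_IDX = {"heel": 0, "m5": 1, "m1": 2, "toe": 3}

# condition modifiers: (cadence factor, amplitude factor, shank amplitude factor)
CONDITION_MODIFIERS = {
    "L1.0": (1.00, 1.00, 1.00),
    "L1.5": (1.18, 1.10, 1.00),
    "I1.0": (0.97, 1.00, 1.15),
    "I1.5": (1.14, 1.10, 1.15),
}


@dataclass
class SegmentWaveform:
    """Per-combo-segment waveform parameters for one segment (deg/s).

    ``level`` is the characteristic angular-velocity plateau of each of the
    seven combo segments of a stride (heel strike, loading, early mid
    stance, forefoot-loaded mid stance, heel-off/terminal stance, push-off,
    swing); consecutive levels are joined by short cosine ramps centered at
    the segment boundary, mimicking the rapid velocity changes at the
    mechanical gait events. Boundaries without a real kinematic event
    (e.g. first-metatarsal contact) get nearly equal neighbouring levels,
    which is what makes the finer phase models genuinely harder to decode.
    ``amp``/``amp2`` add ``sin(pi s)`` / ``sin(2 pi s)`` bumps within a
    segment (vanishing at its edges), used for the swing peak.
    """

    level: np.ndarray  # (7,)
    amp: np.ndarray  # (7,)
    amp2: np.ndarray  # (7,)

    def __post_init__(self) -> None:
        self.level = np.asarray(self.level, dtype=float)
        self.amp = np.asarray(self.amp, dtype=float)
        self.amp2 = np.asarray(self.amp2, dtype=float)
        for arr in (self.level, self.amp, self.amp2):
            if arr.shape != (7,):
                raise ValueError("waveform parameters need one entry per combo segment")


def _default_foot() -> SegmentWaveform:
    # near-zero foot rotation while the sole is loaded; spikes at heel
    # strike and push-off; large positive swing peak
    return SegmentWaveform(
        level=np.array([-60.0, 0.0, 2.0, 18.0, -35.0, -120.0, 170.0]),
        amp=np.array([0.0, 0.0, 0.0, 0.0, 0.0, -40.0, 120.0]),
        amp2=np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 80.0]),
    )


def _default_shank() -> SegmentWaveform:
    # double-peaked swing bump (second harmonic); stance levels closer
    # together than the foot's, as in pediatric shank recordings
    return SegmentWaveform(
        level=np.array([-40.0, -6.0, -3.0, 8.0, -25.0, -90.0, 130.0]),
        amp=np.array([0.0, 0.0, 0.0, 0.0, 0.0, -30.0, 60.0]),
        amp2=np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, -70.0]),
    )


@dataclass
class GaitTemplate:
    """Nominal stride structure of one (synthetic) walker."""

    cadence_spm: float = 42.0  # strides per minute
    #: 6P phase duration fractions (IC, LR, MS, TS, PS, SW), summing to 1
    fractions: np.ndarray = field(
        default_factory=lambda: np.array([0.04, 0.07, 0.28, 0.13, 0.08, 0.40])
    )
    #: portion of MS spent with all four switches pressed (forefoot loaded)
    ms_split: float = 0.75
    #: half-width (s) of the cosine ramp joining phase plateaus
    ramp_s: float = 0.02
    foot: SegmentWaveform = field(default_factory=_default_foot)
    shank: SegmentWaveform = field(default_factory=_default_shank)
    strict_combos: bool = False
    #: relative magnitude of off-sagittal components (3-axis mode); 0 disables
    offsag_scale: float = 0.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (6,) or (self.fractions <= 0).any():
            raise ValueError("need six positive phase fractions")
        if not math.isclose(self.fractions.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("phase fractions must sum to 1")
        if not self.cadence_spm > 0:
            raise ValueError("cadence must be positive")
        if not 0.0 < self.ms_split < 1.0:
            raise ValueError("ms_split must lie in (0, 1)")

    @property
    def stride_s(self) -> float:
        return 60.0 / self.cadence_spm

    def check_resolvable(self, fs_gyro: float = 50.0) -> None:
        """Every phase must span at least 2 gyro samples per stride."""
        samples = self.fractions * self.stride_s * fs_gyro
        if (samples < 2).any():
            short = PHASES_6P[int(np.argmin(samples))]
            raise ValueError(
                f"phase {short} shorter than 2 samples at {fs_gyro} Hz"
            )

    def combo_segments(self) -> list[tuple[tuple[str, ...], str, float, int]]:
        """(switch combo, phase, duration fraction, waveform-level index)
        per stride segment."""
        f = self.fractions
        if self.strict_combos:
            fracs = [f[0], f[1], f[2], f[3], f[4], f[5]]
            idx = [0, 1, 2, 4, 5, 6]
            return [
                (c, p, fr, k)
                for (c, p), fr, k in zip(_STRICT_COMBOS, fracs, idx)
            ]
        fracs = [f[0], f[1], f[2] * (1 - self.ms_split), f[2] * self.ms_split,
                 f[3], f[4], f[5]]
        return [(c, p, fr, k)
                for (c, p), fr, k in zip(_DEFAULT_COMBOS, fracs, range(7))]


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults follow the study conditions: ten subjects per group, four
    walking conditions, two repetitions of at least 60 s each; children
    with hemiplegia carry a higher intra-subject (stride-to-stride)
    variability than typically developed children.
    """

    n_subjects: int = 10
    group: str = "TD"
    conditions: tuple[str, ...] = CONDITIONS
    duration_s: float = 60.0
    inter_subject_sd: float = 0.06
    intra_subject_sd: Optional[float] = None  # default 0.03 TD / 0.08 HC
    noise_sd: float = 12.0  # additive gyro noise, deg/s
    seed: int = 0
    template: GaitTemplate = field(default_factory=GaitTemplate)
    three_axis: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("TD", "HC"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.intra_subject_sd is None:
            self.intra_subject_sd = 0.03 if self.group == "TD" else 0.08
        for name in ("inter_subject_sd", "intra_subject_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {bad}")


# ---------------------------------------------------------------------------
# Stride timeline construction

def _stride_plan(template: GaitTemplate, duration_s: float,
                 rng: np.random.Generator, intra_sd: float,
                 frac_factors: np.ndarray, fs_gyro: float = 50.0):
    """List of (start_time, duration, fractions) strides covering a trial."""
    strides = []
    t = 0.0
    base_d = template.stride_s
    while t < duration_s:
        d = base_d * float(np.clip(1.0 + rng.normal(0.0, intra_sd), 0.6, 1.6))
        fr = template.fractions * frac_factors
        fr = fr * np.clip(1.0 + rng.normal(0.0, intra_sd, 6), 0.5, 1.5)
        # keep every phase resolvable at the gyro rate despite jitter
        fr = np.maximum(fr / fr.sum(), 2.5 / (d * fs_gyro))
        fr = fr / fr.sum()
        strides.append((t, d, fr))
        t += d
    return strides


def _segment_tables(template: GaitTemplate, strides):
    """Absolute combo/phase boundary times across the whole trial."""
    combo_times: list[float] = []
    combo_rows: list[np.ndarray] = []
    phase_times: list[float] = []
    phase_ids: list[int] = []
    segs = template.combo_segments()
    for t0, d, fr in strides:
        edges = _segment_edges(template, (t0, d, fr))
        prev_phase = None
        for k, (combo, phase, _, _) in enumerate(segs):
            row = np.zeros(4, dtype=np.int8)
            for c in combo:
                row[_CHANNEL_IDX[c]] = 1
            combo_times.append(edges[k])
            combo_rows.append(row)
            if phase != prev_phase:
                phase_times.append(edges[k])
                phase_ids.append(PHASES_6P.index(phase))
                prev_phase = phase
    return (np.array(combo_times), np.array(combo_rows),
            np.array(phase_times), np.array(phase_ids, dtype=np.int64))


def _segment_edges(template: GaitTemplate, stride) -> np.ndarray:
    """Absolute combo-segment edge times of one stride (n_seg + 1 values).

    Segment fractions are rescaled to the stride's jittered phase
    fractions so footswitch, phase script and waveform share edge floats.
    """
    t0, d, fr = stride
    seg_fr = []
    for combo, phase, base_fr, _ in template.combo_segments():
        pi = PHASES_6P.index(phase)
        share = base_fr / template.fractions[pi]
        seg_fr.append(fr[pi] * share)
    return t0 + d * np.concatenate([[0.0], np.cumsum(seg_fr)])


def _sample_waveform(times: np.ndarray, strides, template: GaitTemplate,
                     wf: SegmentWaveform, scale: float,
                     amp_jitters: np.ndarray) -> np.ndarray:
    values = np.empty(times.size)
    segs = template.combo_segments()
    lvl_idx = [k for _, _, _, k in segs]
    n_seg = len(segs)
    starts = np.array([s[0] for s in strides])
    stride_idx = np.clip(np.searchsorted(starts, times, side="right") - 1,
                         0, len(strides) - 1)
    h = template.ramp_s
    for si in range(len(strides)):
        mask = stride_idx == si
        if not mask.any():
            continue
        tt = times[mask]
        edges = _segment_edges(template, strides[si])
        ph = np.clip(np.searchsorted(edges, tt, side="right") - 1, 0, n_seg - 1)
        v = np.empty(tt.size)
        for p in range(n_seg):
            m = ph == p
            if not m.any():
                continue
            t_p = tt[m]
            width = edges[p + 1] - edges[p]
            s = (t_p - edges[p]) / width
            k = lvl_idx[p]
            lvl = np.full(t_p.size, wf.level[k])
            # cosine ramps centred on the segment boundaries
            dl = t_p - edges[p]
            left = dl < h
            if left.any():
                u = dl[left] / h
                l_prev = wf.level[lvl_idx[(p - 1) % n_seg]]
                lvl[left] = l_prev + (wf.level[k] - l_prev) * (
                    0.5 + 0.5 * np.sin(np.pi / 2 * u)
                )
            dr = edges[p + 1] - t_p
            right = (dr < h) & ~left
            if right.any():
                u = dr[right] / h
                l_next = wf.level[lvl_idx[(p + 1) % n_seg]]
                lvl[right] = l_next + (wf.level[k] - l_next) * (
                    0.5 + 0.5 * np.sin(np.pi / 2 * u)
                )
            v[m] = lvl + wf.amp[k] * np.sin(np.pi * s) + wf.amp2[k] * np.sin(
                2 * np.pi * s
            )
            v[m] *= scale * amp_jitters[si]
        values[mask] = v
    return values


def generate_cycle(
    template: GaitTemplate,
    rng: Optional[np.random.Generator] = None,
    fs_gyro: float = 50.0,
    fs_fsw: float = 200.0,
    noise_sd: float = 0.0,
    intra_sd: float = 0.0,
):
    """One gait cycle: (foot gyro, shank gyro, 6P script, footswitch channels).

    The footswitch script traverses the template's combo progression; its
    partition under the 6P rules equals the emitted phase script exactly
    when ``noise_sd`` is zero.
    """
    template.check_resolvable(fs_gyro)
    rng = rng or np.random.default_rng(0)
    strides = _stride_plan(template, 1e-12, rng, intra_sd, np.ones(6), fs_gyro)[:1]
    d = strides[0][1]
    t_gyro = np.arange(int(round(d * fs_gyro))) / fs_gyro
    t_fsw = np.arange(int(round(d * fs_fsw))) / fs_fsw
    combo_t, combo_rows, phase_t, phase_ids = _segment_tables(template, strides)
    fsw = combo_rows[np.clip(np.searchsorted(combo_t, t_fsw, side="right") - 1,
                             0, len(combo_t) - 1)]
    script = phase_ids[np.clip(np.searchsorted(phase_t, t_gyro, side="right") - 1,
                               0, len(phase_t) - 1)]
    foot = _sample_waveform(t_gyro, strides, template, template.foot, 1.0,
                            np.ones(len(strides)))
    shank = _sample_waveform(t_gyro, strides, template, template.shank, 1.0,
                             np.ones(len(strides)))
    if noise_sd > 0:
        foot = foot + rng.normal(0.0, noise_sd, foot.size)
        shank = shank + rng.normal(0.0, noise_sd, shank.size)
    return foot, shank, script, fsw


def generate_trial(
    template: GaitTemplate,
    subject_id: str,
    group: str,
    condition: str,
    repetition: int,
    duration_s: float,
    rng: np.random.Generator,
    intra_sd: float,
    noise_sd: float,
    amp_factors: tuple[float, float] = (1.0, 1.0),
    frac_factors: Optional[np.ndarray] = None,
    three_axis: bool = False,
    fs_gyro: float = 50.0,
    fs_fsw: float = 200.0,
) -> tuple[Trial, PhaseSequence]:
    """One synthetic trial plus its emitted 6P phase script (at gyro rate)."""
    cad_f, amp_f, shank_f = CONDITION_MODIFIERS[condition]
    tpl = replace(template, cadence_spm=template.cadence_spm * cad_f)
    tpl.check_resolvable(fs_gyro)
    if frac_factors is None:
        frac_factors = np.ones(6)

    strides = _stride_plan(tpl, duration_s, rng, intra_sd, frac_factors, fs_gyro)
    n_gyro = int(round(duration_s * fs_gyro))
    n_fsw = int(round(duration_s * fs_fsw))
    t_gyro = np.arange(n_gyro) / fs_gyro
    t_fsw = np.arange(n_fsw) / fs_fsw

    combo_t, combo_rows, phase_t, phase_ids = _segment_tables(tpl, strides)
    fsw = combo_rows[np.clip(np.searchsorted(combo_t, t_fsw, side="right") - 1,
                             0, len(combo_t) - 1)]
    script = phase_ids[np.clip(np.searchsorted(phase_t, t_gyro, side="right") - 1,
                               0, len(phase_t) - 1)]

    amp_jit = np.clip(1.0 + rng.normal(0.0, intra_sd, len(strides)), 0.5, 1.5)
    scale_ft = amp_f * amp_factors[0]
    scale_sh = amp_f * shank_f * amp_factors[1]
    foot = _sample_waveform(t_gyro, strides, tpl, tpl.foot, scale_ft, amp_jit)
    shank = _sample_waveform(t_gyro, strides, tpl, tpl.shank, scale_sh, amp_jit)
    if noise_sd > 0:
        foot = foot + rng.normal(0.0, noise_sd, n_gyro)
        shank = shank + rng.normal(0.0, noise_sd, n_gyro)

    offsag_foot = offsag_shank = None
    if three_axis:
        k = tpl.offsag_scale
        offsag_foot = np.column_stack([0.4 * k * foot, 0.25 * k * foot])
        offsag_shank = np.column_stack([0.4 * k * shank, 0.25 * k * shank])

    trial = Trial(
        subject_id=subject_id,
        group=group,
        condition=condition,
        repetition=repetition,
        gyro_foot=GyroSignal("foot", foot, fs_gyro, 0.0),
        gyro_shank=GyroSignal("shank", shank, fs_gyro, 0.0),
        footswitch=FootswitchSignal(fsw, fs_fsw, 0.0),
        offsag_foot=offsag_foot,
        offsag_shank=offsag_shank,
    )
    script_seq = PhaseSequence("6P", fs_gyro, script, source="reference", t0=0.0)
    return trial, script_seq


def subject_template(template: GaitTemplate, rng: np.random.Generator,
                     inter_sd: float):
    """Per-subject perturbation: timing, amplitude and fraction factors."""
    timing = float(np.clip(1.0 + rng.normal(0.0, inter_sd), 0.7, 1.3))
    amp_ft = float(np.clip(1.0 + rng.normal(0.0, inter_sd), 0.6, 1.4))
    amp_sh = float(np.clip(1.0 + rng.normal(0.0, inter_sd), 0.6, 1.4))
    frac = np.clip(1.0 + rng.normal(0.0, inter_sd / 2.0, 6), 0.8, 1.2)
    tpl = replace(template, cadence_spm=template.cadence_spm / timing)
    return tpl, (amp_ft, amp_sh), frac


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Fully reproducible synthetic cohort per the study design.

    Returns every subject x condition x repetition trial; the emitted 6P
    phase scripts can be re-derived at any time by partitioning the
    footswitch traces.
    """
    ss = np.random.SeedSequence(spec.seed)
    subject_seeds = ss.spawn(spec.n_subjects)
    cohort = CohortDataset()
    for i in range(spec.n_subjects):
        sid = f"{spec.group}{i + 1:02d}"
        s_ss = subject_seeds[i]
        base_rng = np.random.default_rng(s_ss)
        tpl, amp_factors, frac_factors = subject_template(
            spec.template, base_rng, spec.inter_subject_sd
        )
        trial_seeds = s_ss.spawn(len(spec.conditions) * 2)
        k = 0
        for cond in spec.conditions:
            for rep in (1, 2):
                rng = np.random.default_rng(trial_seeds[k])
                k += 1
                trial, _ = generate_trial(
                    tpl, sid, spec.group, cond, rep, spec.duration_s, rng,
                    intra_sd=spec.intra_subject_sd, noise_sd=spec.noise_sd,
                    amp_factors=amp_factors, frac_factors=frac_factors,
                    three_axis=spec.three_axis,
                )
                cohort.add(trial)
    return cohort


# ---------------------------------------------------------------------------
# IMU-misalignment sensitivity

def perturb_rotation(trial: Trial, angles_deg: tuple[float, float]) -> Trial:
    """Rotate the 3-axis angular-velocity vector and re-extract the sagittal
    component, emulating IMU misalignment; footswitches are unchanged.

    ``angles_deg`` are rotations about the frontal and transverse axes.
    Requires a trial generated in 3-axis mode.
    """
    if trial.offsag_foot is None or trial.offsag_shank is None:
        raise ValueError(
            "trial has no off-sagittal components; generate with three_axis=True"
        )
    a = math.radians(angles_deg[0])
    b = math.radians(angles_deg[1])
    # rotation about the frontal axis mixes sagittal and transverse components;
    # rotation about the transverse axis mixes sagittal and frontal components
    Rf = np.array([[math.cos(a), 0.0, -math.sin(a)],
                   [0.0, 1.0, 0.0],
                   [math.sin(a), 0.0, math.cos(a)]])
    Rt = np.array([[math.cos(b), -math.sin(b), 0.0],
                   [math.sin(b), math.cos(b), 0.0],
                   [0.0, 0.0, 1.0]])
    R = Rt @ Rf

    def rotate(sag: np.ndarray, offsag: np.ndarray):
        v = np.column_stack([sag, offsag])  # (T, 3): sagittal, frontal, transverse
        w = v @ R.T
        return w[:, 0], w[:, 1:]

    foot, off_ft = rotate(trial.gyro_foot.values, trial.offsag_foot)
    shank, off_sh = rotate(trial.gyro_shank.values, trial.offsag_shank)
    return Trial(
        subject_id=trial.subject_id,
        group=trial.group,
        condition=trial.condition,
        repetition=trial.repetition,
        gyro_foot=replace(trial.gyro_foot, values=foot),
        gyro_shank=replace(trial.gyro_shank, values=shank),
        footswitch=trial.footswitch,
        offsag_foot=off_ft,
        offsag_shank=off_sh,
    )
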