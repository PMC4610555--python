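"""Training protocols: subject-specific (SST) and standardized-parameter (SPT).

SST trains each classifier on a subject's own first repetition of a walking
condition and tests it on the second repetition. SPT builds a standardized
parameter set from the healthy (TD) cohort: every included TD subject's
first-repetition strides are time-normalized, averaged within subject, then
averaged across subjects into a paradigmatic cycle; a TD test subject is
left out of its own training set (leave-one-out), while hemiplegic (HC)
subjects are always tested against the full TD template.

The factorial design crosses {SST, SPT} x {2P, 4P, 6P} x {foot SC, shank
SC, foot+shank DC}, giving the 18 classifier configurations of the study.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    DistributedClassifier,
    ScalarClassifier,
    build_A_dc,
    classify_distributed,
    classify_scalar,
    fuse_posteriors,
    decode_scores,
)
from .evaluation import EvalResult, transition_confusion
from .hmm import HmmParams, baum_welch, build_left_right_A, forward_backward, uniform_pi
from .phases import PhaseSequence, get_model, partition_trial, segment_cycles
from .signals import CohortDataset, GyroSignal, Trial, lowpass_filter

PROCEDURES = ("SST", "SPT")
SIGNALS = ("ft", "sh", "ftsh")
_SEGMENT_OF = {"ft": "foot", "sh": "shank"}


@dataclass(frozen=True)
class ClassifierSpec:
    """One cell of the classifier taxonomy."""

    procedure: str  # SST | SPT
    model_id: str  # 2P | 4P | 6P
    signal: str  # ft | sh | ftsh
    kind: str  # SC | DC

    def __post_init__(self) -> None:
        if self.procedure not in PROCEDURES:
            raise ValueError(f"unknown procedure {self.procedure!r}")
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")
        if self.kind not in ("SC", "DC"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if (self.kind == "DC") != (self.signal == "ftsh"):
            raise ValueError("kind must be DC exactly when signal is ftsh")
        get_model(self.model_id)

    @property
    def code(self) -> str:
        return f"{self.procedure}_{self.model_id}_{self.signal}_{self.kind}"

    @property
    def table_code(self) -> str:
        """Compact study-table naming, e.g. ``S2pPTshSC``."""
        tr = "ST" if self.procedure == "SST" else "PT"
        return f"S{self.model_id.lower()}{tr}{self.signal}{self.kind}"

    @classmethod
    def from_code(cls, code: str) -> "ClassifierSpec":
        parts = code.split("_")
        if len(parts) != 4:
            raise ValueError(f"malformed classifier code {code!r}")
        return cls(*parts)


def enumerate_classifiers() -> list[ClassifierSpec]:
    """All 18 classifier configurations of the factorial design."""
    specs = []
    for proc, model in itertools.product(PROCEDURES, ("2P", "4P", "6P")):
        for signal in SIGNALS:
            kind = "DC" if signal == "ftsh" else "SC"
            specs.append(ClassifierSpec(proc, model, signal, kind))
    return specs


@dataclass
class TrainConfig:
    """Tunable knobs of preprocessing, training and evaluation."""

    cutoff_hz: float = 15.0
    filter_order: int = 4
    fs_hz: float = 50.0
    l_norm: int = 100  # samples per normalized phase occurrence
    l_cycle: int = 200  # samples per normalized cycle (SPT template)
    spt_cycles: int = 10  # template cycles concatenated for EM refinement
    refine: bool = True  # Baum-Welch refinement after supervised init
    bw_max_iter: int = 10
    bw_tol: float = 1e-6
    stay_prob_dc: float = 0.9
    dc_weights: str = "uniform"  # or "performance"
    decoder: str = "viterbi"  # or "fixed_lag"
    lag_samples: int = 15
    tolerance_ms: float = 60.0
    tolerance_rounding: str = "floor"


@dataclass
class EmissionInit:
    """Supervised per-phase emission statistics (deg/s) and durations."""

    mu: np.ndarray  # (n,)
    sigma: np.ndarray  # (n,)
    durations: np.ndarray  # (n,), mean raw samples per occurrence
    l_norm: int

    def __post_init__(self) -> None:
        if (self.sigma <= 0).any():
            raise ValueError("per-phase sd must be positive")
        if (self.durations < 1).any():
            raise ValueError("per-phase durations must be >= 1 sample")


def _phase_segments(labels: np.ndarray, phase_idx: int) -> list[tuple[int, int]]:
    """Contiguous [start, stop) runs of one phase."""
    mask = labels == phase_idx
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = [0] if mask[0] else []
    starts += [int(e) + 1 for e in edges if not mask[e]]
    stops = [int(e) + 1 for e in edges if mask[e]]
    if mask[-1]:
        stops.append(labels.size)
    return list(zip(starts, stops))


def init_emissions(
    gyro: GyroSignal | np.ndarray,
    ref: PhaseSequence,
    l_norm: int = 100,
    min_sigma: Optional[float] = None,
) -> EmissionInit:
    """Phase-wise emission statistics after time-normalization.

    Each occurrence of a phase is resampled to ``l_norm`` points by linear
    interpolation, so short and long occurrences contribute equally; mean
    and (ML) standard deviation are then taken over the pooled normalized
    ensemble. Mean phase durations come from the raw segment lengths.
    """
    values = gyro.values if isinstance(gyro, GyroSignal) else np.asarray(gyro, float)
    if values.size != len(ref):
        raise ValueError("signal and reference must have equal length")
    model = ref.model
    if min_sigma is None:
        min_sigma = max(1e-2 * float(values.std()), 1e-6)
    mu = np.empty(model.n_phases)
    sigma = np.empty(model.n_phases)
    durations = np.empty(model.n_phases)
    grid = np.linspace(0.0, 1.0, l_norm)
    for i, phase in enumerate(model.phases):
        segs = _phase_segments(ref.labels, i)
        if not segs:
            raise ValueError(f"phase {phase} absent from the reference sequence")
        pooled = []
        for a, b in segs:
            seg = values[a:b]
            if seg.size == 1:
                pooled.append(np.full(l_norm, seg[0]))
            else:
                pooled.append(np.interp(grid, np.linspace(0, 1, seg.size), seg))
        ens = np.concatenate(pooled)
        mu[i] = ens.mean()
        sigma[i] = max(float(ens.std()), min_sigma)
        durations[i] = max(float(np.mean([b - a for a, b in segs])), 1.0)
    return EmissionInit(mu=mu, sigma=sigma, durations=durations, l_norm=l_norm)


def params_from_init(init: EmissionInit) -> HmmParams:
    """Cyclic left-right HMM with single-Gaussian emissions from an init."""
    n = init.mu.size
    return HmmParams(
        A=build_left_right_A(n, init.durations, cyclic=True),
        pi=uniform_pi(n),
        w=np.ones((n, 1)),
        mu=init.mu[:, None],
        sigma=init.sigma[:, None],
    )


def _train_scalar(
    signal: str,
    model_id: str,
    obs: np.ndarray,
    ref: PhaseSequence,
    config: TrainConfig,
    meta: dict,
) -> ScalarClassifier:
    init = init_emissions(obs, ref, config.l_norm)
    params = params_from_init(init)
    if config.refine:
        params, trace = baum_welch(
            params, [obs], tol=config.bw_tol, max_iter=config.bw_max_iter
        )
        meta = {**meta, "loglik_trace": [float(x) for x in trace]}
    return ScalarClassifier(signal, model_id, params, meta=meta)


def _filtered(gyro: GyroSignal, config: TrainConfig) -> GyroSignal:
    return lowpass_filter(gyro, config.cutoff_hz, config.filter_order)


def _reference_for(trial: Trial, model_id: str, config: TrainConfig,
                   segment: str = "foot") -> PhaseSequence:
    gyro = trial.gyro(segment)
    return partition_trial(trial.footswitch, model_id, times=gyro.times)


def _make_dc(members: tuple[ScalarClassifier, ScalarClassifier],
             config: TrainConfig, meta: dict) -> DistributedClassifier:
    n = get_model(members[0].model_id).n_phases
    return DistributedClassifier(
        members=members,
        weights=np.array([0.5, 0.5]),
        A_dc=build_A_dc(n, config.stay_prob_dc),
        meta=meta,
    )


def train_sst(
    spec: ClassifierSpec,
    trial_rep1: Trial,
    config: Optional[TrainConfig] = None,
) -> ScalarClassifier | DistributedClassifier:
    """Subject-specific training on the first repetition of a condition.

    Emissions are initialized from the trial's own footswitch reference,
    the transition matrix from the measured mean phase durations, and the
    parameters are refined by Baum-Welch on the filtered signal. The
    second repetition is never touched here.
    """
    if spec.procedure != "SST":
        raise ValueError("spec.procedure must be SST")
    if trial_rep1.repetition != 1:
        raise ValueError("SST trains on repetition 1")
    config = config or TrainConfig()
    meta = {
        "procedure": "SST",
        "subject_id": trial_rep1.subject_id,
        "condition": trial_rep1.condition,
        "training_trials": [list(trial_rep1.key)],
        "fs_hz": config.fs_hz,
        "filter": {"cutoff_hz": config.cutoff_hz, "order": config.filter_order},
    }
    ref = _reference_for(trial_rep1, spec.model_id, config)

    def scalar_for(sig: str) -> ScalarClassifier:
        gyro = _filtered(trial_rep1.gyro(_SEGMENT_OF[sig]), config)
        return _train_scalar(sig, spec.model_id, gyro.values, ref, config,
                             {**meta, "signal": sig})

    if spec.kind == "SC":
        return scalar_for(spec.signal)
    return _make_dc((scalar_for("ft"), scalar_for("sh")), config, meta)


# ---------------------------------------------------------------------------
# SPT: standardized parameters from the healthy cohort

@dataclass
class SptTemplate:
    """Averaged paradigmatic cycle of the healthy cohort for one condition."""

    condition: str
    foot_mean: np.ndarray  # (l_cycle,)
    shank_mean: np.ndarray
    foot_disp: np.ndarray  # cross-subject SD per normalized point
    shank_disp: np.ndarray
    phase_scripts: dict[str, np.ndarray]  # model_id -> (l_cycle,) labels
    mean_cycle_samples: float
    included_subjects: list[str] = field(default_factory=list)

    def waveform(self, signal: str) -> np.ndarray:
        return self.foot_mean if signal == "ft" else self.shank_mean

    def dispersion(self, signal: str) -> np.ndarray:
        return self.foot_disp if signal == "ft" else self.shank_disp


def _normalized_cycles(values: np.ndarray, starts: Sequence[int],
                       l_cycle: int) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, l_cycle, endpoint=False)
    out = []
    for a, b in zip(starts[:-1], starts[1:]):
        seg = values[a:b]
        out.append(np.interp(grid, np.linspace(0, 1, seg.size, endpoint=False), seg))
    return np.array(out)


def _normalized_labels(labels: np.ndarray, starts: Sequence[int],
                       l_cycle: int) -> np.ndarray:
    out = []
    for a, b in zip(starts[:-1], starts[1:]):
        idx = a + np.floor(np.arange(l_cycle) * (b - a) / l_cycle).astype(int)
        out.append(labels[idx])
    return np.array(out)


def _majority(rows: np.ndarray) -> np.ndarray:
    """Column-wise majority vote over integer label rows."""
    n_lab = int(rows.max()) + 1
    counts = np.stack([(rows == k).sum(axis=0) for k in range(n_lab)])
    return np.argmax(counts, axis=0).astype(np.int64)


def build_spt_template(
    cohort: CohortDataset,
    condition: str,
    exclude_subject: Optional[str] = None,
    l_cycle: int = 200,
    config: Optional[TrainConfig] = None,
) -> SptTemplate:
    """Average the TD group's first-repetition cycles into a template.

    Cycles are delimited by heel contact on the 6P reference, resampled to
    ``l_cycle`` points, averaged within each subject and then across the
    included subjects; the per-point cross-subject standard deviation is
    retained as dispersion. ``exclude_subject`` implements leave-one-out
    (that subject contributes nothing).
    """
    config = config or TrainConfig()
    included = [s for s in cohort.subjects("TD") if s != exclude_subject]
    if len(included) < 2:
        raise ValueError("SPT template needs at least 2 included TD subjects")
    foot_rows, shank_rows = [], []
    label_rows: dict[str, list[np.ndarray]] = {m: [] for m in ("2P", "4P", "6P")}
    cycle_lens = []
    for sid in included:
        trial = cohort.get(sid, condition, 1)
        gyro_ft = _filtered(trial.gyro_foot, config)
        gyro_sh = _filtered(trial.gyro_shank, config)
        ref6 = partition_trial(trial.footswitch, "6P", times=gyro_ft.times)
        starts = segment_cycles(ref6)
        if len(starts) < 2:
            raise ValueError(f"subject {sid}: too few cycles for a template")
        foot_rows.append(_normalized_cycles(gyro_ft.values, starts, l_cycle).mean(axis=0))
        shank_rows.append(_normalized_cycles(gyro_sh.values, starts, l_cycle).mean(axis=0))
        cycle_lens.append(float(np.mean(np.diff(starts))))
        for m in label_rows:
            ref = ref6 if m == "6P" else partition_trial(
                trial.footswitch, m, times=gyro_ft.times
            )
            label_rows[m].append(_majority(_normalized_labels(ref.labels, starts, l_cycle)))
    foot_arr = np.array(foot_rows)
    shank_arr = np.array(shank_rows)
    return SptTemplate(
        condition=condition,
        foot_mean=foot_arr.mean(axis=0),
        shank_mean=shank_arr.mean(axis=0),
        foot_disp=foot_arr.std(axis=0, ddof=1),
        shank_disp=shank_arr.std(axis=0, ddof=1),
        phase_scripts={m: _majority(np.array(v)) for m, v in label_rows.items()},
        mean_cycle_samples=float(np.mean(cycle_lens)),
        included_subjects=list(included),
    )


def _spt_scalar(signal: str, model_id: str, template: SptTemplate,
                config: TrainConfig, meta: dict) -> ScalarClassifier:
    model = get_model(model_id)
    wave = template.waveform(signal)
    disp = template.dispersion(signal)
    script = template.phase_scripts[model_id]
    l_cycle = wave.size
    n = model.n_phases
    mu = np.empty(n)
    sigma = np.empty(n)
    durations = np.empty(n)
    min_sigma = max(1e-2 * float(wave.std()), 1e-6)
    for i, phase in enumerate(model.phases):
        mask = script == i
        if not mask.any():
            raise ValueError(f"phase {phase} absent from the SPT template script")
        mu[i] = wave[mask].mean()
        # pooled spread: waveform variation within the phase plus the
        # cross-subject dispersion (averaging alone would shrink sigma)
        sigma[i] = max(
            float(np.sqrt(wave[mask].var() + np.mean(disp[mask] ** 2))), min_sigma
        )
        durations[i] = max(
            mask.sum() / l_cycle * template.mean_cycle_samples, 1.0
        )
    init = EmissionInit(mu=mu, sigma=sigma, durations=durations,
                        l_norm=config.l_norm)
    params = params_from_init(init)
    if config.refine:
        cyc = int(round(template.mean_cycle_samples))
        grid = np.linspace(0.0, 1.0, cyc, endpoint=False)
        one = np.interp(grid, np.linspace(0, 1, l_cycle, endpoint=False), wave)
        obs = np.tile(one, config.spt_cycles)
        params, trace = baum_welch(
            params, [obs], tol=config.bw_tol, max_iter=config.bw_max_iter,
            var_floor=min_sigma,
        )
        meta = {**meta, "loglik_trace": [float(x) for x in trace]}
    return ScalarClassifier(signal, model_id, params, meta=meta)


def train_spt(
    spec: ClassifierSpec,
    cohort: CohortDataset,
    condition: str,
    exclude_subject: Optional[str] = None,
    config: Optional[TrainConfig] = None,
    template: Optional[SptTemplate] = None,
) -> ScalarClassifier | DistributedClassifier:
    """Standardized-parameter training from the healthy cohort.

    A prebuilt template may be supplied to amortize template construction
    across the classifiers that share it.
    """
    if spec.procedure != "SPT":
        raise ValueError("spec.procedure must be SPT")
    config = config or TrainConfig()
    if template is None:
        template = build_spt_template(cohort, condition, exclude_subject,
                                      config.l_cycle, config)
    meta = {
        "procedure": "SPT",
        "condition": condition,
        "excluded_subject": exclude_subject,
        "included_subjects": template.included_subjects,
        "fs_hz": config.fs_hz,
        "filter": {"cutoff_hz": config.cutoff_hz, "order": config.filter_order},
    }
    if spec.kind == "SC":
        return _spt_scalar(spec.signal, spec.model_id, template, config,
                           {**meta, "signal": spec.signal})
    members = (
        _spt_scalar("ft", spec.model_id, template, config, {**meta, "signal": "ft"}),
        _spt_scalar("sh", spec.model_id, template, config, {**meta, "signal": "sh"}),
    )
    return _make_dc(members, config, meta)


# ---------------------------------------------------------------------------
# Full factorial study

def run_study(
    cohort: CohortDataset,
    specs: Optional[Sequence[ClassifierSpec]] = None,
    config: Optional[TrainConfig] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Train/test every classifier for every subject and condition.

    For each (spec, subject, condition): train on repetition 1 per the
    spec's protocol, classify the second repetition, and evaluate the
    predicted transitions against the repetition-2 footswitch reference.
    Returns one row per cell with confusion counts, TPR, TNR, G and the
    ROC category. Deterministic given the cohort.
    """
    specs = list(specs) if specs is not None else enumerate_classifiers()
    config = config or TrainConfig()

    scalar_cache: dict[tuple, ScalarClassifier] = {}
    template_cache: dict[tuple, SptTemplate] = {}
    gamma_cache: dict[tuple, tuple[PhaseSequence, np.ndarray]] = {}

    def get_scalar(proc: str, model_id: str, sig: str, subject: str,
                   condition: str) -> Optional[ScalarClassifier]:
        exclude = subject if (proc == "SPT" and cohort.group_of(subject) == "TD") else None
        key = (proc, model_id, sig, condition,
               subject if proc == "SST" else exclude)
        if key in scalar_cache:
            return scalar_cache[key]
        if proc == "SST":
            trial1 = cohort.get(subject, condition, 1)
            clf = train_sst(ClassifierSpec("SST", model_id, sig, "SC"), trial1, config)
        else:
            tkey = (condition, exclude)
            if tkey not in template_cache:
                template_cache[tkey] = build_spt_template(
                    cohort, condition, exclude, config.l_cycle, config
                )
            clf = train_spt(
                ClassifierSpec("SPT", model_id, sig, "SC"), cohort, condition,
                exclude, config, template=template_cache[tkey]
            )
        scalar_cache[key] = clf
        return clf

    def decode(clf: ScalarClassifier, trial: Trial):
        key = (id(clf), trial.key)
        if key not in gamma_cache:
            gyro = _filtered(trial.gyro(_SEGMENT_OF[clf.signal_source]), config)
            lag = config.lag_samples if config.decoder == "fixed_lag" else None
            seq, gamma = classify_scalar(clf, gyro, decoder=config.decoder,
                                         lag_samples=lag)
            gamma_cache[key] = (seq, gamma)
        return gamma_cache[key]

    rows = []
    conditions = cohort.conditions
    work = [
        (spec, subject, cond)
        for spec in specs
        for subject in cohort.subjects()
        for cond in conditions
    ]
    iterator = work
    if progress:
        from tqdm import tqdm  # pragma: no cover

        iterator = tqdm(work)  # pragma: no cover
    for spec, subject, cond in iterator:
        if (subject, cond, 1) not in cohort or (subject, cond, 2) not in cohort:
            warnings.warn(f"skipping {subject}/{cond}: missing repetition",
                          stacklevel=2)
            continue
        trial2 = cohort.get(subject, cond, 2)
        ref = _reference_for(trial2, spec.model_id, config)
        if spec.kind == "SC":
            clf = get_scalar(spec.procedure, spec.model_id, spec.signal,
                             subject, cond)
            pred, _ = decode(clf, trial2)
        else:
            m_ft = get_scalar(spec.procedure, spec.model_id, "ft", subject, cond)
            m_sh = get_scalar(spec.procedure, spec.model_id, "sh", subject, cond)
            dc = _make_dc((m_ft, m_sh), config, {})
            _, g_ft = decode(m_ft, trial2)
            _, g_sh = decode(m_sh, trial2)
            fused = fuse_posteriors([g_ft, g_sh], dc.weights)
            states = decode_scores(fused, dc.A_dc)
            pred = PhaseSequence(spec.model_id, ref.fs_hz, states,
                                 source="predicted", t0=ref.t0)
        res = transition_confusion(pred, ref, config.tolerance_ms,
                                   config.tolerance_rounding)
        rows.append(
            {
                "spec": spec.code,
                "table_code": spec.table_code,
                "procedure": spec.procedure,
                "model": spec.model_id,
                "signal": spec.signal,
                "kind": spec.kind,
                "subject": subject,
                "group": cohort.group_of(subject),
                "condition": cond,
                "TP": res.tp,
                "FP": res.fp,
                "TN": res.tn,
                "FN": res.fn,
                "TPR": res.tpr,
                "TNR": res.tnr,
                "G": res.g,
                "category": res.category,
            }
        )
    return pd.DataFrame(rows)
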