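"""Model/results front-end for the gait-phase classifiers.

Mirrors the fit/results idiom of statistical modelling packages: a model
object is built from data, ``fit()`` estimates the HMM parameters and
returns a results object carrying the estimates, training diagnostics,
prediction and evaluation methods, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    DistributedClassifier,
    ScalarClassifier,
    classify_distributed,
    classify_scalar,
)
from .evaluation import EvalResult, aggregate_study, transition_confusion
from .phases import PhaseSequence, get_model, partition_trial
from .signals import CohortDataset, GyroSignal, Trial, lowpass_filter
from .training import (
    ClassifierSpec,
    TrainConfig,
    enumerate_classifiers,
    run_study,
    train_spt,
    train_sst,
)


class ScalarGaitHMM:
    """Scalar gait-phase classifier model for one subject and condition.

    Built from a training trial (repetition 1); ``fit()`` runs supervised
    initialization from the footswitch reference followed by Baum-Welch
    refinement and returns a :class:`GaitHMMResults`.
    """

    def __init__(self, trial_rep1: Trial, model_id: str, signal: str = "ft",
                 config: Optional[TrainConfig] = None) -> None:
        if signal not in ("ft", "sh"):
            raise ValueError("scalar model signal must be 'ft' or 'sh'")
        self.trial = trial_rep1
        self.model_id = model_id
        self.signal = signal
        self.config = config or TrainConfig()
        self.spec = ClassifierSpec("SST", model_id, signal, "SC")

    def fit(self) -> "GaitHMMResults":
        clf = train_sst(self.spec, self.trial, self.config)
        return GaitHMMResults(self, clf)


class DistributedGaitHMM(ScalarGaitHMM):
    """Foot+shank fusion classifier model (subject-specific training)."""

    def __init__(self, trial_rep1: Trial, model_id: str,
                 config: Optional[TrainConfig] = None) -> None:
        self.trial = trial_rep1
        self.model_id = model_id
        self.signal = "ftsh"
        self.config = config or TrainConfig()
        self.spec = ClassifierSpec("SST", model_id, "ftsh", "DC")


class InterSubjectGaitHMM:
    """Standardized-parameter (inter-subject) classifier model.

    Built from a healthy cohort; the evaluated subject is excluded from the
    template when it belongs to the TD group.
    """

    def __init__(self, cohort: CohortDataset, condition: str, model_id: str,
                 signal: str = "ft", exclude_subject: Optional[str] = None,
                 config: Optional[TrainConfig] = None) -> None:
        self.cohort = cohort
        self.condition = condition
        self.model_id = model_id
        self.signal = signal
        self.exclude_subject = exclude_subject
        self.config = config or TrainConfig()
        kind = "DC" if signal == "ftsh" else "SC"
        self.spec = ClassifierSpec("SPT", model_id, signal, kind)

    def fit(self) -> "GaitHMMResults":
        clf = train_spt(self.spec, self.cohort, self.condition,
                        self.exclude_subject, self.config)
        return GaitHMMResults(self, clf)


@dataclass
class GaitHMMResults:
    """Fitted classifier: parameters, diagnostics, prediction, evaluation."""

    model: object
    classifier: ScalarClassifier | DistributedClassifier

    @property
    def params(self):
        if isinstance(self.classifier, ScalarClassifier):
            return self.classifier.params
        return [m.params for m in self.classifier.members]

    @property
    def loglik_trace(self) -> list[float]:
        meta = self.classifier.meta
        if "loglik_trace" in meta:
            return meta["loglik_trace"]
        return [t for m in getattr(self.classifier, "members", [])
                for t in m.meta.get("loglik_trace", [])]

    def predict(self, trial: Trial) -> PhaseSequence:
        """Predicted phase sequence for a trial (signals filtered first)."""
        cfg: TrainConfig = self.model.config
        if isinstance(self.classifier, ScalarClassifier):
            seg = "foot" if self.classifier.signal_source == "ft" else "shank"
            gyro = lowpass_filter(trial.gyro(seg), cfg.cutoff_hz, cfg.filter_order)
            lag = cfg.lag_samples if cfg.decoder == "fixed_lag" else None
            seq, _ = classify_scalar(self.classifier, gyro, decoder=cfg.decoder,
                                     lag_samples=lag)
            return seq
        ft = lowpass_filter(trial.gyro_foot, cfg.cutoff_hz, cfg.filter_order)
        sh = lowpass_filter(trial.gyro_shank, cfg.cutoff_hz, cfg.filter_order)
        return classify_distributed(self.classifier, ft, sh)

    def predict_proba(self, trial: Trial) -> np.ndarray:
        """Per-sample state posteriors (scalar classifiers only)."""
        if not isinstance(self.classifier, ScalarClassifier):
            raise ValueError("posteriors are defined per scalar member")
        cfg: TrainConfig = self.model.config
        seg = "foot" if self.classifier.signal_source == "ft" else "shank"
        gyro = lowpass_filter(trial.gyro(seg), cfg.cutoff_hz, cfg.filter_order)
        _, gamma = classify_scalar(self.classifier, gyro)
        return gamma

    def evaluate(self, trial: Trial) -> EvalResult:
        """Tolerance-windowed transition evaluation against the footswitch
        reference of the given trial."""
        cfg: TrainConfig = self.model.config
        pred = self.predict(trial)
        ref = partition_trial(trial.footswitch, self.classifier.model_id,
                              times=trial.gyro_foot.times)
        return transition_confusion(pred, ref, cfg.tolerance_ms,
                                    cfg.tolerance_rounding)

    def summary(self) -> str:
        lines = []
        clf = self.classifier
        model = get_model(clf.model_id)
        kind = "Scalar" if isinstance(clf, ScalarClassifier) else "Distributed"
        lines.append(f"{kind} gait-phase HMM ({clf.model_id}: "
                     f"{', '.join(model.phases)})")
        lines.append("=" * 60)
        members = [clf] if isinstance(clf, ScalarClassifier) else list(clf.members)
        for m in members:
            lines.append(f"signal: {m.signal_source}")
            lines.append(f"{'phase':>8} {'mu (deg/s)':>12} {'sigma':>10} "
                         f"{'self-trans':>12}")
            for i, ph in enumerate(model.phases):
                lines.append(
                    f"{ph:>8} {m.params.mu[i, 0]:>12.2f} "
                    f"{m.params.sigma[i, 0]:>10.2f} {m.params.A[i, i]:>12.4f}"
                )
        trace = self.loglik_trace
        if trace:
            lines.append(f"Baum-Welch iterations: {len(trace)}, "
                         f"final loglik: {trace[-1]:.2f}")
        return "\n".join(lines)


class GaitStudy:
    """The full factorial classifier study on a cohort.

    ``fit()`` trains and tests every requested classifier configuration for
    every subject and walking condition and returns a
    :class:`GaitStudyResults`.
    """

    def __init__(self, cohort: CohortDataset,
                 specs: Optional[Sequence[ClassifierSpec]] = None,
                 config: Optional[TrainConfig] = None) -> None:
        self.cohort = cohort
        self.specs = list(specs) if specs is not None else enumerate_classifiers()
        self.config = config or TrainConfig()

    def fit(self, progress: bool = False) -> "GaitStudyResults":
        frame = run_study(self.cohort, self.specs, self.config, progress=progress)
        return GaitStudyResults(self, frame)


@dataclass
class GaitStudyResults:
    """Per-cell evaluation table of a factorial study, with aggregation."""

    study: GaitStudy
    frame: pd.DataFrame

    def aggregate(self, group_by: Sequence[str] = (
            "group", "condition", "model", "signal", "procedure")) -> pd.DataFrame:
        return aggregate_study(self.frame, group_by)

    def mean_g_by_classifier(self) -> pd.Series:
        """Mean goodness per classifier configuration, pooled over cells."""
        return self.frame.groupby("spec")["G"].mean().sort_values()

    def summary(self) -> str:
        per_clf = self.mean_g_by_classifier()
        lines = ["Gait-phase classifier study", "=" * 46,
                 f"{'classifier':>20} {'mean G':>9} {'category':>10}"]
        from .evaluation import categorize

        for code, g in per_clf.items():
            lines.append(f"{code:>20} {g:>9.3f} {categorize(float(g)):>10}")
        lines.append("-" * 46)
        lines.append(f"rows: {len(self.frame)}; "
                     f"max mean G: {per_clf.max():.3f}; "
                     f"max cell SD: {self.max_cell_sd():.3f}")
        return "\n".join(lines)

    def max_cell_sd(self) -> float:
        agg = self.aggregate(("group", "condition", "spec"))
        return float(agg["sd_G"].max())
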