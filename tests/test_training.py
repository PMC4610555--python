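import numpy as np
import pytest

from gaitphase.classifiers import DistributedClassifier, ScalarClassifier
from gaitphase.phases import PhaseSequence, partition_trial
from gaitphase.simulate import CohortSpec, generate_cohort
from gaitphase.training import (
    ClassifierSpec,
    TrainConfig,
    build_spt_template,
    enumerate_classifiers,
    init_emissions,
    run_study,
    train_spt,
    train_sst,
)

FAST = TrainConfig(bw_max_iter=3)


class TestClassifierSpec:
    def test_eighteen_configurations(self):
        specs = enumerate_classifiers()
        assert len(specs) == 18
        codes = {s.code for s in specs}
        assert len(codes) == 18
        assert "SPT_2P_sh_SC" in codes

    def test_scalar_never_uses_both_signals(self):
        with pytest.raises(ValueError):
            ClassifierSpec("SST", "2P", "ftsh", "SC")
        with pytest.raises(ValueError):
            ClassifierSpec("SST", "2P", "ft", "DC")

    def test_code_round_trip(self):
        spec = ClassifierSpec.from_code("SPT_4P_ftsh_DC")
        assert spec == ClassifierSpec("SPT", "4P", "ftsh", "DC")
        assert spec.code == "SPT_4P_ftsh_DC"

    def test_table_codes_match_study_naming(self):
        codes = {s.table_code for s in enumerate_classifiers()}
        assert "S2pPTshSC" in codes
        assert "S6pSTftshDC" in codes


class TestInitEmissions:
    def test_hand_computed_pooled_statistics(self):
        # two SP occurrences with values [1,1] and [3,3]: normalized pooling
        # gives mean 2 and ML sd of {1,1,3,3} = 1
        values = np.array([1.0, 1.0, 9.0, 9.0, 3.0, 3.0])
        ref = PhaseSequence("2P", 50.0, np.array([0, 0, 1, 1, 0, 0]))
        init = init_emissions(values, ref, l_norm=2)
        assert init.mu[0] == pytest.approx(2.0)
        assert init.sigma[0] == pytest.approx(1.0)
        assert init.mu[1] == pytest.approx(9.0)

    def test_mean_invariant_to_occurrence_duration(self):
        # a long and a short occurrence contribute equally after
        # time-normalization
        values = np.array([1.0] * 10 + [9.0] * 3 + [3.0] * 2 + [9.0] * 3)
        labels = np.array([0] * 10 + [1] * 3 + [0] * 2 + [1] * 3)
        init = init_emissions(values, PhaseSequence("2P", 50.0, labels),
                              l_norm=50)
        assert init.mu[0] == pytest.approx(2.0)

    def test_zero_variance_clamped(self):
        values = np.array([5.0, 5.0, 5.0, 7.0])
        ref = PhaseSequence("2P", 50.0, np.array([0, 0, 0, 1]))
        init = init_emissions(values, ref, l_norm=4)
        assert init.sigma[0] > 0

    def test_absent_phase_named_in_error(self):
        values = np.zeros(10)
        ref = PhaseSequence("2P", 50.0, np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="SW"):
            init_emissions(values, ref, l_norm=10)

    def test_durations_from_raw_segments(self):
        labels = np.array([0] * 4 + [1] * 6 + [0] * 8 + [1] * 6)
        init = init_emissions(np.arange(24.0),
                              PhaseSequence("2P", 50.0, labels), l_norm=10)
        assert init.durations[0] == pytest.approx(6.0)
        assert init.durations[1] == pytest.approx(6.0)


class TestTrainSst:
    def test_requires_repetition_one(self, small_cohort):
        t2 = small_cohort.get("TD01", "L1.0", 2)
        with pytest.raises(ValueError, match="repetition 1"):
            train_sst(ClassifierSpec("SST", "2P", "ft", "SC"), t2, FAST)

    def test_scalar_classifier_reaches_optimum_on_own_subject(
            self, small_cohort):
        t1 = small_cohort.get("TD01", "L1.0", 1)
        t2 = small_cohort.get("TD01", "L1.0", 2)
        clf = train_sst(ClassifierSpec("SST", "2P", "ft", "SC"), t1, FAST)
        from gaitphase.classifiers import classify_scalar
        from gaitphase.evaluation import transition_confusion
        from gaitphase.signals import lowpass_filter

        gyro = lowpass_filter(t2.gyro_foot, 15.0, 4)
        pred, _ = classify_scalar(clf, gyro)
        ref = partition_trial(t2.footswitch, "2P", times=gyro.times)
        res = transition_confusion(pred, ref, 60.0)
        assert res.g <= 0.25

    def test_distributed_spec_trains_both_members(self, small_cohort):
        t1 = small_cohort.get("TD02", "L1.0", 1)
        clf = train_sst(ClassifierSpec("SST", "2P", "ftsh", "DC"), t1, FAST)
        assert isinstance(clf, DistributedClassifier)
        assert {m.signal_source for m in clf.members} == {"ft", "sh"}
        # both trained on the same rep-1 trial
        for m in clf.members:
            assert m.meta["training_trials"] == [["TD02", "L1.0", 1]]

    def test_params_satisfy_invariants(self, small_cohort):
        t1 = small_cohort.get("TD03", "L1.0", 1)
        clf = train_sst(ClassifierSpec("SST", "6P", "sh", "SC"), t1, FAST)
        clf.params.validate()
        A = clf.params.A
        allowed = np.zeros_like(A, dtype=bool)
        n = A.shape[0]
        for i in range(n):
            allowed[i, i] = allowed[i, (i + 1) % n] = True
        assert np.all(A[~allowed] == 0.0)


class TestSptTemplate:
    def test_leave_one_out_excludes_subject(self, small_cohort):
        tpl = build_spt_template(small_cohort, "L1.0",
                                 exclude_subject="TD02", config=FAST)
        assert "TD02" not in tpl.included_subjects
        assert len(tpl.included_subjects) == 3

    def test_no_exclusion_uses_all_td(self, small_cohort):
        tpl = build_spt_template(small_cohort, "L1.0", None, config=FAST)
        assert len(tpl.included_subjects) == 4

    def test_too_few_subjects_rejected(self, small_cohort):
        sub = type(small_cohort)()
        sub.add(small_cohort.get("TD01", "L1.0", 1))
        sub.add(small_cohort.get("TD01", "L1.0", 2))
        with pytest.raises(ValueError, match="at least 2"):
            build_spt_template(sub, "L1.0", None, config=FAST)

    def test_phase_scripts_cover_all_models(self, small_cohort):
        tpl = build_spt_template(small_cohort, "L1.0", None, config=FAST)
        for model_id, n in (("2P", 2), ("4P", 4), ("6P", 6)):
            script = tpl.phase_scripts[model_id]
            assert set(np.unique(script)) == set(range(n))

    def test_template_of_identical_subjects_matches_each(self, template):
        # subjects with no inter/intra variability all walk the template:
        # the averaged cycle equals any subject's own mean cycle
        spec = CohortSpec(n_subjects=3, group="TD", conditions=("L1.0",),
                          duration_s=15.0, inter_subject_sd=0.0,
                          intra_subject_sd=0.0, noise_sd=0.0, seed=0)
        cohort = generate_cohort(spec)
        tpl = build_spt_template(cohort, "L1.0", None, config=FAST)
        assert np.max(tpl.foot_disp) < 1e-6


class TestTrainSpt:
    def test_metadata_audits_exclusion(self, small_cohort):
        clf = train_spt(ClassifierSpec("SPT", "2P", "ft", "SC"), small_cohort,
                        "L1.0", exclude_subject="TD01", config=FAST)
        assert clf.meta["excluded_subject"] == "TD01"
        assert "TD01" not in clf.meta["included_subjects"]

    def test_left_right_zeros_preserved(self, small_cohort):
        clf = train_spt(ClassifierSpec("SPT", "6P", "sh", "SC"), small_cohort,
                        "L1.0", None, config=FAST)
        A = clf.params.A
        n = A.shape[0]
        allowed = np.zeros_like(A, dtype=bool)
        for i in range(n):
            allowed[i, i] = allowed[i, (i + 1) % n] = True
        assert np.all(A[~allowed] == 0.0)

    def test_distributed_spt(self, small_cohort):
        clf = train_spt(ClassifierSpec("SPT", "2P", "ftsh", "DC"),
                        small_cohort, "L1.0", None, config=FAST)
        assert isinstance(clf, DistributedClassifier)


@pytest.fixture(scope="module")
def study_frame(small_cohort):
    specs = [ClassifierSpec("SST", "2P", "ft", "SC"),
             ClassifierSpec("SPT", "2P", "ftsh", "DC")]
    return run_study(small_cohort, specs, FAST)


class TestRunStudy:

    def test_row_count(self, study_frame, small_cohort):
        assert len(study_frame) == 2 * 4 * 1  # specs x subjects x conditions

    def test_columns_and_vocabulary(self, study_frame):
        assert {"spec", "subject", "group", "condition", "TP", "FP", "TN",
                "FN", "TPR", "TNR", "G", "category"} <= set(study_frame.columns)
        assert set(study_frame["group"]) == {"TD"}

    def test_deterministic_rerun(self, small_cohort, study_frame):
        specs = [ClassifierSpec("SST", "2P", "ft", "SC"),
                 ClassifierSpec("SPT", "2P", "ftsh", "DC")]
        again = run_study(small_cohort, specs, FAST)
        np.testing.assert_allclose(again["G"].to_numpy(dtype=float),
                                   study_frame["G"].to_numpy(dtype=float))
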