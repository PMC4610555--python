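import numpy as np
import pytest

from gaitphase.phases import partition_trial, segment_cycles, transitions
from gaitphase.simulate import (
    CohortSpec,
    GaitTemplate,
    generate_cohort,
    generate_cycle,
    generate_trial,
    perturb_rotation,
)


class TestTemplateValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GaitTemplate(fractions=np.array([0.2, 0.2, 0.2, 0.2, 0.1, 0.2]))

    def test_sub_resolution_phase_rejected(self):
        tpl = GaitTemplate(cadence_spm=42.0,
                           fractions=np.array([0.01, 0.1, 0.28, 0.13, 0.08,
                                               0.40]))
        with pytest.raises(ValueError, match="2 samples"):
            tpl.check_resolvable(50.0)


class TestGenerateCycle:
    def test_partition_matches_emitted_script(self, template):
        from gaitphase.signals import FootswitchSignal

        foot, shank, script, fsw = generate_cycle(template)
        seq = partition_trial(FootswitchSignal(fsw, 200.0), "6P",
                              times=np.arange(len(script)) / 50.0)
        np.testing.assert_array_equal(seq.labels, script)

    def test_noise_free_cycles_are_identical(self):
        # cadence 40 -> 1.5 s strides, an integer number of samples at both
        # rates, so consecutive noise-free cycles coincide sample-by-sample
        tpl = GaitTemplate(cadence_spm=40.0)
        rng = np.random.default_rng(0)
        trial, script = generate_trial(tpl, "S", "TD", "L1.0", 1, 12.0, rng,
                                       intra_sd=0.0, noise_sd=0.0)
        n = 75  # samples per stride at 50 Hz
        np.testing.assert_allclose(trial.gyro_foot.values[:n],
                                   trial.gyro_foot.values[n:2 * n],
                                   atol=1e-9)
        # phase boundaries that fall exactly on a sample tick may resolve to
        # either side by one float ulp; everything else must coincide
        mismatches = int((script.labels[:n] != script.labels[n:2 * n]).sum())
        assert mismatches <= 1

    def test_cycle_count_matches_cadence(self, template):
        rng = np.random.default_rng(1)
        trial, script = generate_trial(template, "S", "TD", "L1.0", 1, 60.0,
                                       rng, intra_sd=0.0, noise_sd=0.0)
        starts = segment_cycles(script)
        # 42 strides/min for 60 s -> 42 +- boundary effects
        assert abs(len(starts) - 42) <= 2


class TestGenerateCohort:
    def test_trial_count(self):
        spec = CohortSpec(n_subjects=10, group="TD", duration_s=11.0, seed=0)
        cohort = generate_cohort(spec)
        assert len(cohort) == 80  # 10 subjects x 4 conditions x 2 reps

    def test_same_seed_reproduces_exactly(self):
        spec = CohortSpec(n_subjects=2, group="HC", conditions=("L1.0",),
                          duration_s=12.0, seed=5)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        ta = a.get("HC01", "L1.0", 2)
        tb = b.get("HC01", "L1.0", 2)
        np.testing.assert_array_equal(ta.gyro_foot.values, tb.gyro_foot.values)
        np.testing.assert_array_equal(ta.footswitch.channels,
                                      tb.footswitch.channels)

    def test_repetitions_differ_within_subject(self):
        spec = CohortSpec(n_subjects=1, group="TD", conditions=("L1.0",),
                          duration_s=12.0, seed=5)
        cohort = generate_cohort(spec)
        r1 = cohort.get("TD01", "L1.0", 1).gyro_foot.values
        r2 = cohort.get("TD01", "L1.0", 2).gyro_foot.values
        assert not np.allclose(r1, r2)

    def test_hemiplegic_group_more_variable_strides(self):
        def stride_cv(group, seed):
            spec = CohortSpec(n_subjects=5, group=group,
                              conditions=("L1.0",), duration_s=30.0,
                              seed=seed)
            cvs = []
            for trial in generate_cohort(spec):
                ref = partition_trial(trial.footswitch, "6P",
                                      times=trial.gyro_foot.times)
                d = np.diff(segment_cycles(ref))
                cvs.append(d.std() / d.mean())
            return np.mean(cvs)

        assert stride_cv("HC", 2) > stride_cv("TD", 2)

    def test_phase_fraction_contract(self, template):
        # across >= 1000 strides the realized mean fractions stay within
        # 2 percentage points of the template fractions
        durations = {p: 0.0 for p in range(6)}
        total = 0.0
        n_strides = 0
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            trial, script = generate_trial(template, "S", "TD", "L1.0", 1,
                                           400.0, rng, intra_sd=0.03,
                                           noise_sd=0.0)
            n_strides += len(segment_cycles(script))
            for p in range(6):
                durations[p] += np.sum(script.labels == p)
            total += len(script)
        assert n_strides >= 1000
        for p in range(6):
            realized = durations[p] / total
            assert abs(realized - template.fractions[p]) < 0.02


class TestRotationPerturbation:
    def _trial3ax(self, offsag_scale=0.0, seed=0):
        from dataclasses import replace

        tpl = replace(GaitTemplate(), offsag_scale=offsag_scale)
        rng = np.random.default_rng(seed)
        trial, _ = generate_trial(tpl, "S", "TD", "L1.0", 1, 12.0, rng,
                                  intra_sd=0.0, noise_sd=0.0,
                                  three_axis=True)
        return trial

    def test_identity_rotation_is_noop(self):
        trial = self._trial3ax(offsag_scale=0.2)
        out = perturb_rotation(trial, (0.0, 0.0))
        np.testing.assert_allclose(out.gyro_foot.values,
                                   trial.gyro_foot.values, atol=1e-12)

    def test_pure_frontal_rotation_scales_by_cosine(self):
        # with zero off-sagittal components only the cosine projection
        # survives
        trial = self._trial3ax(offsag_scale=0.0)
        out = perturb_rotation(trial, (2.0, 0.0))
        np.testing.assert_allclose(out.gyro_foot.values,
                                   np.cos(np.radians(2.0))
                                   * trial.gyro_foot.values, rtol=1e-12)

    def test_footswitch_untouched(self):
        trial = self._trial3ax(offsag_scale=0.3)
        out = perturb_rotation(trial, (2.0, 2.0))
        np.testing.assert_array_equal(out.footswitch.channels,
                                      trial.footswitch.channels)

    def test_sagittal_only_trial_rejected(self, clean_trial):
        trial, _ = clean_trial
        with pytest.raises(ValueError, match="three_axis"):
            perturb_rotation(trial, (2.0, 2.0))

    def test_small_rotation_barely_degrades_goodness(self):
        # a 2 degree misalignment changes G by a small amount, as in the
        # IMU-positioning sensitivity check
        from gaitphase.models import ScalarGaitHMM
        from gaitphase.training import TrainConfig

        t1 = self._trial3ax(offsag_scale=0.2, seed=1)
        t2 = self._trial3ax(offsag_scale=0.2, seed=1)
        res = ScalarGaitHMM(t1, "2P", "ft", TrainConfig(bw_max_iter=3)).fit()
        g_ref = res.evaluate(t2).g
        g_rot = res.evaluate(perturb_rotation(t2, (2.0, 2.0))).g
        assert abs(g_rot - g_ref) <= 0.05
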