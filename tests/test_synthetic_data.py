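import dataclasses

import numpy as np
import pandas as pd
import pytest

from romocap import (BodyModel, CohortSpec, TaskProfile, primary_angle,
                     segment_trial)
from romocap.synthetic_data import (equalized_spec, inject_gaps,
                                    simulate_cohort, simulate_trial)


class TestSimulateTrial:
    def test_noiseless_primary_curve_matches_ground_truth(self, make_trial):
        """Per-repetition (max - min) of the primary angle equals the
        recorded ground truth to 1e-6 deg."""
        traj, truth = make_trial("frontal_rise", 111.22, seed=0,
                                 rep_rom_sd=2.0)
        res = segment_trial(primary_angle(traj, "frontal_rise"))
        assert len(res.repetitions) == 6
        np.testing.assert_allclose(res.rep_roms, truth.rep_roms, atol=1e-6)

    def test_positive_trend_gives_monotone_rom_sequence(self):
        profile = TaskProfile(task="twist", true_rom=29.66, rep_rom_sd=0.0,
                              trend_deg_per_rep=1.9)
        _, truth = simulate_trial(profile, seed=0)
        assert (np.diff(truth.rep_roms) > 0).all()

    def test_same_seed_reproduces_different_seed_diverges(self, make_trial):
        t1, _ = make_trial("twist", 30.0, noise_sd=1.0, seed=5)
        t2, _ = make_trial("twist", 30.0, noise_sd=1.0, seed=5)
        t3, _ = make_trial("twist", 30.0, noise_sd=1.0, seed=6)
        for m in t1.markers:
            np.testing.assert_array_equal(t1.positions[m], t2.positions[m])
        assert any(not np.array_equal(t1.positions[m], t3.positions[m])
                   for m in t1.markers)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(Exception):
            TaskProfile(task="handstand", true_rom=30.0)
        profile = TaskProfile(task="twist", true_rom=30.0)
        with pytest.raises(ValueError):
            simulate_trial(profile, noise_sd=-1.0)

    def test_body_model_validates_lengths(self):
        with pytest.raises(ValueError):
            BodyModel(upper_arm=-1.0)


class TestInjectGaps:
    def test_zero_rate_is_identity(self, make_trial):
        traj, _ = make_trial("twist", 30.0, seed=1)
        out = inject_gaps(traj, rate=0.0, seed=2)
        assert not out.has_gaps()

    def test_gap_count_is_binomial(self, make_trial):
        traj, _ = make_trial("twist", 30.0, seed=1)
        n = traj.n_samples
        out = inject_gaps(traj, rate=0.05, max_len=50, seed=3,
                          markers=["S1"])
        count = out.gap_mask["S1"].sum()
        # 5 sigma band around n * 0.05
        sigma = np.sqrt(n * 0.05 * 0.95)
        assert abs(count - 0.05 * n) < 5 * sigma

    def test_runs_never_exceed_max_len_nor_touch_boundaries(self, make_trial):
        traj, _ = make_trial("twist", 30.0, seed=1)
        out = inject_gaps(traj, rate=0.3, max_len=4, seed=4)
        for m in out.markers:
            mask = out.gap_mask[m]
            assert not mask[0] and not mask[-1]
            run, longest = 0, 0
            for v in mask:
                run = run + 1 if v else 0
                longest = max(longest, run)
            assert longest <= 4

    def test_rate_out_of_range_rejected(self, make_trial):
        traj, _ = make_trial("twist", 30.0, seed=1)
        with pytest.raises(ValueError):
            inject_gaps(traj, rate=1.5)


class TestSimulateCohort:
    SPEC = dict(n_per_group=3, tasks=("backward_push",), sides=("right",),
                n_sets=1)

    def test_session_structure_and_trial_counts(self):
        spec = CohortSpec(seed=1, **self.SPEC)
        trials, truth = simulate_cohort(spec)
        # 3 WG x 3 sessions + 3 CG x 2 sessions, one side, one set
        assert len(trials) == 3 * 3 + 3 * 2
        by_group = truth.groupby("group")["session"].unique()
        assert set(by_group["WG"]) == {"PRE", "ACUTE", "POST"}
        assert set(by_group["CG"]) == {"PRE", "POST"}

    def test_zero_sd_cohort_reproduces_mean_gain_exactly(self):
        spec = CohortSpec(seed=1, marker_noise_sd_mm=0.0, rep_rom_sd=0.0,
                          **self.SPEC)
        params = {"backward_push": {
            "WG": {"PRE": (29.92, 0.0), "ACUTE": (32.63, 0.0),
                   "POST": (38.73, 0.0)},
            "CG": {"PRE": (30.08, 0.0), "POST": (31.07, 0.0)}}}
        spec = dataclasses.replace(spec, rom_params=params)
        _, truth = simulate_cohort(spec, keep_trajectories=False)
        wg = truth[(truth.group == "WG") & (truth.parameter == "SE_ROM")]
        piv = wg.pivot_table(index="participant", columns="session",
                             values="value")
        np.testing.assert_allclose(piv["POST"] - piv["PRE"], 8.81, atol=1e-9)

    def test_fixed_seed_reproduces_truth_table(self):
        spec = CohortSpec(seed=7, **self.SPEC)
        _, t1 = simulate_cohort(spec, keep_trajectories=False)
        _, t2 = simulate_cohort(spec, keep_trajectories=False)
        pd.testing.assert_frame_equal(t1, t2)
        _, t3 = simulate_cohort(dataclasses.replace(spec, seed=8),
                                keep_trajectories=False)
        assert not t1["value"].equals(t3["value"])

    def test_equalized_spec_removes_group_specific_gain(self):
        spec = equalized_spec(CohortSpec(seed=1, **self.SPEC))
        wg = spec.rom_params["backward_push"]["WG"]
        cg = spec.rom_params["backward_push"]["CG"]
        assert cg["POST"][0] - cg["PRE"][0] == pytest.approx(
            wg["POST"][0] - wg["PRE"][0])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_group=1)
        with pytest.raises(ValueError):
            CohortSpec(within_subject_corr=1.5)
        with pytest.raises(ValueError):
            CohortSpec(tasks=("no_such_task",))
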