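"""Tests of the synthetic cohort generator: determinism, built-in effect
directions, bookkeeping, and recovery of design-implied quantities."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from copsway.errors import InvalidArgumentError
from copsway.metrics import mean_velocity, path_length
from copsway.psychometrics import icc_3_1
from copsway.synthetic import (
    CONDITIONS,
    OUParams,
    StudyDesign,
    SubjectProfile,
    simulate_study,
    simulate_trial,
)

from conftest import small_design


def _profile(**kw):
    base = dict(
        subject_id="S01",
        latent_ability=0.0,
        base_sway_scale=1.0,
        heel_distance_baseline=20.0,
        heel_distance_slope=-0.02,
        age=50.0,
        height=170.0,
        weight=70.0,
        sex="M",
    )
    base.update(kw)
    return SubjectProfile(**base)


class TestSimulateTrial:
    def test_zero_diffusion_is_constant_at_origin(self):
        traj = simulate_trial(
            _profile(), OUParams(sigma=(0.0, 0.0)), ("OE", "OF"),
            duration=2.0, rate=50.0, seed=1,
        )
        assert path_length(traj) == 0.0
        assert np.all(traj.x == 0.0) and np.all(traj.y == 0.0)

    def test_same_seed_same_trajectory(self):
        a = simulate_trial(_profile(), OUParams(), ("CE", "CF"), 2.0, 50.0, seed=5,
                           ce_multiplier=1.6, cf_multiplier=1.1)
        b = simulate_trial(_profile(), OUParams(), ("CE", "CF"), 2.0, 50.0, seed=5,
                           ce_multiplier=1.6, cf_multiplier=1.1)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_sample_count(self):
        traj = simulate_trial(_profile(), OUParams(), ("OE", "OF"), 51.2, 50.0, seed=0)
        assert traj.n_samples == round(51.2 * 50) + 1

    def test_rejects_nonpositive_duration_or_rate(self):
        with pytest.raises(InvalidArgumentError):
            simulate_trial(_profile(), OUParams(), ("OE", "OF"), 0.0, 50.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            simulate_trial(_profile(), OUParams(), ("OE", "OF"), 1.0, -2.0, seed=0)

    def test_closed_eyes_inflate_velocity(self, rng):
        """Monte-Carlo check of the built-in condition effect direction:
        with ce_multiplier 1.6 the mean V under CE exceeds OE (one-sided
        test at alpha = 0.01, n = 200 trials per condition)."""
        v = {}
        for vision in ("OE", "CE"):
            vals = [
                mean_velocity(
                    simulate_trial(
                        _profile(), OUParams(), (vision, "OF"), 10.24, 50.0,
                        rng=rng, ce_multiplier=1.6,
                    )
                )
                for _ in range(200)
            ]
            v[vision] = np.asarray(vals)
        t = stats.ttest_ind(v["CE"], v["OE"], alternative="greater")
        assert t.pvalue < 0.01


class TestSimulateStudy:
    def test_bit_identical_under_fixed_seed(self):
        design = small_design()
        a = simulate_study(design)
        b = simulate_study(design)
        pd.testing.assert_frame_equal(a.study, b.study, check_exact=True)
        pd.testing.assert_frame_equal(a.subjects, b.subjects, check_exact=True)

    def test_no_dropout_keeps_all_conditions(self):
        sim = simulate_study(small_design(n_subjects=8))
        per_session = sim.study.groupby(["subject_id", "session_index"]).apply(
            lambda g: set(zip(g["vision"], g["support"])), include_groups=False
        )
        assert all(s == set(CONDITIONS) for s in per_session)

    def test_row_count_bookkeeping(self):
        """Rows = sessions x surviving conditions x trials, exactly."""
        design = StudyDesign(seed=42)  # default cohort incl. dropout
        sim = simulate_study(design)
        expected = 0
        for s in sim.subjects.itertuples():
            n_conds = sum(
                not ((v == "CE" and s.drop_ce) or (su == "CF" and s.drop_cf))
                for v, su in CONDITIONS
            )
            expected += s.n_sessions * n_conds * design.trials_per_condition
        assert len(sim.study) == expected

    def test_cohort_size_near_target(self, default_sim):
        """Default design: ~23 subjects, ~111 sessions."""
        n_sessions = (
            default_sim.study[["subject_id", "session_index"]]
            .drop_duplicates()
            .shape[0]
        )
        assert default_sim.subjects.shape[0] == 23
        assert 80 <= n_sessions <= 145

    def test_scale_bounds_and_sum(self, default_sim):
        s = default_sim.study
        assert s["bbs"].between(0, 56).all()
        assert s["ts"].between(0, 40).all()
        assert s["ts_e"].between(0, 24).all()
        assert s["ts_l"].between(0, 16).all()
        assert s["wisci"].between(0, 20).all()
        assert (s["ts"] == s["ts_e"] + s["ts_l"]).all()

    def test_heel_distance_only_for_feet_apart(self, default_sim):
        s = default_sim.study
        assert s.loc[s["support"] == "OF", "heel_distance_cm"].notna().all()
        assert s.loc[s["support"] == "CF", "heel_distance_cm"].isna().all()

    def test_dropout_hits_low_ability_tail(self):
        sim = simulate_study(StudyDesign(seed=9))
        sub = sim.subjects
        if sub["drop_cf"].any() and (~sub["drop_cf"]).any():
            assert (
                sub.loc[sub["drop_cf"], "latent_ability"].max()
                < sub.loc[~sub["drop_cf"], "latent_ability"].min()
            )
        # monotone difficulty: anyone unable to close eyes also within the
        # feet-together dropout tail (dropout_prob_cf >= dropout_prob_ce)
        assert not (sub["drop_ce"] & ~sub["drop_cf"]).any()

    def test_validates_design(self):
        with pytest.raises(InvalidArgumentError):
            StudyDesign(trials_per_condition=1, seed=0)
        with pytest.raises(InvalidArgumentError):
            StudyDesign(dropout_prob_ce=1.5, seed=0)
        with pytest.raises(InvalidArgumentError):
            StudyDesign(ce_multiplier=0.0, seed=0)


class TestDesignRecovery:
    def test_bbs_correlation_matches_design_target(self):
        """With vanishing trial noise and many subjects, the Spearman
        correlation between BBS and session-mean V approaches the
        design-implied value (within +/- 0.1)."""
        design = small_design(
            n_subjects=250, sessions_per_subject=1, trial_sd_log_sway=0.01, seed=5
        )
        sim = simulate_study(design)
        of_oe = sim.study[(sim.study["vision"] == "OE") & (sim.study["support"] == "OF")]
        per_session = of_oe.groupby("subject_id").agg({"V": "mean", "bbs": "first"})
        rho = stats.spearmanr(per_session["bbs"], per_session["V"]).statistic
        target = design.expected_scale_correlation("bbs")
        assert target < 0
        assert rho == pytest.approx(target, abs=0.1)

    def test_session_icc_matches_design(self):
        """One large two-session study: the ICC of log session-mean V falls
        inside the estimate's 95 % CI of the design-implied
        tau^2/(tau^2 + sigma_session^2)."""
        design = small_design(
            n_subjects=120, sessions_per_subject=2, trial_sd_log_sway=0.02, seed=11
        )
        sim = simulate_study(design)
        of_oe = sim.study[(sim.study["vision"] == "OE") & (sim.study["support"] == "OF")]
        mat = (
            of_oe.groupby(["subject_id", "session_index"])["V"]
            .mean()
            .unstack()
            .to_numpy()
        )
        icc, (lo, hi) = icc_3_1(np.log(mat))
        assert lo <= design.expected_session_icc() <= hi
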