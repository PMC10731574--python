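import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachcomp import (
    ChainConfig,
    JointProgram,
    MarkerName,
    Side,
    Task,
    analytic_decomposition_oracle,
    decompose,
    detect_reach_window,
    full_trial_window,
    get_preset,
    marker_positions_from_pose,
    minimum_jerk_profile,
    simulate_cohort,
    simulate_trial,
)
from reachcomp.decomposition import components_mapping
from reachcomp.errors import ReachcompError
from reachcomp.simulator import DOF_NAMES, REST_POSE, StrategyPreset, TruncatedNormal

M = MarkerName


class TestMinimumJerkProfile:
    def test_boundaries(self):
        assert minimum_jerk_profile(0.0, 0.0, 1.0) == 0.0
        assert minimum_jerk_profile(1.0, 0.0, 1.0) == 1.0
        assert minimum_jerk_profile(-5.0, 0.0, 1.0) == 0.0
        assert minimum_jerk_profile(99.0, 0.0, 1.0) == 1.0

    def test_midpoint_symmetry(self):
        assert minimum_jerk_profile(0.5, 0.0, 1.0) == pytest.approx(0.5)

    def test_rest_to_rest_derivatives(self):
        eps = 1e-6
        v0 = (minimum_jerk_profile(eps, 0, 1) - 0.0) / eps
        v1 = (1.0 - minimum_jerk_profile(1 - eps, 0, 1)) / eps
        # analytic slope at distance eps from either end is 30*eps^2 ~ 3e-11
        assert v0 == pytest.approx(0.0, abs=1e-8)
        assert v1 == pytest.approx(0.0, abs=1e-8)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert minimum_jerk_profile(lo, 0, 1) <= minimum_jerk_profile(hi, 0, 1)

    def test_onset_and_duration_shift(self):
        assert minimum_jerk_profile(2.5, 2.0, 1.0) == pytest.approx(0.5)
        assert minimum_jerk_profile(1.9, 2.0, 1.0) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ReachcompError):
            minimum_jerk_profile(0.5, 0.0, 0.0)


class TestForwardKinematics:
    def test_rest_posture_geometry(self, chain):
        p = marker_positions_from_pose(chain, REST_POSE)
        np.testing.assert_allclose(
            p[M.MP_R] - p[M.ACROMION_R],
            [0.0, chain.forearm_length, -chain.upper_arm_length],
            atol=1e-12,
        )
        np.testing.assert_allclose(p[M.TROCHANTER_R], [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(
            p[M.C7], [0, 0, chain.trunk_length], atol=1e-12
        )

    def test_quarter_turn_trunk_flexion(self, chain):
        pose = REST_POSE | {"trunk_flexion": 90.0}
        p = marker_positions_from_pose(chain, pose)
        np.testing.assert_allclose(
            p[M.C7], [0.0, chain.trunk_length, 0.0], atol=1e-9
        )

    def test_girdle_elevation_rides_whole_arm(self, chain):
        rest = marker_positions_from_pose(chain, REST_POSE)
        shrug = marker_positions_from_pose(chain, REST_POSE | {"girdle_elevation": 40.0})
        for m in (M.ACROMION_R, M.EPICONDYLE_R, M.MP_R):
            np.testing.assert_allclose(shrug[m] - rest[m], [0, 0, 40.0], atol=1e-12)
        np.testing.assert_allclose(shrug[M.CHIN], rest[M.CHIN], atol=1e-12)

    def test_full_marker_set_emitted(self, chain):
        p = marker_positions_from_pose(chain, REST_POSE)
        assert set(p) == set(MarkerName)

    def test_left_side_mirrors_x(self, chain):
        pr = marker_positions_from_pose(chain, REST_POSE, Side.RIGHT)
        pl = marker_positions_from_pose(chain, REST_POSE, Side.LEFT)
        np.testing.assert_allclose(pl[M.MP_L][0], -pr[M.MP_R][0], atol=1e-12)
        np.testing.assert_allclose(pl[M.MP_L][1:], pr[M.MP_R][1:], atol=1e-12)

    def test_vectorized_over_frames(self, chain):
        pose = {d: np.linspace(REST_POSE[d], REST_POSE[d] + 10, 7) for d in DOF_NAMES}
        p = marker_positions_from_pose(chain, pose)
        assert p[M.MP_R].shape == (7, 3)
        single = marker_positions_from_pose(chain, {d: pose[d][3] for d in DOF_NAMES})
        np.testing.assert_allclose(p[M.MP_R][3], single[M.MP_R], atol=1e-12)


class TestChainConfig:
    def test_lengths_must_be_positive(self):
        with pytest.raises(ReachcompError):
            ChainConfig(upper_arm_length=-1.0)

    def test_declared_limb_length_consistency(self):
        # 300 + 330 = 630 mm acromion->MP is consistent with ~716 mm
        ChainConfig(upper_extremity_length=716.0)
        with pytest.raises(ReachcompError, match="inconsistent"):
            ChainConfig(upper_extremity_length=500.0)

    def test_from_upper_extremity_length_scales(self):
        cfg = ChainConfig.from_upper_extremity_length(717.0)
        reach = cfg.upper_arm_length + cfg.forearm_length
        assert reach == pytest.approx(0.88 * 717.0)


class TestSimulateTrial:
    def test_single_dof_elbow_gives_pure_shoulder_elbow(self, chain):
        program = JointProgram.from_end_values({"elbow_flexion": 0.0})  # full extension
        trial = simulate_trial(chain, program, Task.FORWARD_REACH)
        dec = decompose(trial, full_trial_window(trial))
        assert dec.percent_shoulder_elbow == pytest.approx(100.0, abs=1e-9)
        assert dec.trunk_rotation == pytest.approx(0.0, abs=1e-9)
        assert dec.trunk_flexion == pytest.approx(0.0, abs=1e-9)

    def test_seeding_contract(self, chain):
        program = JointProgram.from_end_values({"shoulder_flexion": 60.0})
        kw = dict(noise_sd=2.0, sampling_rate=60.0)
        a = simulate_trial(chain, program, Task.FORWARD_REACH, seed=7, **kw)
        b = simulate_trial(chain, program, Task.FORWARD_REACH, seed=7, **kw)
        c = simulate_trial(chain, program, Task.FORWARD_REACH, seed=8, **kw)
        assert a.allclose(b, atol=0.0)
        assert not a.allclose(c, atol=1e-6)

    def test_noise_free_matches_oracle(self, chain):
        program = JointProgram.from_end_values(
            {
                "shoulder_flexion": 55.0,
                "elbow_flexion": 25.0,
                "trunk_flexion": 12.0,
                "trunk_rotation": 6.0,
                "girdle_elevation": 15.0,
            },
            duration=1.1,
        )
        for task in Task:
            oracle = analytic_decomposition_oracle(chain, program, task)
            trial = simulate_trial(chain, program, task)
            dec = decompose(trial, detect_reach_window(trial, threshold_fraction=0.0))
            for name, expected in components_mapping(dec).items():
                assert expected == pytest.approx(oracle[name], abs=1e-6), name
            assert dec.total == pytest.approx(oracle["total"], abs=1e-6)

    def test_noise_magnitude_respected(self, chain):
        program = JointProgram.from_end_values({"shoulder_flexion": 60.0})
        clean = simulate_trial(chain, program, Task.FORWARD_REACH, noise_sd=0.0)
        noisy = simulate_trial(
            chain, program, Task.FORWARD_REACH, noise_sd=(2.4, 1.7, 1.7), seed=3
        )
        resid = noisy.marker(M.MP_R) - clean.marker(M.MP_R)
        sd = resid.std(axis=0)
        np.testing.assert_allclose(sd, [2.4, 1.7, 1.7], rtol=0.35)


class TestAnalyticOracle:
    def test_pure_trunk_flexion_forward(self, chain):
        program = JointProgram.from_end_values({"trunk_flexion": 20.0})
        oracle = analytic_decomposition_oracle(chain, program, Task.FORWARD_REACH)
        expected_c7 = chain.trunk_length * np.sin(np.radians(20.0))
        assert oracle["trunk_flexion"] == pytest.approx(expected_c7, abs=1e-9)
        assert oracle["shoulder_elbow"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_abduction_hand_to_mouth(self, chain):
        program = JointProgram.from_end_values({"shoulder_abduction": 30.0})
        oracle = analytic_decomposition_oracle(chain, program, Task.HAND_TO_MOUTH)
        expected = chain.upper_arm_length * (1 - np.cos(np.radians(30.0)))
        assert oracle["shoulder_abduction"] == pytest.approx(expected, abs=1e-9)
        assert oracle["girdle_elevation"] == pytest.approx(0.0, abs=1e-9)

    def test_telescoping_identity_any_program(self, chain, rng):
        for _ in range(20):
            ends = {
                "trunk_flexion": rng.uniform(0, 30),
                "trunk_rotation": rng.uniform(-10, 20),
                "girdle_elevation": rng.uniform(0, 40),
                "shoulder_flexion": rng.uniform(0, 80),
                "shoulder_abduction": rng.uniform(0, 40),
                "elbow_flexion": rng.uniform(20, 150),
                "neck_flexion": rng.uniform(-5, 15),
            }
            program = JointProgram.from_end_values(ends)
            for task in Task:
                oracle = analytic_decomposition_oracle(chain, program, task)
                parts = sum(v for k, v in oracle.items() if k != "total")
                assert parts == pytest.approx(oracle["total"], rel=1e-12, abs=1e-9)


class TestSingleDOFAttribution:
    """Each DOF moved alone lands in its assigned component (noise-free)."""

    CASES = [
        (Task.FORWARD_REACH, {"shoulder_flexion": 70.0}, "shoulder_elbow"),
        (Task.FORWARD_REACH, {"elbow_flexion": 0.0}, "shoulder_elbow"),
        (Task.FORWARD_REACH, {"trunk_rotation": 25.0}, "trunk_rotation"),
        (Task.FORWARD_REACH, {"trunk_flexion": 25.0}, "trunk_flexion"),
        (Task.HAND_TO_MOUTH, {"elbow_flexion": 140.0}, "shoulder_elbow_flexion"),
        (Task.HAND_TO_MOUTH, {"shoulder_abduction": 35.0}, "shoulder_abduction"),
        (Task.HAND_TO_MOUTH, {"girdle_elevation": 40.0}, "girdle_elevation"),
        (Task.HAND_TO_MOUTH, {"neck_flexion": 15.0}, "cervical_flexion"),
    ]

    @pytest.mark.parametrize("task,ends,component", CASES)
    def test_attribution(self, chain, task, ends, component):
        program = JointProgram.from_end_values(ends)
        oracle = analytic_decomposition_oracle(chain, program, task)
        total = oracle["total"]
        assert abs(total) > 1.0
        assert oracle[component] / total >= 0.99

    def test_shoulder_flexion_leaks_into_abduction_component(self, chain):
        # documented approximation: raising the arm forward elevates the
        # epicondyle, which the abduction formula picks up
        program = JointProgram.from_end_values({"shoulder_flexion": 40.0})
        oracle = analytic_decomposition_oracle(chain, program, Task.HAND_TO_MOUTH)
        leak = oracle["shoulder_abduction"]
        expected = chain.upper_arm_length * (1 - np.cos(np.radians(40.0)))
        assert leak == pytest.approx(expected, abs=1e-9)
        assert leak > 0


class TestSimulateCohort:
    def test_reproducible(self):
        preset = get_preset("stroke", Task.FORWARD_REACH)
        a = simulate_cohort(preset, 4, seed=11)
        b = simulate_cohort(preset, 4, seed=11)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert sa == sb
            assert ta.allclose(tb, atol=0.0)

    def test_zero_sd_preset_gives_identical_subjects_up_to_noise(self, chain):
        preset = StrategyPreset(
            name="frozen",
            group="healthy",
            task=Task.FORWARD_REACH,
            dof_end={"shoulder_flexion": TruncatedNormal(60.0, 0.0, 0.0, 90.0)},
            noise_sd=(0.0, 0.0, 0.0),
            uel_sd=0.0,
        )
        cohort = simulate_cohort(preset, 3, config=chain, seed=1)
        first = cohort[0][0]
        for trial, _ in cohort[1:]:
            assert trial.allclose(first, atol=1e-9)

    def test_group_difference_directions(self):
        means = {}
        for group, n, seed in (("healthy", 12, 2), ("stroke", 8, 1)):
            for task in Task:
                vals = []
                for trial, _ in simulate_cohort(get_preset(group, task), n, seed=seed):
                    from reachcomp.pipeline import analyze_trial

                    _, dec = analyze_trial(trial)
                    vals.append(dec)
                means[(group, task)] = vals
        fwd_h = np.mean([d.percent_trunk_flexion for d in means[("healthy", Task.FORWARD_REACH)]])
        fwd_s = np.mean([d.percent_trunk_flexion for d in means[("stroke", Task.FORWARD_REACH)]])
        assert fwd_s > fwd_h
        htm_h = np.mean([d.percent_shoulder_abduction for d in means[("healthy", Task.HAND_TO_MOUTH)]])
        htm_s = np.mean([d.percent_shoulder_abduction for d in means[("stroke", Task.HAND_TO_MOUTH)]])
        assert htm_s > htm_h

    def test_stroke_subjects_reach_left(self):
        cohort = simulate_cohort(get_preset("stroke", Task.FORWARD_REACH), 2, seed=0)
        for trial, subject in cohort:
            assert trial.reaching_side is Side.LEFT
            assert subject.group == "stroke"

    def test_invalid_n(self):
        with pytest.raises(ReachcompError):
            simulate_cohort(get_preset("healthy", Task.FORWARD_REACH), 0)


class TestNoiseRobustness:
    def test_percent_contributions_stable_under_device_noise(self, chain):
        # >= 200 mm reach under worst-case device noise: percent
        # contributions stay within 3 points of the noise-free values
        program = JointProgram.from_end_values(
            {"shoulder_flexion": 45.0, "elbow_flexion": 60.0, "trunk_flexion": 10.0}
        )
        from reachcomp.decomposition import percents_mapping
        from reachcomp.pipeline import analyze_trial

        clean = simulate_trial(chain, program, Task.FORWARD_REACH)
        _, dec0 = analyze_trial(clean, filter_trajectories=False)
        assert dec0.total_forward > 200.0
        ref = percents_mapping(dec0)

        ok = 0
        n_rep = 60
        for seed in range(n_rep):
            noisy = simulate_trial(
                chain, program, Task.FORWARD_REACH, noise_sd=(2.4, 1.7, 1.7), seed=seed
            )
            _, dec = analyze_trial(noisy)
            pct = percents_mapping(dec)
            if all(abs(pct[k] - ref[k]) < 3.0 for k in ref):
                ok += 1
        assert ok / n_rep >= 0.95
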