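import numpy as np
import pytest
from dataclasses import replace

from activecortex import synthetic
from activecortex.errors import ConfigurationError, ValidationError
from activecortex.synthetic import (
    derive_sc,
    generate_rt,
    make_ground_truth,
    make_trial_schedule,
    simulate_run,
)


class TestMakeGroundTruth:
    def test_sign_structure(self):
        m = make_ground_truth(n_roi=8, seed=1)
        half = 4
        for a in range(8):
            for b in range(8):
                w = m.edge_weight[a, b]
                if a == b or w == 0:
                    continue
                same = (a < half) == (b < half)
                if same or abs(a - b) == half:
                    assert w > 0
                else:
                    assert w < 0

    def test_contralateral_pairs_always_connected(self):
        m = make_ground_truth(n_roi=8, seed=3)
        for i in range(4):
            assert m.edge_weight[i, i + 4] > 0 and m.edge_weight[i + 4, i] > 0

    def test_same_seed_identical_models(self):
        a = make_ground_truth(seed=11)
        b = make_ground_truth(seed=11)
        np.testing.assert_array_equal(a.edge_weight, b.edge_weight)
        assert a.stimulus_rois == b.stimulus_rois

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_linearization_is_stable(self, seed):
        m = make_ground_truth(seed=seed)
        eig = np.linalg.eigvals(m.linearization("rest"))
        assert np.max(eig.real) < 0
        eig_task = np.linalg.eigvals(m.linearization("task:x"))
        assert np.max(eig_task.real) < 0

    def test_odd_roi_count_rejected(self):
        with pytest.raises(ConfigurationError):
            make_ground_truth(n_roi=7, seed=0)

    def test_task_mask_subset_of_rest(self):
        m = make_ground_truth(seed=4)
        assert not np.any(m.task_mask & ~m.rest_mask)
        assert np.all(np.diag(m.edge_weight) == 0)


class TestSimulateRun:
    def test_origin_is_fixed_point_without_noise(self):
        m = replace(make_ground_truth(seed=0), noise_sd=0.0)
        ts, _ = simulate_run(m, 50, seed=0)
        assert np.all(ts.values == 0.0)

    def test_isolated_node_decays_geometrically(self):
        m = make_ground_truth(seed=0)
        m = replace(
            m,
            edge_weight=np.zeros_like(m.edge_weight),
            rest_mask=np.zeros_like(m.rest_mask),
            task_mask=np.zeros_like(m.task_mask),
            noise_sd=0.0,
        )
        x0 = np.zeros(m.n_roi)
        x0[3] = 1.0
        ts, _ = simulate_run(m, 40, seed=0, initial_state=x0)
        expected = (1 + m.lambda_decay) ** np.arange(40)
        np.testing.assert_allclose(ts.values[3], expected, atol=1e-12)
        others = np.delete(np.arange(m.n_roi), 3)
        assert np.all(ts.values[others] == 0.0)

    def test_rest_run_is_stationary(self):
        m = make_ground_truth(n_roi=8, seed=2)
        ts, _ = simulate_run(m, 5000, seed=5)
        var = ts.values.var(axis=1)
        assert np.all(np.isfinite(var))
        assert np.all(var < 100 * m.noise_sd**2)
        first = ts.values[:, : 2500].var(axis=1)
        second = ts.values[:, 2500:].var(axis=1)
        assert np.all(second < 2 * np.maximum(first, 1e-12))

    def test_task_equals_rest_when_condition_effects_disabled(self):
        m = replace(
            make_ground_truth(seed=2),
            task_elevation=1.0,
            offtask_attenuation=1.0,
            stimulus_amp_mean=0.0,
            stimulus_amp_sd=0.0,
        )
        schedule = make_trial_schedule("synthetic", n_trials=10, seed=0)
        rest, _ = simulate_run(m, 800, seed=9)
        task, trials = simulate_run(m, 800, schedule=schedule, seed=9)
        np.testing.assert_array_equal(rest.values, task.values)
        assert np.all(trials.df["amplitude"].to_numpy() == 0.0)

    def test_schedule_overrun_rejected(self):
        m = make_ground_truth(seed=0)
        schedule = make_trial_schedule("synthetic", n_trials=10, seed=0)
        with pytest.raises(ValidationError):
            simulate_run(m, 100, schedule=schedule, seed=0)

    def test_too_short_run_rejected(self):
        with pytest.raises(ValidationError):
            simulate_run(make_ground_truth(seed=0), 1, seed=0)


class TestTrialSchedule:
    @pytest.mark.parametrize("task,n", [("WM", 80), ("GB", 32), ("REL", 27), ("EM", 30)])
    def test_default_trial_counts(self, task, n):
        assert len(make_trial_schedule(task, seed=0)) == n

    def test_single_trial_starts_at_requested_time(self):
        t = make_trial_schedule("WM", n_trials=1, start_s=12.0, seed=0)
        assert len(t) == 1 and t.onsets[0] == 12.0

    def test_empty_label_set_rejected(self):
        with pytest.raises(ConfigurationError):
            make_trial_schedule("custom", n_trials=5, subtask_labels=[], seed=0)


class TestGenerateRt:
    def test_affine_link_exact(self):
        m = replace(make_ground_truth(seed=0), rt_intercept_ms=1000.0, rt_slope_ms=-200.0)
        rt = generate_rt(m, np.array([1.0, 2.0]), rt_noise_sd=0.0, seed=0)
        np.testing.assert_allclose(rt, [800.0, 600.0])

    def test_noiseless_rt_decreasing_in_amplitude(self):
        m = make_ground_truth(seed=0)
        amps = np.linspace(0.1, 1.0, 20)
        rt = generate_rt(m, amps, rt_noise_sd=0.0, seed=0)
        assert np.all(np.diff(rt) < 0)

    def test_noisy_slope_recovered_by_ols(self):
        m = replace(make_ground_truth(seed=0), rt_intercept_ms=1000.0, rt_slope_ms=-200.0)
        rng = np.random.default_rng(42)
        amps = rng.uniform(0.5, 2.0, 500)
        rt = generate_rt(m, amps, rt_noise_sd=50.0, seed=7)
        design = np.column_stack([np.ones_like(amps), amps])
        coef, res, *_ = np.linalg.lstsq(design, rt, rcond=None)
        sigma2 = res[0] / (len(amps) - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(design.T @ design)[1, 1])
        assert abs(coef[1] - (-200.0)) < 3 * se

    def test_floor_at_100ms(self):
        m = make_ground_truth(seed=0)
        rt = generate_rt(m, np.array([100.0]), rt_noise_sd=0.0, seed=0)
        assert rt[0] == 100.0

    def test_nonpositive_amplitudes_rejected(self):
        with pytest.raises(ValidationError):
            generate_rt(make_ground_truth(seed=0), np.array([1.0, 0.0]), seed=0)


class TestDeriveSc:
    def test_undistorted_counts_proportional_to_positive_weights(self):
        m = make_ground_truth(seed=1)
        sc = derive_sc(m, distortion_sd=0.0, seed=0)
        pos = m.edge_weight > 0
        r = np.corrcoef(sc.counts[pos], np.abs(m.edge_weight[pos]))[0, 1]
        assert r > 1 - 1e-12
        assert np.all(sc.counts[m.edge_weight < 0] == 0)

    def test_counts_nonnegative(self):
        sc = derive_sc(make_ground_truth(seed=2), distortion_sd=0.5, seed=3)
        assert np.all(sc.counts >= 0)

    def test_distortion_degrades_but_preserves_correlation(self):
        m = make_ground_truth(n_roi=16, seed=4)
        sc = derive_sc(m, distortion_sd=0.5, seed=5)
        pos = m.edge_weight > 0
        r = np.corrcoef(sc.counts[pos], np.abs(m.edge_weight[pos]))[0, 1]
        assert 0.5 < r < 1.0


def test_two_task_models_share_rest_network():
    a, b = synthetic.two_task_models(seed=0)
    np.testing.assert_array_equal(a.edge_weight, b.edge_weight)
    assert not np.array_equal(a.task_mask, b.task_mask)
    overlap = np.sum(a.task_mask & b.task_mask)
    assert overlap > 0  # the tasks engage overlapping processes
    assert a.stimulus_rois != b.stimulus_rois
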