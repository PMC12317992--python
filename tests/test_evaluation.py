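import numpy as np
import pytest

from activecortex import synthetic
from activecortex.errors import ValidationError
from activecortex.evaluation import (
    canonical_hrf,
    derivative_prediction_correlation,
    ec_sc_correlation,
    fc_matrix,
    hrf_decay_rate,
    jacobian_eigenmodes,
    mean_abs_offdiagonal,
    pareto_sweep,
    simulate_hrf,
)
from activecortex.io import StructuralConnectivity
from activecortex.studies import _child_seeds, fit_ec_from_run
from activecortex.synthetic import TRIANGLE
from conftest import diagonal_ec, make_timeseries


class TestFcMatrix:
    def test_identical_rows_fully_correlated(self):
        x = np.tile(np.random.default_rng(0).standard_normal(50), (2, 1))
        fc = fc_matrix(x)
        assert fc[0, 1] == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        x = np.random.default_rng(1).standard_normal(50)
        fc = fc_matrix(np.vstack([x, -x]))
        assert fc[0, 1] == pytest.approx(-1.0)

    def test_independent_noise_nearly_uncorrelated(self):
        x = np.random.default_rng(2).standard_normal((6, 10_000))
        assert mean_abs_offdiagonal(fc_matrix(x)) < 0.03

    def test_constant_row_marked_missing(self):
        x = np.vstack([np.ones(30), np.random.default_rng(0).standard_normal(30)])
        fc = fc_matrix(x)
        assert np.isnan(fc[0, 1]) and fc[0, 0] == 1.0


class TestDerivativePrediction:
    def test_perfect_model_scores_one(self):
        # a pure-decay trajectory: forward increments equal the model drift
        lam = -0.2
        ec = diagonal_ec(4, lam)
        x0 = np.array([1.0, -2.0, 0.5, 3.0])
        traj = x0[:, None] * (1 + lam) ** np.arange(30)[None, :]
        r = derivative_prediction_correlation(ec, make_timeseries(traj), "forward")
        np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_permuted_edges_predict_no_flow_on_noise(self, fitted_ec):
        # network specificity: permuted edges predict none of the non-decay
        # derivative on runs with no network structure at all
        from activecortex.sysid import predict_derivative

        ec, _ = fitted_ec
        rng = np.random.default_rng(9)
        perm = rng.permutation(ec.n_roi)
        shuffled = diagonal_ec(ec.n_roi, ec.lambda_diag, order=ec.order)
        off = ec.order1().copy()
        np.fill_diagonal(off, 0.0)
        shuffled.coeffs[:, :, 0] += off[np.ix_(perm, perm)]
        noise = make_timeseries(rng.standard_normal((ec.n_roi, 5000)) * 0.1)
        measured_flow = np.diff(noise.values, axis=1) - ec.lambda_diag * noise.values[:, :-1]
        predicted_flow = (predict_derivative(shuffled, noise).values
                          - ec.lambda_diag * noise.values)[:, :-1]
        rs = [np.corrcoef(predicted_flow[a], measured_flow[a])[0, 1]
              for a in range(ec.n_roi)]
        assert np.mean(np.abs(rs)) < 0.05

    def test_recovered_model_predicts_heldout_dynamics(self, fitted_ec, model16):
        # pointwise r is bounded by the drift/noise power ratio; the fitted
        # model should approach that bound, far above the permuted null
        ec, _ = fitted_ec
        heldout, _ = synthetic.simulate_run(model16, 4000, seed=77)
        r = derivative_prediction_correlation(ec, heldout, "forward")
        assert np.nanmedian(r) > 0.25
        # and the model drift itself matches the true drift almost perfectly
        truth = model16.effective_weights("rest")
        drift = model16.lambda_decay * heldout.values + truth @ np.tanh(heldout.values)
        from activecortex.sysid import predict_derivative

        pred = predict_derivative(ec, heldout).values
        rs = [np.corrcoef(pred[a], drift[a])[0, 1] for a in range(16)]
        assert np.median(rs) > 0.9


class TestEcScCorrelation:
    def test_exact_proportionality_gives_one(self):
        ec = diagonal_ec(6, -0.22)
        rng = np.random.default_rng(0)
        ec.coeffs[:, :, 0] += np.abs(rng.standard_normal((6, 6))) * (~np.eye(6, dtype=bool))
        counts = np.abs(ec.order1().copy())
        np.fill_diagonal(counts, 0.0)
        sc = StructuralConnectivity(counts=counts, roi_labels=ec.roi_labels)
        assert ec_sc_correlation(ec, sc, order=1, edge_cls="all") == pytest.approx(1.0)

    def test_permuted_counts_uncorrelated_on_average(self, fitted_ec, model16):
        ec, _ = fitted_ec
        sc = synthetic.derive_sc(model16, distortion_sd=0.0, seed=0)
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(200):
            counts = sc.counts.copy()
            off = ~np.eye(16, dtype=bool)
            vals = counts[off]
            rng.shuffle(vals)
            counts[off] = vals
            np.fill_diagonal(counts, 0.0)
            perm_sc = StructuralConnectivity(counts=counts, roi_labels=sc.roi_labels)
            rs.append(ec_sc_correlation(ec, perm_sc, order=1, edge_cls="all"))
        assert np.mean(np.abs(rs)) < 0.1

    def test_zero_coefficients_rejected(self, model16):
        ec = diagonal_ec(16, -0.22, order=2)
        sc = synthetic.derive_sc(model16, seed=0)
        with pytest.raises(ValidationError):
            ec_sc_correlation(ec, sc, order=2, edge_cls="all")

    def test_unknown_class_rejected(self, fitted_ec, model16):
        ec, _ = fitted_ec
        sc = synthetic.derive_sc(model16, seed=0)
        with pytest.raises(ValidationError):
            ec_sc_correlation(ec, sc, edge_cls="nope")


class TestSimulateHrf:
    def test_decay_only_model_matches_convolution(self):
        lam = -0.22
        ec = diagonal_ec(4, lam)
        trace = simulate_hrf(ec, input_roi=1, n_starts=5, horizon=40)
        expected = np.zeros(40)
        stim = np.zeros(40)
        stim[1 : 1 + len(TRIANGLE)] = TRIANGLE
        for t in range(39):
            expected[t + 1] = (1 + lam) * expected[t] + stim[t]
        np.testing.assert_allclose(trace[1], expected, atol=1e-8)
        assert np.all(trace[[0, 2, 3]] == 0.0)

    def test_response_is_causal(self, fitted_ec, rest_run):
        ec, _ = fitted_ec
        trace = simulate_hrf(ec, input_roi=0, n_starts=20, reference=rest_run)
        peak = int(np.argmax(trace[0]))
        assert peak >= 1 + int(np.argmax(TRIANGLE))  # at or after the input peak

    def test_post_peak_amplitude_ordered_by_decay(self):
        values = {}
        for lam in (-0.06, -0.22, -0.4):
            trace = simulate_hrf(diagonal_ec(4, lam), input_roi=0, n_starts=1)[0]
            peak = int(np.argmax(trace))
            values[lam] = trace[peak + 15]
        assert values[-0.06] > values[-0.22] > values[-0.4]


class TestParetoSweep:
    @pytest.fixture(scope="class")
    def sweep(self, model16):
        s_model, s_train, s_held = _child_seeds(3, 3)
        model = synthetic.make_ground_truth(seed=s_model)
        train, _ = synthetic.simulate_run(model, 8000, seed=s_train)
        held, _ = synthetic.simulate_run(model, 2000, seed=s_held)
        sc = synthetic.derive_sc(model, distortion_sd=0.3, seed=1)
        return pareto_sweep(
            train, held, sc,
            lambda_grid=np.array([-0.06, -0.22, -0.4]),
            threshold_grid=np.array([0.0, 1e-3, 1e-2, 5e-2]),
        )

    def test_one_row_per_grid_point(self, sweep):
        assert len(sweep) == 12

    def test_nonzero_fraction_monotone_in_threshold(self, sweep):
        for lam, grp in sweep.groupby("lambda"):
            fracs = grp.sort_values("threshold")["nonzero_fraction"].to_numpy()
            assert np.all(np.diff(fracs) <= 1e-12)

    def test_operating_rule_attainable_on_fixture(self, sweep):
        assert sweep["meets_rule"].any()

    def test_tradeoff_is_nondegenerate(self, sweep):
        best_dyn = sweep["adjusted_r2"].idxmax()
        best_sc = sweep["sc_corr"].idxmax()
        assert best_dyn != best_sc


class TestJacobianEigenmodes:
    def test_decay_only_spectrum(self):
        vals, _ = jacobian_eigenmodes(diagonal_ec(5, -0.22))
        np.testing.assert_allclose(vals, -0.22)

    def test_symmetric_jacobian_has_real_spectrum(self):
        ec = diagonal_ec(6, -0.3)
        rng = np.random.default_rng(2)
        sym = rng.standard_normal((6, 6))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, -0.3)
        ec.coeffs[:, :, 0] = sym
        vals, _ = jacobian_eigenmodes(ec)
        assert np.max(np.abs(vals.imag)) < 1e-10
        assert np.all(np.diff(vals.real) <= 1e-12)  # sorted descending

    def test_fitted_model_is_stable(self, fitted_ec):
        ec, _ = fitted_ec
        vals, _ = jacobian_eigenmodes(ec)
        assert vals[0].real < 0


class TestHrfDecayRate:
    def test_canonical_shape(self):
        t = np.arange(0, 32, 0.72)
        h = canonical_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.04)  # peak near 5 s
        assert h.min() < 0  # undershoot present

    def test_falling_limb_rate_near_hemodynamic_value(self):
        assert hrf_decay_rate() == pytest.approx(-0.22, abs=0.005)


def test_residual_fc_weaker_than_measured(fitted_ec, model16):
    from activecortex.evaluation import evaluate_model

    ec, _ = fitted_ec
    heldout, _ = synthetic.simulate_run(model16, 4000, seed=55)
    report = evaluate_model(ec, heldout, derivative_method="forward")
    assert mean_abs_offdiagonal(report.fc_residual) < mean_abs_offdiagonal(report.fc_measured)
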