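import numpy as np
import pytest

from activecortex.errors import ConfigurationError, NumericalError, SchemaError
from activecortex.io import DerivativeMatrix
from activecortex.sysid import (
    LibraryMatrix,
    build_library,
    edge_function,
    fit_constrained_ridge,
    load_ec,
    predict_derivative,
    save_ec,
)
from conftest import diagonal_ec, make_timeseries

LAM = -0.22


class TestBuildLibrary:
    def test_monomial_row(self):
        ts = make_timeseries(np.array([[2.0], [3.0]]).repeat(2, axis=1))
        lib = build_library(ts, 2)
        np.testing.assert_array_equal(lib.values[0], [2, 3, 4, 9])

    def test_order_one_is_transposed_data(self):
        x = np.random.default_rng(0).standard_normal((4, 10))
        lib = build_library(make_timeseries(x), 1)
        np.testing.assert_array_equal(lib.values, x.T)

    def test_column_count_is_nroi_times_order(self):
        x = np.zeros((16, 9))
        assert build_library(make_timeseries(x), 7).values.shape[1] == 112

    @pytest.mark.parametrize("order", [0, 8])
    def test_order_outside_range_rejected(self, order):
        with pytest.raises(ConfigurationError):
            build_library(make_timeseries(np.zeros((2, 5))), order)


class TestConstrainedRidge:
    def _linear_instance(self, n_roi=10, n_samples=10_000, order=2, seed=0):
        """States and exact derivatives of a known linear network."""
        rng = np.random.default_rng(seed)
        j = rng.normal(0, 0.05, (n_roi, n_roi))
        np.fill_diagonal(j, LAM)
        # many short trajectories keep the state distribution well conditioned
        states, derivs = [], []
        n_restarts = 500
        per = n_samples // n_restarts
        for _ in range(n_restarts):
            x = rng.standard_normal(n_roi)
            for _ in range(per):
                states.append(x.copy())
                dx = j @ x
                derivs.append(dx)
                x = x + dx
        x_mat = np.array(states).T  # n_roi x n_samples
        d_mat = np.array(derivs).T
        lib = build_library(make_timeseries(x_mat), order)
        deriv = DerivativeMatrix(values=d_mat, method="forward")
        return j, lib, deriv

    def test_recovers_linear_network_exactly(self):
        j, lib, deriv = self._linear_instance()
        ec, _ = fit_constrained_ridge(lib, deriv, lambda_diag=LAM, ridge_alpha=1e-6, threshold=0.0)
        np.testing.assert_allclose(ec.order1(), j, atol=1e-4)
        assert np.max(np.abs(ec.coeffs[:, :, 1])) < 1e-4  # no spurious quadratic terms

    def test_matches_independent_ridge_oracle(self):
        # closed-form ridge via the augmented least-squares system
        j, lib, deriv = self._linear_instance(n_samples=2000, seed=3)
        alpha = 0.5
        ec, _ = fit_constrained_ridge(lib, deriv, lambda_diag=LAM, ridge_alpha=alpha, threshold=0.0)
        theta = lib.values
        n, p = lib.n_roi, lib.order
        for a in range(n):
            free = [c for c in range(n * p) if c != a]
            design = np.vstack([theta[:, free], np.sqrt(alpha) * np.eye(len(free))])
            target = np.concatenate([deriv.values[a] - LAM * theta[:, a], np.zeros(len(free))])
            beta, *_ = np.linalg.lstsq(design, target, rcond=None)
            mine = np.concatenate([ec.coeffs[a, :, k] for k in range(p)])[free]
            assert np.max(np.abs(mine - beta)) < 1e-8

    def test_diagonal_constraint_reinstated_exactly(self, fitted_ec, model16):
        ec, _ = fitted_ec
        assert np.all(np.diag(ec.order1()) == model16.lambda_decay)

    def test_infinite_threshold_leaves_decay_only(self):
        _, lib, deriv = self._linear_instance(n_samples=1000, seed=1)
        ec, _ = fit_constrained_ridge(lib, deriv, lambda_diag=LAM, threshold=np.inf)
        off = ~np.eye(lib.n_roi, dtype=bool)
        assert np.all(ec.order1()[off] == 0.0)
        assert np.all(ec.coeffs[:, :, 1] == 0.0)
        ts = make_timeseries(np.random.default_rng(0).standard_normal((lib.n_roi, 20)))
        pred = predict_derivative(ec, ts)
        np.testing.assert_allclose(pred.values, LAM * ts.values)

    def test_nonzero_fraction_non_increasing_in_threshold(self):
        _, lib, deriv = self._linear_instance(n_samples=2000, seed=2)
        fracs = [
            fit_constrained_ridge(lib, deriv, lambda_diag=LAM, threshold=thr)[1].nonzero_fraction
            for thr in (0.0, 1e-3, 1e-2, 0.05, 0.2)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_singular_design_without_ridge_raises_hint(self):
        x = np.zeros((4, 50))  # all-zero states: singular gram matrix
        lib = build_library(make_timeseries(x), 1)
        deriv = DerivativeMatrix(values=np.zeros((4, 50)), method="forward")
        with pytest.raises(NumericalError, match="ridge_alpha"):
            fit_constrained_ridge(lib, deriv, lambda_diag=LAM, ridge_alpha=0.0, threshold=0.0)

    def test_shape_mismatch_rejected(self):
        lib = build_library(make_timeseries(np.zeros((4, 50))), 1)
        deriv = DerivativeMatrix(values=np.zeros((4, 49)), method="forward")
        with pytest.raises(SchemaError):
            fit_constrained_ridge(lib, deriv, lambda_diag=LAM)


class TestPredictDerivative:
    def test_zero_state_gives_zero_derivative(self):
        ec = diagonal_ec(4, LAM, order=3)
        pred = predict_derivative(ec, make_timeseries(np.zeros((4, 10))))
        assert np.all(pred.values == 0.0)

    def test_single_edge_arithmetic(self):
        ec = diagonal_ec(4, -0.2)
        ec.coeffs[0, 1, 0] = 0.5  # edge b=1 -> a=0
        state = np.zeros((4, 1))
        state[0, 0], state[1, 0] = 1.0, 2.0
        pred = predict_derivative(ec, make_timeseries(np.column_stack([state, state])))
        assert pred.values[0, 0] == pytest.approx(-0.2 * 1.0 + 0.5 * 2.0)

    def test_training_prediction_is_library_times_coefficients(self, fitted_ec, rest_run):
        ec, _ = fitted_ec
        lib = build_library(rest_run, ec.order)
        direct = ec.as_design_matrix() @ lib.values.T
        pred = predict_derivative(ec, rest_run)
        assert np.max(np.abs(pred.values - direct)) < 1e-10


class TestEdgeFunction:
    def test_zero_edge_gives_zero_curve(self):
        ec = diagonal_ec(4, LAM)
        curve, _ = edge_function(ec, 0, 1, np.linspace(-1, 1, 11))
        assert np.all(curve == 0.0)

    def test_matches_horner_evaluation(self):
        ec = diagonal_ec(4, LAM, order=3)
        ec.coeffs[0, 1] = [1.0, 0.0, -1 / 6]  # cubic-truncated sigmoid shape
        grid = np.linspace(-1, 1, 21)
        curve, _ = edge_function(ec, 0, 1, grid)
        expected = np.array([np.polyval([-1 / 6, 0.0, 1.0, 0.0], x) for x in grid])
        np.testing.assert_allclose(curve, expected, atol=1e-12)

    def test_edge_classes(self):
        ec = diagonal_ec(4, LAM)
        assert edge_function(ec, 0, 1, np.zeros(1))[1] == "intrahemispheric"
        assert edge_function(ec, 0, 2, np.zeros(1))[1] == "contralateral"
        assert edge_function(ec, 1, 2, np.zeros(1))[1] == "interhemispheric"
        assert edge_function(ec, 1, 1, np.zeros(1))[1] == "diagonal"
        with pytest.raises(IndexError):
            edge_function(ec, 0, 9, np.zeros(1))


def test_save_load_round_trip_bit_exact(tmp_path, fitted_ec):
    ec, _ = fitted_ec
    save_ec(ec, tmp_path / "ec")
    back = load_ec(tmp_path / "ec")
    np.testing.assert_array_equal(back.coeffs, ec.coeffs)
    np.testing.assert_array_equal(back.sparsity_mask, ec.sparsity_mask)
    assert back.lambda_diag == ec.lambda_diag
    assert back.roi_labels == ec.roi_labels
    assert back.training_meta == ec.training_meta
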