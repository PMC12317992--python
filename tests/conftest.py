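import numpy as np
import pytest

from activecortex import synthetic
from activecortex.io import RoiTimeseries, estimate_derivative
from activecortex.separation import extract_trial_windows
from activecortex.studies import _task_fixture, fit_ec_from_run
from activecortex.sysid import EffectiveConnectivity


def make_timeseries(values, tr=0.72, condition="rest", run_id="run-0"):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    half = n // 2
    labels = [f"roi{i:02d}_L" for i in range(half)] + [f"roi{i:02d}_R" for i in range(n - half)]
    hemis = ["left"] * half + ["right"] * (n - half)
    return RoiTimeseries(values=values, tr_seconds=tr, roi_labels=labels,
                         hemisphere=hemis, condition=condition, run_id=run_id)


def diagonal_ec(n_roi, lam, order=1):
    """Effective connectivity with only the decay term."""
    coeffs = np.zeros((n_roi, n_roi, order))
    mask = np.zeros_like(coeffs, dtype=bool)
    for a in range(n_roi):
        coeffs[a, a, 0] = lam
        mask[a, a, 0] = True
    half = n_roi // 2
    return EffectiveConnectivity(
        coeffs=coeffs, lambda_diag=lam, order=order, sparsity_mask=mask,
        roi_labels=[f"roi{i:02d}_L" for i in range(half)] + [f"roi{i:02d}_R" for i in range(n_roi - half)],
        hemisphere=["left"] * half + ["right"] * (n_roi - half),
    )


@pytest.fixture(scope="session")
def model16():
    return synthetic.make_ground_truth(seed=0)


@pytest.fixture(scope="session")
def rest_run(model16):
    ts, _ = synthetic.simulate_run(model16, 6000, seed=1)
    return ts


@pytest.fixture(scope="session")
def fitted_ec(rest_run, model16):
    ec, report = fit_ec_from_run(rest_run, lambda_diag=model16.lambda_decay)
    return ec, report


@pytest.fixture(scope="session")
def task_windows(model16):
    """Held-out task run: (windows, rt), smoothed-derivative windows."""
    ts, trials, rt = _task_fixture(model16, seed=21, n_trials=60)
    deriv = estimate_derivative(ts, "smoothed_finite_difference")
    win = extract_trial_windows(ts, deriv, trials)
    return win, rt[: win.n_trials]


@pytest.fixture(scope="session")
def rest_task_ecs(model16, rest_run):
    """Rest and task models fitted with the window-consistent estimator."""
    ec_rest, _ = fit_ec_from_run(rest_run, lambda_diag=model16.lambda_decay,
                                 derivative_method="smoothed_finite_difference")
    train_ts, _, _ = _task_fixture(model16, seed=22, n_trials=120)
    ec_task, _ = fit_ec_from_run(train_ts, lambda_diag=model16.lambda_decay,
                                 derivative_method="smoothed_finite_difference")
    return ec_rest, ec_task
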