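"""Seeded study procedures over the synthetic ground truth.

Each function runs one self-contained experiment at desk scale and returns
plain numbers, so the numbered analysis scripts, the test suite and the
acceptance script all execute exactly the same computations.

Problem sizes (the package's study conditions): 16 regions, 20,000-sample
rest runs for model identification, 500 training / 300 test trials for the
reaction-time studies, and 50 individuals per task (6 trials each) for the
functional-connectivity embedding study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import behavior, evaluation, fc_embed, synthetic
from .io import estimate_derivative
from .separation import SeparationSpec, extract_trial_windows, separate_window, sweep_c1_c2
from .synthetic import GroundTruthModel, make_ground_truth, make_trial_schedule, simulate_run
from .sysid import build_library, fit_constrained_ridge

logger = logging.getLogger(__name__)

DERIVATIVE_METHOD = "forward"  # Euler-matched estimator for model fitting
WINDOW_DERIVATIVE_METHOD = "smoothed_finite_difference"  # smooth, BOLD-like trial windows
REST_SAMPLES = 20_000
TRAIN_TRIALS = 500
TEST_TRIALS = 300
TRIAL_SPACING_S = 21.6  # 30 samples at TR = 0.72 s
RT_NOISE_SD = 40.0


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def fit_ec_from_run(ts, lambda_diag: float = -0.22, order: int = 1,
                    ridge_alpha: float = 1e-2, threshold: float = 1e-3,
                    derivative_method: str = DERIVATIVE_METHOD):
    """Identify a network model from one run (shared fitting settings)."""
    deriv = estimate_derivative(ts, derivative_method)
    lib = build_library(ts, order)
    return fit_constrained_ridge(lib, deriv, lambda_diag=lambda_diag,
                                 ridge_alpha=ridge_alpha, threshold=threshold)


# ---------------------------------------------------------------------------
# decay constant from the canonical HRF
# ---------------------------------------------------------------------------

def hrf_decay_study(tr_seconds: float = 0.72) -> float:
    """Exponential decay rate of the canonical double-gamma HRF's falling limb."""
    return evaluation.hrf_decay_rate(tr_seconds=tr_seconds)


# ---------------------------------------------------------------------------
# parameter recovery on rest runs
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    order1_correlation: float
    negative_edge_sign_fraction: float
    diagonal_exact: bool
    heldout_median_r: float


def recovery_study(seed: int = 0, n_roi: int = 16, n_samples: int = REST_SAMPLES,
                   order: int = 1) -> RecoveryResult:
    """Fit a rest run of a known network and compare with the ground truth.

    The recovered first-order coefficients are correlated with the true
    linearization over off-diagonal entries; the fraction of truly negative
    interhemispheric edges recovered with negative sign is also reported,
    along with the held-out derivative-prediction correlation.
    """
    s_model, s_train, s_test = _child_seeds(seed, 3)
    model = make_ground_truth(n_roi=n_roi, seed=s_model)
    train, _ = simulate_run(model, n_samples, seed=s_train)
    ec, _ = fit_ec_from_run(train, lambda_diag=model.lambda_decay, order=order)

    truth = model.linearization("rest")
    off = ~np.eye(n_roi, dtype=bool)
    corr = float(np.corrcoef(ec.order1()[off], truth[off])[0, 1])
    neg = model.edge_weight < 0
    sign_frac = float(np.mean(ec.order1()[neg] < 0)) if neg.any() else float("nan")
    diag_exact = bool(np.all(np.diag(ec.order1()) == model.lambda_decay))

    heldout, _ = simulate_run(model, 5_000, seed=s_test)
    r = evaluation.derivative_prediction_correlation(ec, heldout, DERIVATIVE_METHOD)
    return RecoveryResult(corr, sign_frac, diag_exact, float(np.nanmedian(r)))


def fc_component_study(seed: int = 0, n_roi: int = 16) -> dict[str, float]:
    """Mean |off-diagonal| FC of measured, network-predicted and residual derivative."""
    s_model, s_train, s_test = _child_seeds(seed, 3)
    model = make_ground_truth(n_roi=n_roi, seed=s_model)
    train, _ = simulate_run(model, REST_SAMPLES, seed=s_train)
    ec, _ = fit_ec_from_run(train, lambda_diag=model.lambda_decay)
    heldout, _ = simulate_run(model, 5_000, seed=s_test)
    report = evaluation.evaluate_model(ec, heldout, sc=None, derivative_method=DERIVATIVE_METHOD)
    return {
        "fc_measured_mean": evaluation.mean_abs_offdiagonal(report.fc_measured),
        "fc_network_mean": evaluation.mean_abs_offdiagonal(report.fc_predicted),
        "fc_residual_mean": evaluation.mean_abs_offdiagonal(report.fc_residual),
    }


# ---------------------------------------------------------------------------
# reaction-time separation study (framework comparison + c1/c2 sweep)
# ---------------------------------------------------------------------------

@dataclass
class SeparationReplicate:
    base_max_corr: float
    base_r2: float
    delta_max_corr: dict[str, float]
    delta_r2: dict[str, float]
    sweep_best_cell: tuple[float, float]


def _task_fixture(model: GroundTruthModel, seed: int, n_trials: int, task_name: str = "synthetic"):
    """One task run with a schedule, realized amplitudes and RTs."""
    s_run, s_rt = _child_seeds(seed, 2)
    schedule = make_trial_schedule(task_name, n_trials=n_trials, spacing_s=TRIAL_SPACING_S, seed=s_run)
    n_samples = int(round(schedule.onsets[-1] / synthetic.TR_SECONDS)) + 100
    ts, trials = simulate_run(model, n_samples, schedule=schedule, seed=s_run, task_name=task_name)
    amps = trials.df["amplitude"].to_numpy()
    rt = synthetic.generate_rt(model, amps, rt_noise_sd=RT_NOISE_SD, seed=s_rt)
    return ts, trials, rt


def separation_replicate(seed: int, run_sweep: bool = False) -> SeparationReplicate:
    """One full replicate: fit rest and task models, separate, score RT links."""
    s_model, s_rest, s_train, s_test = _child_seeds(seed, 4)
    model = make_ground_truth(seed=s_model)

    rest, _ = simulate_run(model, REST_SAMPLES, seed=s_rest)
    ec_rest, _ = fit_ec_from_run(rest, lambda_diag=model.lambda_decay,
                                 derivative_method=WINDOW_DERIVATIVE_METHOD)

    train_ts, _, _ = _task_fixture(model, s_train, TRAIN_TRIALS)
    ec_task, _ = fit_ec_from_run(train_ts, lambda_diag=model.lambda_decay,
                                 derivative_method=WINDOW_DERIVATIVE_METHOD)

    test_ts, test_trials, rt = _task_fixture(model, s_test, TEST_TRIALS)
    deriv = estimate_derivative(test_ts, WINDOW_DERIVATIVE_METHOD)
    win = extract_trial_windows(test_ts, deriv, test_trials)
    rt = rt[: win.n_trials]

    base = separate_window(win, ec_rest, ec_task, SeparationSpec.named("unseparated"))
    base_mc = behavior.max_abs_correlation(behavior.spatiotemporal_rt_correlation(base, rt))
    base_r2 = float(np.mean(behavior.elastic_net_rt(base, rt, seed=seed)))

    d_mc, d_r2 = {}, {}
    for name in ("rest_baseline", "task_baseline", "acm"):
        sep = separate_window(win, ec_rest, ec_task, SeparationSpec.named(name))
        mc = behavior.max_abs_correlation(behavior.spatiotemporal_rt_correlation(sep, rt))
        r2 = float(np.mean(behavior.elastic_net_rt(sep, rt, seed=seed)))
        d_mc[name] = mc - base_mc
        d_r2[name] = r2 - base_r2

    best = (0.0, 0.0)
    if run_sweep:
        grid = sweep_c1_c2(win, ec_rest, ec_task, rt)
        row = grid.loc[grid["delta_max_corr"].idxmax()]
        best = (float(row["c1"]), float(row["c2"]))
    return SeparationReplicate(base_mc, base_r2, d_mc, d_r2, best)


def separation_study(seed: int = 0, n_replicates: int = 12, n_sweeps: int = 4) -> dict:
    """Median framework effects over seeded replicates (Fig. 2-style ordering).

    The c1/c2 sweep is run on the first ``n_sweeps`` replicates; a sweep
    maximum is 'on the diagonal' when |c1 + c2| <= 0.5 (one grid step).
    """
    seeds = _child_seeds(seed, n_replicates)
    reps = [separation_replicate(s, run_sweep=(i < n_sweeps)) for i, s in enumerate(seeds)]
    out: dict = {"n_replicates": n_replicates}
    for name in ("rest_baseline", "task_baseline", "acm"):
        out[f"median_delta_max_corr_{name}"] = float(np.median([r.delta_max_corr[name] for r in reps]))
        out[f"median_delta_r2_{name}"] = float(np.median([r.delta_r2[name] for r in reps]))
    out["median_base_max_corr"] = float(np.median([r.base_max_corr for r in reps]))
    out["median_base_r2"] = float(np.median([r.base_r2 for r in reps]))
    diag = [abs(sum(r.sweep_best_cell)) <= 0.5 for r in reps[:n_sweeps]]
    out["sweep_diagonal_fraction"] = float(np.mean(diag)) if diag else float("nan")
    return out


# ---------------------------------------------------------------------------
# two-task functional-connectivity embedding study
# ---------------------------------------------------------------------------

TWO_TASK_INDIVIDUALS = 50
TWO_TASK_TRIALS = 6
INDIVIDUAL_JITTER_SD = 0.5


def two_task_replicate(seed: int) -> dict[str, float]:
    """UMAP/SVM separability of per-individual task FCs, before/after ACM."""
    s_model, s_rest, s_a, s_b, s_ind = _child_seeds(seed, 5)
    model_a, model_b = synthetic.two_task_models(seed=s_model)

    rest, _ = simulate_run(model_a, REST_SAMPLES, seed=s_rest)
    ec_rest, _ = fit_ec_from_run(rest, lambda_diag=model_a.lambda_decay,
                                 derivative_method=WINDOW_DERIVATIVE_METHOD)
    ecs = {}
    for name, model, s in (("A", model_a, s_a), ("B", model_b, s_b)):
        train_ts, _, _ = _task_fixture(model, s, TRAIN_TRIALS, task_name=name)
        ecs[name], _ = fit_ec_from_run(train_ts, lambda_diag=model.lambda_decay,
                                       derivative_method=WINDOW_DERIVATIVE_METHOD)

    ind_seeds = _child_seeds(s_ind, 2 * TWO_TASK_INDIVIDUALS)
    fcs_unsep, fcs_acm, labels = [], [], []
    for i, s in enumerate(ind_seeds):
        name = "A" if i < TWO_TASK_INDIVIDUALS else "B"
        model = model_a if name == "A" else model_b
        individual = synthetic.jitter_individual(model, INDIVIDUAL_JITTER_SD, s)
        ts, trials, _ = _task_fixture(individual, s + 1, TWO_TASK_TRIALS, task_name=name)
        deriv = estimate_derivative(ts, WINDOW_DERIVATIVE_METHOD)
        win = extract_trial_windows(ts, deriv, trials)
        sep = separate_window(win, ec_rest, ecs[name], SeparationSpec.named("acm"))
        fcs_unsep.append(fc_embed.individual_task_fc(win))
        fcs_acm.append(fc_embed.individual_task_fc(sep))
        labels.append(name)
    labels = np.asarray(labels)

    out = {}
    for tag, fcs in (("unseparated", fcs_unsep), ("acm", fcs_acm)):
        coords = fc_embed.embed_fcs(np.stack(fcs), seed=seed)
        acc, _ = fc_embed.classify_embedding(coords, labels, seed=seed)
        dist = fc_embed.cluster_distances(coords, labels)
        out[f"svm_accuracy_{tag}"] = acc
        out[f"distance_ratio_{tag}"] = dist.between_within_ratio
    return out


def two_task_study(seed: int = 0, n_replicates: int = 3) -> dict[str, float]:
    """Medians of the embedding metrics over seeded replicates (Fig. 4 analog)."""
    seeds = _child_seeds(seed, n_replicates)
    reps = [two_task_replicate(s) for s in seeds]
    out = {"n_replicates": float(n_replicates)}
    for key in reps[0]:
        out[f"median_{key}"] = float(np.median([r[key] for r in reps]))
    return out
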