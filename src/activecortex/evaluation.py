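"""Plausibility metrics for an identified network ODE.

Three criteria judge a fitted model: (1) it should predict held-out
derivative timeseries, (2) its first-order coefficients should resemble the
structural (tractography) network, and (3) its impulse response should look
like a hemodynamic response function (HRF).  A hyperparameter sweep exposes
the trade-off between (1) and (2) as a Pareto table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma

from .errors import StabilityError, ValidationError
from .io import DerivativeMatrix, RoiTimeseries, StructuralConnectivity, edge_class, estimate_derivative
from .synthetic import TRIANGLE
from .sysid import EffectiveConnectivity, build_library, fit_constrained_ridge, predict_derivative, predict_derivative_states

logger = logging.getLogger(__name__)


def fc_matrix(values: np.ndarray) -> np.ndarray:
    """ROI x ROI Pearson correlation; constant rows yield NaN entries."""
    x = np.asarray(values, dtype=float)
    if x.shape[1] < 3:
        raise ValidationError("functional connectivity needs at least 3 samples")
    sd = x.std(axis=1)
    fc = np.corrcoef(x)
    const = sd < 1e-15
    if np.any(const):
        logger.warning("FC undefined for %d constant row(s); entries set to NaN", int(const.sum()))
        fc[const, :] = np.nan
        fc[:, const] = np.nan
    np.fill_diagonal(fc, 1.0)
    return fc


def mean_abs_offdiagonal(fc: np.ndarray) -> float:
    mask = ~np.eye(fc.shape[0], dtype=bool)
    return float(np.nanmean(np.abs(fc[mask])))


def derivative_prediction_correlation(
    ec: EffectiveConnectivity,
    ts_heldout: RoiTimeseries,
    derivative_method: str = "forward",
) -> np.ndarray:
    """Pearson r between predicted and measured derivative, per region."""
    measured = estimate_derivative(ts_heldout, derivative_method).values
    predicted = predict_derivative(ec, ts_heldout).values
    out = np.full(ec.n_roi, np.nan)
    for a in range(ec.n_roi):
        if measured[a].std() < 1e-15 or predicted[a].std() < 1e-15:
            logger.warning("region %d has zero variance; correlation recorded as missing", a)
            continue
        out[a] = np.corrcoef(predicted[a], measured[a])[0, 1]
    return out


def ec_sc_correlation(
    ec: EffectiveConnectivity,
    sc: StructuralConnectivity,
    order: int = 1,
    edge_cls: str = "all",
) -> float:
    """Correlate order-n coefficients with tract counts over off-diagonal edges.

    Intra- and interhemispheric classes are correlated with signed
    coefficients (the sign structure is the finding of interest); the
    ``all`` class uses magnitudes, since tract counts carry no sign.
    """
    if edge_cls not in ("intrahemispheric", "interhemispheric", "all"):
        raise ValidationError(f"unknown edge class {edge_cls!r}")
    if not 1 <= order <= ec.order:
        raise ValidationError(f"order {order} outside fitted range 1..{ec.order}")
    n = ec.n_roi
    xs, ys = [], []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            cls = edge_class(a, b, ec.roi_labels, ec.hemisphere)
            if edge_cls != "all" and not (
                cls == edge_cls or (edge_cls == "interhemispheric" and cls == "contralateral")
            ):
                continue
            coef = ec.coeffs[a, b, order - 1]
            xs.append(abs(coef) if edge_cls == "all" else coef)
            ys.append(sc.counts[a, b])
    if len(xs) < 3:
        raise ValidationError(f"edge class {edge_cls!r} has fewer than 3 edges")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.std() < 1e-15 or ys.std() < 1e-15:
        raise ValidationError("degenerate inputs: zero variance in coefficients or counts")
    return float(np.corrcoef(xs, ys)[0, 1])


def simulate_hrf(
    ec: EffectiveConnectivity,
    input_roi: int,
    n_starts: int = 100,
    seed: int = 0,
    reference: RoiTimeseries | None = None,
    horizon: int = 40,
) -> np.ndarray:
    """Mean impulse response of the identified system (n_roi x horizon).

    Starting states are the ``n_starts`` samples of the reference run
    nearest the origin (all-zero states when no reference is given); from
    each, the ODE is integrated forward with a single triangular input
    (unit peak, 3 samples up / 3 down) injected into the derivative of
    ``input_roi``, and trajectories are averaged across starts.
    """
    n = ec.n_roi
    if reference is None:
        starts = np.zeros((n_starts, n))
    else:
        norms = np.linalg.norm(reference.values, axis=0)
        idx = np.argsort(norms)[:n_starts]
        starts = reference.values[:, idx].T
    stim = np.zeros(horizon)
    stim[1 : 1 + len(TRIANGLE)] = TRIANGLE

    mean_trace = np.zeros((n, horizon))
    for x0 in starts:
        x = np.zeros((n, horizon))
        x[:, 0] = x0
        for t in range(horizon - 1):
            dx = predict_derivative_states(ec, x[:, t : t + 1])[:, 0]
            dx[input_roi] += stim[t]
            x[:, t + 1] = x[:, t] + dx
            if np.max(np.abs(x[:, t + 1])) > 1e6:
                raise StabilityError(
                    f"impulse response diverged; revisit lambda_diag={ec.lambda_diag} "
                    f"and threshold={ec.training_meta.get('threshold')}"
                )
        mean_trace += x
    return mean_trace / len(starts)


def canonical_hrf(t_seconds: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6)."""
    t = np.asarray(t_seconds, dtype=float)
    return gamma.pdf(t, 6.0) - gamma.pdf(t, 16.0) / 6.0


def hrf_decay_rate(tr_seconds: float = 0.72, stop_fraction: float = 0.1) -> float:
    """Per-sample exponential decay rate of the canonical HRF's falling limb.

    The canonical response is sampled at the scanner TR and a log-linear fit
    is taken from the peak down to ``stop_fraction`` of the peak value; below
    that the undershoot lobe dominates and the decay is no longer
    single-exponential.  Returned as the discrete-time rate ``lambda`` such
    that successive samples shrink by ``(1 + lambda)``.
    """
    t = np.arange(0.0, 32.0, tr_seconds)
    h = canonical_hrf(t)
    peak = int(np.argmax(h))
    limb = h[peak:]
    limb = limb[: int(np.argmax(limb <= 0)) or len(limb)]
    limb = limb[limb >= stop_fraction * h[peak]]
    slope = np.polyfit(np.arange(len(limb)), np.log(limb), 1)[0]
    return float(np.exp(slope) - 1.0)


@dataclass
class EvaluationReport:
    """Aggregate model-plausibility metrics."""

    per_roi_derivative_corr: np.ndarray
    fc_measured: np.ndarray
    fc_predicted: np.ndarray
    fc_residual: np.ndarray
    ec_sc_corr_by_order: list[float]
    pareto_rows: pd.DataFrame | None = None


def evaluate_model(
    ec: EffectiveConnectivity,
    heldout: RoiTimeseries,
    sc: StructuralConnectivity | None = None,
    derivative_method: str = "forward",
) -> EvaluationReport:
    """Criteria 1 and 2 on a held-out run: dynamics fit and SC similarity.

    The functional-connectivity triple compares the measured derivative, the
    model-predicted (network) derivative and their residual: a good network
    model leaves residuals with visibly weaker inter-regional correlation.
    """
    measured = estimate_derivative(heldout, derivative_method).values
    predicted = predict_derivative(ec, heldout).values
    residual = measured - predicted
    corr = derivative_prediction_correlation(ec, heldout, derivative_method)
    by_order = []
    if sc is not None:
        for k in range(1, ec.order + 1):
            try:
                by_order.append(ec_sc_correlation(ec, sc, order=k, edge_cls="all"))
            except ValidationError:
                by_order.append(float("nan"))
    return EvaluationReport(
        per_roi_derivative_corr=corr,
        fc_measured=fc_matrix(measured),
        fc_predicted=fc_matrix(predicted),
        fc_residual=fc_matrix(residual),
        ec_sc_corr_by_order=by_order,
    )


def pareto_sweep(
    train_ts: RoiTimeseries,
    heldout_ts: RoiTimeseries,
    sc: StructuralConnectivity,
    lambda_grid: np.ndarray,
    threshold_grid: np.ndarray,
    order: int = 1,
    ridge_alpha: float = 1e-2,
    derivative_method: str = "forward",
    r2_rule: float = 0.1,
    sc_rule: float = 0.4,
) -> pd.DataFrame:
    """Fit one model per (lambda, threshold) grid point.

    Each row carries the training adjusted R-squared, the first-order
    coefficient/SC correlation, the nonzero fraction, and whether the row
    meets the operating rule (adjusted R^2 above ``r2_rule`` and SC
    correlation above ``sc_rule``).
    """
    lambda_grid = np.atleast_1d(lambda_grid)
    threshold_grid = np.atleast_1d(threshold_grid)
    if lambda_grid.size == 0 or threshold_grid.size == 0:
        raise ValidationError("sweep grids must be non-empty")
    lib = build_library(train_ts, order)
    deriv = estimate_derivative(train_ts, derivative_method)
    rows = []
    for lam in lambda_grid:
        for thr in threshold_grid:
            ec, report = fit_constrained_ridge(
                lib, deriv, lambda_diag=float(lam), ridge_alpha=ridge_alpha, threshold=float(thr)
            )
            try:
                sc_corr = ec_sc_correlation(ec, sc, order=1, edge_cls="all")
            except ValidationError:
                sc_corr = float("nan")
            heldout_r = derivative_prediction_correlation(ec, heldout_ts, derivative_method)
            rows.append(
                {
                    "lambda": float(lam),
                    "threshold": float(thr),
                    "adjusted_r2": report.adjusted_r2,
                    "sc_corr": sc_corr,
                    "nonzero_fraction": report.nonzero_fraction,
                    "heldout_median_r": float(np.nanmedian(heldout_r)),
                    "meets_rule": bool(report.adjusted_r2 > r2_rule and sc_corr > sc_rule),
                }
            )
    return pd.DataFrame(rows)


def jacobian_eigenmodes(ec: EffectiveConnectivity) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the first-order coefficients, by real part desc."""
    vals, vecs = np.linalg.eig(ec.order1())
    order = np.argsort(-vals.real)
    return vals[order], vecs[:, order]
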