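"""Network-ODE identification from ROI timeseries.

The derivative of each region is modelled as a sum of per-edge Taylor
polynomials plus a fixed linear decay:

    dX_a/dt = lambda * X_a + sum_b sum_{k=1..p} Xi[a,b,k] * X_b^k

The coefficients Xi are found by ridge regression of the estimated
derivative on a polynomial library with no interaction terms, with
sequential thresholding (STLSQ) for sparsity.  The first-order diagonal
coefficient is not estimated: it is fixed to the decay constant
``lambda_diag``, which is subtracted from the regression target before the
solve and reinstated afterwards.  Higher-order diagonal terms stay free, so
self-edges can still be sigmoidal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import ConfigurationError, NumericalError, SchemaError, ValidationError
from .io import DerivativeMatrix, RoiTimeseries, edge_class

logger = logging.getLogger(__name__)

MAX_ORDER = 7


@dataclass
class LibraryMatrix:
    """Monomial library Theta(X): columns [x_1..x_n, x_1^2..x_n^2, ...]."""

    values: np.ndarray            # (n_samples, n_roi * order)
    order: int
    n_roi: int
    roi_labels: list[str]
    hemisphere: list[str]
    source_run: str = ""

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class FitReport:
    """Training residuals and fit summary of an identification."""

    residuals: DerivativeMatrix
    adjusted_r2: float
    nonzero_fraction: float


@dataclass
class EffectiveConnectivity:
    """Per-edge polynomial coefficients with a fixed diagonal decay.

    ``coeffs[a, b, k]`` is the coefficient of ``X_b^(k+1)`` in the equation
    of region ``a`` (k is 0-based, so k=0 is the linear order).
    """

    coeffs: np.ndarray            # (n_roi, n_roi, order)
    lambda_diag: float
    order: int
    sparsity_mask: np.ndarray     # bool, same shape
    roi_labels: list[str]
    hemisphere: list[str]
    training_meta: dict = field(default_factory=dict)

    @property
    def n_roi(self) -> int:
        return self.coeffs.shape[0]

    def order1(self) -> np.ndarray:
        """First-order coefficient matrix (the Jacobian at the origin)."""
        return self.coeffs[:, :, 0]

    def combine(self, other: "EffectiveConnectivity", c_self: float, c_other: float) -> "EffectiveConnectivity":
        """Linear combination c_self*this + c_other*other (same ROI set/order)."""
        if other.n_roi != self.n_roi or other.order != self.order:
            raise SchemaError("effective connectivities differ in ROI count or order")
        coeffs = c_self * self.coeffs + c_other * other.coeffs
        return EffectiveConnectivity(
            coeffs=coeffs,
            lambda_diag=c_self * self.lambda_diag + c_other * other.lambda_diag,
            order=self.order,
            sparsity_mask=coeffs != 0,
            roi_labels=self.roi_labels,
            hemisphere=self.hemisphere,
            training_meta={"combined": True},
        )

    def as_design_matrix(self) -> np.ndarray:
        """Coefficients flattened to match the library column order."""
        n, p = self.n_roi, self.order
        return np.concatenate([self.coeffs[:, :, k] for k in range(p)], axis=1)  # (n, n*p)


def build_library(ts: RoiTimeseries, order: int) -> LibraryMatrix:
    """Evaluate the monomial library for every sample of a timeseries."""
    if not 1 <= order <= MAX_ORDER:
        raise ConfigurationError(f"polynomial order must lie in [1, {MAX_ORDER}], got {order}")
    x = ts.values.T  # (n_samples, n_roi)
    cols = [x ** k for k in range(1, order + 1)]
    return LibraryMatrix(
        values=np.concatenate(cols, axis=1),
        order=order,
        n_roi=ts.n_roi,
        roi_labels=list(ts.roi_labels),
        hemisphere=list(ts.hemisphere),
        source_run=ts.run_id,
    )


def _ridge_solve(design: np.ndarray, target: np.ndarray, alpha: float) -> np.ndarray:
    gram = design.T @ design
    if alpha > 0:
        gram = gram + alpha * np.eye(gram.shape[0])
    try:
        sol = np.linalg.solve(gram, design.T @ target)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular design matrix; increase ridge_alpha above 0 or add data"
        ) from exc
    if alpha == 0 and not np.all(np.isfinite(sol)):
        raise NumericalError("ill-conditioned solve; increase ridge_alpha above 0")
    return sol


def fit_constrained_ridge(
    library: LibraryMatrix,
    deriv: DerivativeMatrix,
    lambda_diag: float = -0.22,
    ridge_alpha: float = 1e-2,
    threshold: float = 1e-3,
    n_iter: int = 10,
) -> tuple[EffectiveConnectivity, FitReport]:
    """Identify the network ODE by per-region constrained ridge + STLSQ.

    For each target region ``a`` the fixed decay contribution
    ``lambda_diag * x_a`` is subtracted from its derivative, the first-order
    diagonal column is removed from the design, the remaining coefficients
    are solved by ridge regression, and ``n_iter`` rounds of sequential
    thresholding zero every coefficient below ``threshold`` and re-solve
    over the survivors.  The diagonal decay is reinstated afterwards.
    """
    if lambda_diag >= 0:
        raise ConfigurationError("lambda_diag must be negative")
    if ridge_alpha < 0 or threshold < 0:
        raise ConfigurationError("ridge_alpha and threshold must be nonnegative")
    theta = library.values
    n_samp, n_cols = theta.shape
    n, p = library.n_roi, library.order
    d = deriv.values
    if d.shape != (n, n_samp):
        raise SchemaError(
            f"derivative shape {d.shape} does not match library ({n} ROIs x {n_samp} samples)"
        )

    coeffs = np.zeros((n, n, p))
    mask = np.zeros((n, n, p), dtype=bool)
    residuals = np.empty_like(d)

    for a in range(n):
        y = d[a] - lambda_diag * theta[:, a]
        free = np.ones(n_cols, dtype=bool)
        free[a] = False  # first-order diagonal column is constrained
        active = free.copy()
        beta = np.zeros(n_cols)
        for _ in range(max(1, n_iter)):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            sol = _ridge_solve(theta[:, idx], y, ridge_alpha)
            beta[:] = 0.0
            beta[idx] = sol
            new_active = active & (np.abs(beta) >= threshold)
            if new_active.sum() == active.sum():
                active = new_active
                break
            active = new_active
        if active.sum() == 0:
            logger.warning("region %d: thresholding removed every term; decay-only model", a)
            beta[:] = 0.0
        else:
            beta[~active] = 0.0
        for k in range(p):
            coeffs[a, :, k] = beta[k * n : (k + 1) * n]
            mask[a, :, k] = active[k * n : (k + 1) * n]
        residuals[a] = (theta @ beta + lambda_diag * theta[:, a]) - d[a]
        coeffs[a, a, 0] = lambda_diag
        mask[a, a, 0] = True

    # adjusted R^2 over the pooled training residuals
    centered = d - d.mean(axis=1, keepdims=True)
    sst = float(np.sum(centered ** 2))
    ssr = float(np.sum(residuals ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    n_obs = d.size
    k_params = int(mask.sum())
    adj = 1.0 - (1.0 - r2) * (n_obs - 1) / max(n_obs - k_params - 1, 1)

    off_mask = mask.copy()
    for a in range(n):
        off_mask[a, a, 0] = False  # fixed term does not count as a discovered edge
    nonzero_fraction = float(off_mask.sum()) / float(n * n * p - n)

    data_hash = hashlib.sha256(theta.tobytes() + d.tobytes()).hexdigest()[:16]
    ec = EffectiveConnectivity(
        coeffs=coeffs,
        lambda_diag=lambda_diag,
        order=p,
        sparsity_mask=mask,
        roi_labels=library.roi_labels,
        hemisphere=library.hemisphere,
        training_meta={
            "ridge_alpha": ridge_alpha,
            "threshold": threshold,
            "n_iter": n_iter,
            "derivative_method": deriv.method,
            "data_hash": data_hash,
        },
    )
    report = FitReport(
        residuals=DerivativeMatrix(values=residuals, method=deriv.method, source_run=library.source_run),
        adjusted_r2=float(adj),
        nonzero_fraction=nonzero_fraction,
    )
    return ec, report


def predict_derivative(ec: EffectiveConnectivity, ts: RoiTimeseries) -> DerivativeMatrix:
    """Evaluate Theta(X) * Xi (including the decay term) on a timeseries."""
    if ts.n_roi != ec.n_roi:
        raise SchemaError(f"timeseries has {ts.n_roi} ROIs, model expects {ec.n_roi}")
    lib = build_library(ts, ec.order)
    pred = ec.as_design_matrix() @ lib.values.T
    return DerivativeMatrix(values=pred, method="model", source_run=ts.run_id)


def predict_derivative_states(ec: EffectiveConnectivity, states: np.ndarray) -> np.ndarray:
    """Same as :func:`predict_derivative` for a raw (n_roi, n_samples) array."""
    x = np.asarray(states, dtype=float)
    theta = np.concatenate([x ** k for k in range(1, ec.order + 1)], axis=0)  # (n*p, T)
    return ec.as_design_matrix() @ theta


def edge_function(ec: EffectiveConnectivity, a: int, b: int, x_grid: np.ndarray) -> tuple[np.ndarray, str]:
    """Evaluate the edge polynomial E_ab on a grid; also return the edge class."""
    n = ec.n_roi
    if not (0 <= a < n and 0 <= b < n):
        raise IndexError(f"edge indices ({a}, {b}) out of range for {n} ROIs")
    x = np.asarray(x_grid, dtype=float)
    curve = np.zeros_like(x)
    for k in range(ec.order - 1, -1, -1):  # Horner on x * P(x)
        curve = curve * x + ec.coeffs[a, b, k]
    curve = curve * x
    return curve, edge_class(a, b, ec.roi_labels, ec.hemisphere)


def save_ec(ec: EffectiveConnectivity, path: str | Path) -> None:
    """Persist as <path>.h5 (coeffs + mask) and <path>.json (metadata)."""
    path = Path(path)
    with h5py.File(path.with_suffix(".h5"), "w") as fh:
        fh.create_dataset("coeffs", data=ec.coeffs, track_times=False)
        fh.create_dataset("sparsity_mask", data=ec.sparsity_mask, track_times=False)
    meta = {
        "lambda_diag": ec.lambda_diag,
        "order": ec.order,
        "roi_labels": ec.roi_labels,
        "hemisphere": ec.hemisphere,
        "training_meta": ec.training_meta,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_ec(path: str | Path) -> EffectiveConnectivity:
    path = Path(path)
    with h5py.File(path.with_suffix(".h5"), "r") as fh:
        coeffs = fh["coeffs"][()]
        mask = fh["sparsity_mask"][()].astype(bool)
    meta = json.loads(path.with_suffix(".json").read_text())
    return EffectiveConnectivity(
        coeffs=coeffs,
        lambda_diag=float(meta["lambda_diag"]),
        order=int(meta["order"]),
        sparsity_mask=mask,
        roi_labels=list(meta["roi_labels"]),
        hemisphere=list(meta["hemisphere"]),
        training_meta=dict(meta["training_meta"]),
    )
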