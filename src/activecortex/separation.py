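"""Trial-window extraction and rest/task signal separation.

For every completed trial the 14.4 s (20 samples) following stimulus onset
are resampled onto a common grid.  A candidate stimulus-independent
background derivative is then formed from a linear combination of the rest
and task network models,

    background(t) = (c1 * Xi_rest + c2 * Xi_task) . Theta(X_unsep(t)),

evaluated on the measured window states, subtracted from the measured
derivative, and re-integrated from the onset value.  Named coefficient
choices: rest baseline (1, 0), task baseline (0, 1), Active Cortex Model
(1, -1), unseparated (0, 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import SchemaError, StatisticalValidityError, ValidationError
from .io import DerivativeMatrix, RoiTimeseries, TrialTable
from .sysid import EffectiveConnectivity, predict_derivative_states

logger = logging.getLogger(__name__)

WINDOW_SECONDS = 14.4
WINDOW_SAMPLES = 20

FRAMEWORKS = {
    "unseparated": (0.0, 0.0),
    "rest_baseline": (1.0, 0.0),
    "task_baseline": (0.0, 1.0),
    "acm": (1.0, -1.0),
}


@dataclass
class SeparationSpec:
    """(c1, c2) coefficients of a separation framework."""

    c1: float
    c2: float
    name: str = "custom"

    @classmethod
    def named(cls, name: str) -> "SeparationSpec":
        if name not in FRAMEWORKS:
            raise ValidationError(f"unknown framework {name!r}; choose from {sorted(FRAMEWORKS)}")
        c1, c2 = FRAMEWORKS[name]
        return cls(c1=c1, c2=c2, name=name)


@dataclass
class TrialWindowSet:
    """Onset-aligned signal and derivative windows (n_trials x n_roi x 20)."""

    signal: np.ndarray
    derivative: np.ndarray
    trial_index: np.ndarray       # indices into the source TrialTable
    roi_labels: list[str]
    hemisphere: list[str]
    window_seconds: float = WINDOW_SECONDS
    n_samples: int = WINDOW_SAMPLES

    @property
    def n_trials(self) -> int:
        return self.signal.shape[0]

    @property
    def n_roi(self) -> int:
        return self.signal.shape[1]


def extract_trial_windows(ts: RoiTimeseries, deriv: DerivativeMatrix, trials: TrialTable) -> TrialWindowSet:
    """Resample each completed trial onto 20 samples spanning [onset, onset+14.4 s).

    Resampling is linear interpolation on the run's native time grid; when
    onsets fall on TR multiples (TR = 0.72 s) it is the identity.  Trials
    whose window would extend past the end of the run are dropped (counted
    in the log).
    """
    if deriv.values.shape != ts.values.shape:
        raise SchemaError("timeseries and derivative are not aligned")
    dt = WINDOW_SECONDS / WINDOW_SAMPLES
    offsets = dt * np.arange(WINDOW_SAMPLES)
    run_end = (ts.n_samples - 1) * ts.tr_seconds
    native_t = ts.tr_seconds * np.arange(ts.n_samples)

    sigs, ders, kept = [], [], []
    n_dropped = 0
    for i, row in trials.df.iterrows():
        if not row["completed"]:
            continue
        times = row["onset_seconds"] + offsets
        if times[-1] > run_end:
            n_dropped += 1
            continue
        sigs.append(np.stack([np.interp(times, native_t, ts.values[r]) for r in range(ts.n_roi)]))
        ders.append(np.stack([np.interp(times, native_t, deriv.values[r]) for r in range(ts.n_roi)]))
        kept.append(i)
    if n_dropped:
        logger.info("dropped %d trial(s) whose window exceeded the run", n_dropped)
    if not kept:
        raise ValidationError("no completed trials fall inside the run")
    return TrialWindowSet(
        signal=np.stack(sigs),
        derivative=np.stack(ders),
        trial_index=np.asarray(kept),
        roi_labels=list(ts.roi_labels),
        hemisphere=list(ts.hemisphere),
    )


def separate_window(
    win: TrialWindowSet,
    ec_rest: EffectiveConnectivity,
    ec_task: EffectiveConnectivity,
    spec: SeparationSpec,
) -> TrialWindowSet:
    """Subtract the (c1, c2) background and re-integrate from the onset value.

    Integration is a left-rectangle (Euler) cumulative sum with a step of
    one sample, matching the discrete-time model convention; sample 0 of the
    separated signal equals the measured onset value.
    """
    if ec_rest.n_roi != win.n_roi or ec_task.n_roi != win.n_roi:
        raise SchemaError("effective connectivity ROI set does not match the windows")
    combined = ec_rest.combine(ec_task, spec.c1, spec.c2)
    design = combined.as_design_matrix()
    n_tr, n_roi, n_t = win.signal.shape

    sep_deriv = np.empty_like(win.derivative)
    sep_signal = np.empty_like(win.signal)
    for i in range(n_tr):
        states = win.signal[i]
        theta = np.concatenate([states ** k for k in range(1, combined.order + 1)], axis=0)
        background = design @ theta
        ds = win.derivative[i] - background
        sep_deriv[i] = ds
        cumulative = np.cumsum(ds, axis=1)
        sep_signal[i, :, 0] = states[:, 0]
        sep_signal[i, :, 1:] = states[:, :1] + cumulative[:, :-1]
    return TrialWindowSet(
        signal=sep_signal,
        derivative=sep_deriv,
        trial_index=win.trial_index.copy(),
        roi_labels=win.roi_labels,
        hemisphere=win.hemisphere,
        window_seconds=win.window_seconds,
        n_samples=win.n_samples,
    )


def _max_abs_corr_with_rt(signal: np.ndarray, rt: np.ndarray) -> float:
    """Largest |Pearson r| between RT and any (region, time) point."""
    rt_c = rt - rt.mean()
    centered = signal - signal.mean(axis=0)
    num = np.einsum("ijk,i->jk", centered, rt_c)
    den = np.sqrt((centered ** 2).sum(axis=0) * (rt_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / den
    return float(np.nanmax(np.abs(corr)))


def sweep_c1_c2(
    win: TrialWindowSet,
    ec_rest: EffectiveConnectivity,
    ec_task: EffectiveConnectivity,
    rt: np.ndarray,
    c1_grid: np.ndarray | None = None,
    c2_grid: np.ndarray | None = None,
) -> "pd.DataFrame":
    """Delta max |RT correlation| over a grid of (c1, c2) combinations.

    For every grid cell the windows are separated, the maximum absolute
    spatiotemporal correlation with reaction time is computed, and the
    unseparated maximum is subtracted.  The default grids span c1 in [-1, 3]
    and c2 in [-3, 1] in steps of 0.5.
    """
    import pandas as pd

    rt = np.asarray(rt, dtype=float)
    if len(rt) != win.n_trials:
        raise SchemaError("rt vector not aligned with windows")
    if win.n_trials < 10:
        raise StatisticalValidityError("need at least 10 valid trials for the sweep")
    if c1_grid is None:
        c1_grid = np.linspace(-1.0, 3.0, 9)
    if c2_grid is None:
        c2_grid = np.linspace(-3.0, 1.0, 9)

    base = _max_abs_corr_with_rt(
        separate_window(win, ec_rest, ec_task, SeparationSpec(0.0, 0.0, "unseparated")).signal, rt
    )
    rows = []
    for c1 in c1_grid:
        for c2 in c2_grid:
            sep = separate_window(win, ec_rest, ec_task, SeparationSpec(float(c1), float(c2)))
            mc = _max_abs_corr_with_rt(sep.signal, rt)
            rows.append({"c1": float(c1), "c2": float(c2), "max_corr": mc, "delta_max_corr": mc - base})
    return pd.DataFrame(rows)
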