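"""Ground-truth network ODEs and synthetic Rest/Task fMRI runs.

The generator stands in for restricted human recordings so that every stage
of the analysis can be validated by parameter recovery.  It emulates the
statistical structure the identification assumes:

* sigmoidal (tanh) coupling between regions with intrahemispheric and
  contralateral-homologue edges positive and the remaining interhemispheric
  edges negative;
* a linear decay to baseline at rate ``lambda_decay`` per sample;
* a stable linearization (all eigenvalue real parts negative) so rest runs
  are stationary;
* task runs in which a sub-network of the rest edges is engaged (elevated by
  ``task_elevation``) while the remaining rest processes lose structure
  (attenuated by ``offtask_attenuation``), so a model fitted on task data is
  a sub-network of the rest model;
* trials that inject a brief triangular input into designated stimulus
  regions, with reaction time affinely (and noisily) linked to the per-trial
  input amplitude.

Simulated time is measured in samples (one sample = one TR of 0.72 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import RoiTimeseries, StructuralConnectivity, TrialTable

logger = logging.getLogger(__name__)

TR_SECONDS = 0.72

#: canonical brief input: rises to the peak over 3 samples, falls over 3.
TRIANGLE = np.array([1 / 3, 2 / 3, 1.0, 2 / 3, 1 / 3])

#: default trial counts per task, matching the HCP task designs.
TASK_TRIAL_COUNTS = {"WM": 80, "GB": 32, "REL": 27, "EM": 30}
TASK_SUBTASKS = {
    "WM": ["Place0b", "Tools0b", "Faces0b", "Body0b", "Place2b", "Tools2b", "Faces2b", "Body2b"],
    "GB": ["Reward", "Punish"],
    "REL": ["Shape", "Texture"],
    "EM": ["Fear", "Neutral"],
}


@dataclass
class GroundTruthModel:
    """A generative network ODE with Rest/Task sub-network structure.

    ``edge_weight`` uses the target-row convention: entry ``[a, b]`` scales
    the influence of region ``b`` on region ``a``.  The decay sits in
    ``lambda_decay`` (per sample); the weight diagonal is zero.
    """

    n_roi: int
    edge_weight: np.ndarray
    edge_gain: float
    lambda_decay: float
    rest_mask: np.ndarray
    task_mask: np.ndarray
    task_elevation: float
    offtask_attenuation: float
    stimulus_rois: tuple[int, ...]
    stimulus_amp_mean: float
    stimulus_amp_sd: float
    rt_intercept_ms: float
    rt_slope_ms: float
    stimulus_gain_coupling: float
    noise_sd: float
    seed: int
    roi_labels: list[str] = field(default_factory=list)
    hemisphere: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edge_weight = np.asarray(self.edge_weight, dtype=float)
        if np.any(np.diag(self.edge_weight) != 0):
            raise ValidationError("edge_weight diagonal must be zero (decay is lambda_decay)")
        if self.lambda_decay >= 0:
            raise ConfigurationError("lambda_decay must be negative")
        if np.any(self.task_mask & ~self.rest_mask):
            raise ValidationError("task_mask must be a subset of rest_mask")
        if self.rt_slope_ms >= 0:
            raise ConfigurationError("rt_slope_ms must be negative (faster responses to stronger input)")

    def linearization(self, condition: str = "rest") -> np.ndarray:
        """Jacobian at the origin: lambda*I + gain * (condition-effective weights)."""
        return self.lambda_decay * np.eye(self.n_roi) + self.edge_gain * self.effective_weights(condition)

    def effective_weights(self, condition: str) -> np.ndarray:
        w = self.edge_weight.copy()
        if condition.startswith("task"):
            w[self.rest_mask & ~self.task_mask] *= self.offtask_attenuation
            w[self.task_mask] *= self.task_elevation
        return w


def _default_labels(n_roi: int) -> tuple[list[str], list[str]]:
    half = n_roi // 2
    labels = [f"roi{i:02d}_L" for i in range(half)] + [f"roi{i:02d}_R" for i in range(half)]
    hemis = ["left"] * half + ["right"] * half
    return labels, hemis


def make_ground_truth(
    n_roi: int = 16,
    intra_density: float = 0.4,
    seed: int = 0,
    *,
    inter_density: float = 0.3,
    inter_scale: float = 0.5,
    weight_sigma: float = 0.5,
    lambda_decay: float = -0.22,
    edge_gain: float = 1.0,
    stability_margin: float = 0.05,
    task_rois: tuple[int, ...] | None = None,
    task_elevation: float = 1.25,
    offtask_attenuation: float = 0.5,
    stimulus_rois: tuple[int, ...] | None = None,
    stimulus_amp_mean: float = 0.3,
    stimulus_amp_sd: float = 0.1,
    rt_intercept_ms: float = 1000.0,
    rt_slope_ms: float = -500.0,
    stimulus_gain_coupling: float = 1.0,
    noise_sd: float = 0.1,
) -> GroundTruthModel:
    """Sample a stable two-hemisphere ground-truth network.

    Intrahemispheric edges are positive (lognormal magnitudes, present with
    probability ``intra_density``); every contralateral homologue pair is
    positive; remaining interhemispheric edges are negative (present with
    probability ``inter_density``, scaled by ``inter_scale``).  Weights are
    rescaled so the largest real part of the rest-condition linearization
    equals ``-stability_margin`` per sample, keeping simulated runs
    stationary but slow, as in resting fMRI.

    The task sub-network spans ``task_rois`` (default: the first half of
    each hemisphere); ``stimulus_rois`` default to the two leading homologue
    pairs of that sub-network.
    """
    if n_roi % 2:
        raise ConfigurationError("n_roi must be even (two hemispheres)")
    if not 0 < intra_density <= 1:
        raise ConfigurationError("intra_density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    half = n_roi // 2
    labels, hemis = _default_labels(n_roi)

    w = np.zeros((n_roi, n_roi))
    for a in range(n_roi):
        for b in range(n_roi):
            if a == b:
                continue
            same_hemi = (a < half) == (b < half)
            if same_hemi:
                if rng.random() < intra_density:
                    w[a, b] = rng.lognormal(0.0, weight_sigma)
            elif abs(a - b) == half:
                w[a, b] = rng.lognormal(0.0, weight_sigma)
            elif rng.random() < inter_density:
                w[a, b] = -inter_scale * rng.lognormal(0.0, weight_sigma)

    # scale weights so the rest linearization sits stability_margin inside
    # the stable half-plane (bisection on the spectral abscissa)
    eye = np.eye(n_roi)

    def max_real(scale: float) -> float:
        return float(np.max(np.real(np.linalg.eigvals(lambda_decay * eye + edge_gain * scale * w))))

    lo, hi = 0.0, 1.0
    while max_real(hi) < -stability_margin:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if max_real(mid) < -stability_margin:
            lo = mid
        else:
            hi = mid
    w *= lo

    if task_rois is None:
        quarter = half // 2
        task_rois = tuple(range(quarter)) + tuple(range(half, half + quarter))
    in_task = np.zeros(n_roi, dtype=bool)
    in_task[list(task_rois)] = True
    rest_mask = w != 0
    task_mask = rest_mask & np.outer(in_task, in_task)
    if stimulus_rois is None:
        left = sorted(r for r in task_rois if r < half)[:2]
        stimulus_rois = tuple(left) + tuple(r + half for r in left)

    return GroundTruthModel(
        n_roi=n_roi,
        edge_weight=w,
        edge_gain=edge_gain,
        lambda_decay=lambda_decay,
        rest_mask=rest_mask,
        task_mask=task_mask,
        task_elevation=task_elevation,
        offtask_attenuation=offtask_attenuation,
        stimulus_rois=tuple(stimulus_rois),
        stimulus_amp_mean=stimulus_amp_mean,
        stimulus_amp_sd=stimulus_amp_sd,
        rt_intercept_ms=rt_intercept_ms,
        rt_slope_ms=rt_slope_ms,
        stimulus_gain_coupling=stimulus_gain_coupling,
        noise_sd=noise_sd,
        seed=seed,
        roi_labels=labels,
        hemisphere=hemis,
    )


def jitter_individual(model: GroundTruthModel, sd: float, seed: int) -> GroundTruthModel:
    """Per-individual connectivity: multiply weights by lognormal(0, sd) noise."""
    rng = np.random.default_rng(seed)
    w = model.edge_weight * rng.lognormal(0.0, sd, model.edge_weight.shape)
    return replace(model, edge_weight=w)


def make_trial_schedule(
    task_name: str,
    n_trials: int | None = None,
    spacing_s: float = 21.6,
    subtask_labels: list[str] | None = None,
    seed: int = 0,
    start_s: float = 36.0,
) -> TrialTable:
    """Build an evenly spaced trial schedule with shuffled sub-task labels."""
    if n_trials is None:
        n_trials = TASK_TRIAL_COUNTS.get(task_name)
        if n_trials is None:
            raise ConfigurationError(f"no default trial count for task {task_name!r}; pass n_trials")
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    if subtask_labels is None:
        subtask_labels = TASK_SUBTASKS.get(task_name, [task_name])
    if not subtask_labels:
        raise ConfigurationError("subtask label set must be non-empty")
    rng = np.random.default_rng(seed)
    labels = [subtask_labels[i % len(subtask_labels)] for i in range(n_trials)]
    rng.shuffle(labels)
    df = pd.DataFrame(
        {
            "onset_seconds": start_s + spacing_s * np.arange(n_trials),
            "duration_seconds": np.full(n_trials, 2.0),
            "subtask": labels,
            "rt_ms": np.full(n_trials, np.nan),
            "correct": np.ones(n_trials, dtype=bool),
            "completed": np.ones(n_trials, dtype=bool),
        }
    )
    return TrialTable(df)


def simulate_run(
    model: GroundTruthModel,
    n_samples: int,
    schedule: TrialTable | None = None,
    seed: int = 0,
    *,
    task_name: str = "synthetic",
    tr_seconds: float = TR_SECONDS,
    initial_state: np.ndarray | None = None,
) -> tuple[RoiTimeseries, TrialTable | None]:
    """Euler-Maruyama integration of the network ODE, one step per sample.

    ``dX_a = lambda*X_a + sum_b w_ab tanh(gain*X_b) + stimulus_a(t) + noise``

    When ``schedule`` is given the run is a task run: task-mask edges are
    multiplied by ``task_elevation``, the remaining rest edges by
    ``offtask_attenuation``, and each trial injects a triangular input
    (peak = per-trial amplitude drawn from the model's amplitude
    distribution) into the stimulus regions.  The realized amplitudes are
    returned inside the TrialTable so recovery tests have an oracle.

    The stimulus also couples with the engaged sub-network: during each
    trial the task-edge flows are multiplied by
    ``1 + stimulus_gain_coupling * amplitude * triangle(t)``, so part of the
    trial response is carried by the network processes themselves rather
    than by the additive input alone.
    """
    if n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    # independent child streams so a task run with zero stimulus and unit
    # elevation/attenuation is bitwise-identical to the rest run
    rng_noise, rng_amp = (np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(2))
    n = model.n_roi
    condition = "rest" if schedule is None else f"task:{task_name}"
    weights = model.effective_weights(condition)

    stim = np.zeros((n, n_samples))
    gain_profile = np.zeros(n_samples)  # per-trial elevation of task-edge flows
    out_schedule: TrialTable | None = None
    if schedule is not None:
        onsets = np.round(schedule.onsets / tr_seconds).astype(int)
        if onsets[-1] + len(TRIANGLE) + 1 > n_samples:
            raise ValidationError(
                f"schedule overruns the run: last onset sample {onsets[-1]} "
                f"+ input length {len(TRIANGLE)} > n_samples {n_samples}"
            )
        floor = min(0.02, model.stimulus_amp_mean)  # no floor for zero-stimulus runs
        amps = np.maximum(
            rng_amp.normal(model.stimulus_amp_mean, model.stimulus_amp_sd, len(onsets)), floor
        )
        rois = list(model.stimulus_rois)
        for onset, amp in zip(onsets, amps):
            stim[rois, onset : onset + len(TRIANGLE)] += amp * TRIANGLE
            gain_profile[onset : onset + len(TRIANGLE)] += model.stimulus_gain_coupling * amp * TRIANGLE
        df = schedule.df.copy()
        df["amplitude"] = amps
        out_schedule = TrialTable(df)

    task_flow = weights * model.task_mask
    other_flow = weights - task_flow
    x = np.zeros((n, n_samples))
    if initial_state is not None:
        x[:, 0] = initial_state
    noise = (
        rng_noise.normal(0.0, model.noise_sd, (n, n_samples))
        if model.noise_sd > 0
        else np.zeros((n, n_samples))
    )
    lam, gain = model.lambda_decay, model.edge_gain
    for t in range(n_samples - 1):
        sig = np.tanh(gain * x[:, t])
        flows = other_flow @ sig + (1.0 + gain_profile[t]) * (task_flow @ sig)
        dx = lam * x[:, t] + flows + stim[:, t] + noise[:, t]
        x[:, t + 1] = x[:, t] + dx

    ts = RoiTimeseries(
        values=x,
        tr_seconds=tr_seconds,
        roi_labels=model.roi_labels,
        hemisphere=model.hemisphere,
        condition=condition,
        run_id=f"{condition}-seed{seed}",
    )
    return ts, out_schedule


def generate_rt(
    model: GroundTruthModel,
    trial_amplitudes: np.ndarray,
    rt_noise_sd: float = 40.0,
    seed: int = 0,
) -> np.ndarray:
    """Reaction times affinely linked to stimulus amplitude, floored at 100 ms."""
    amps = np.asarray(trial_amplitudes, dtype=float)
    if np.any(amps <= 0):
        raise ValidationError("trial amplitudes must be positive")
    rng = np.random.default_rng(seed)
    rt = model.rt_intercept_ms + model.rt_slope_ms * amps
    if rt_noise_sd > 0:
        rt = rt + rng.normal(0.0, rt_noise_sd, amps.shape)
    return np.maximum(rt, 100.0)


def derive_sc(model: GroundTruthModel, distortion_sd: float = 0.0, seed: int = 0,
              count_scale: float = 1000.0) -> StructuralConnectivity:
    """Tractography-like counts: proportional to |w| on positive edges only.

    Tractography sees no sign, and the negative interhemispheric couplings of
    the generative model have no white-matter analogue here, so those entries
    map to zero.  Counts carry multiplicative lognormal distortion.
    """
    if distortion_sd < 0:
        raise ConfigurationError("distortion_sd must be >= 0")
    rng = np.random.default_rng(seed)
    counts = np.where(model.edge_weight > 0, np.abs(model.edge_weight) * count_scale, 0.0)
    if distortion_sd > 0:
        counts *= rng.lognormal(0.0, distortion_sd, counts.shape)
    np.fill_diagonal(counts, 0.0)
    return StructuralConnectivity(counts=counts, roi_labels=list(model.roi_labels))


def two_task_models(
    seed: int = 0,
    n_roi: int = 16,
    *,
    task_elevation: float = 1.15,
    offtask_attenuation: float = 0.85,
) -> tuple[GroundTruthModel, GroundTruthModel]:
    """Two overlapping task variants of one rest network (multi-task study).

    The two tasks engage sub-networks sharing 6 of 8 regions, with distinct
    stimulus sites, and a deliberately weak condition contrast — individual
    task recordings are confusable before separation, as in real multi-task
    fMRI.
    """
    half = n_roi // 2
    quarter = half // 2
    rois_a = tuple(range(quarter)) + tuple(range(half, half + quarter))
    rois_b = tuple(range(1, quarter + 1)) + tuple(range(half + 1, half + quarter + 1))
    base = make_ground_truth(
        n_roi=n_roi,
        seed=seed,
        task_rois=rois_a,
        task_elevation=task_elevation,
        offtask_attenuation=offtask_attenuation,
        stimulus_rois=(0, half),
    )
    in_b = np.zeros(n_roi, dtype=bool)
    in_b[list(rois_b)] = True
    model_b = replace(
        base,
        task_mask=base.rest_mask & np.outer(in_b, in_b),
        stimulus_rois=(quarter, half + quarter),
    )
    return base, model_b
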