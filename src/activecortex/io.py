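"""Domain containers, readers/writers and signal preprocessing.

The package works on region-of-interest (ROI) fMRI matrices: one row per
brain region, one column per repetition time (TR).  Timeseries travel as a
tab-separated matrix plus a JSON sidecar carrying the sampling metadata;
trial/event tables use the BIDS ``events.tsv`` convention.

All model fitting downstream works in units of *samples* (one sample = one
TR), so derivatives produced here are expressed in signal units per sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.signal.windows import tukey

from .errors import ConfigurationError, ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

HEMISPHERES = ("left", "right", "midline")


@dataclass
class RoiTimeseries:
    """ROI x time signal matrix with sampling metadata.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_roi, n_samples)``.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    roi_labels
        One label per ROI.  Homologous regions in opposite hemispheres share
        the same base name (label minus a trailing ``_L``/``_R``).
    hemisphere
        Per-ROI tag, one of ``left``/``right``/``midline``.
    condition
        ``"rest"`` or ``"task:<name>"``.
    run_id
        Free-form identifier of the recording.
    """

    values: np.ndarray
    tr_seconds: float
    roi_labels: list[str]
    hemisphere: list[str]
    condition: str = "rest"
    run_id: str = "run-0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("timeseries values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("timeseries contains non-finite values")
        if self.values.shape[1] < 2:
            raise ValidationError("a timeseries needs at least 2 samples")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        n = self.values.shape[0]
        if len(self.roi_labels) != n or len(self.hemisphere) != n:
            raise SchemaError(
                f"matrix has {n} ROI rows but sidecar lists "
                f"{len(self.roi_labels)} labels / {len(self.hemisphere)} hemisphere tags"
            )
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise SchemaError(f"unknown hemisphere tags: {sorted(bad)}")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DerivativeMatrix:
    """Per-sample derivative of a :class:`RoiTimeseries` (units/sample)."""

    values: np.ndarray
    method: str
    source_run: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("derivative contains non-finite values")


@dataclass
class StructuralConnectivity:
    """Nonnegative tract-count matrix with a zero diagonal."""

    counts: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise SchemaError("SC counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValidationError("SC counts must be nonnegative")
        if np.any(np.diag(self.counts) != 0):
            raise ValidationError("SC diagonal must be zero")
        if len(self.roi_labels) != self.counts.shape[0]:
            raise SchemaError("SC label count does not match matrix size")


# BIDS events columns written/read by trial tables.
_EVENT_COLUMNS = ["onset", "duration", "trial_type", "response_time", "correct", "completed"]


@dataclass
class TrialTable:
    """Trial/event metadata: onsets, sub-task labels, reaction times.

    Backed by a DataFrame with columns ``onset_seconds``, ``duration_seconds``,
    ``subtask``, ``rt_ms`` (NaN when missing), ``correct``, ``completed`` and,
    for synthetic runs, ``amplitude`` (the realized per-trial stimulus
    amplitude, kept for parameter-recovery oracles).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        onsets = df["onset_seconds"].to_numpy(float)
        if np.any(np.diff(onsets) <= 0):
            raise ValidationError("trial onsets must be strictly increasing")
        if np.any(df["duration_seconds"].to_numpy(float) <= 0):
            raise ValidationError("trial durations must be positive")
        has_rt = df["rt_ms"].notna().to_numpy()
        completed = df["completed"].to_numpy(bool)
        if np.any(has_rt & ~completed):
            raise ValidationError("rt_ms present for trials not completed")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset_seconds"].to_numpy(float)

    def completed_mask(self) -> np.ndarray:
        return self.df["completed"].to_numpy(bool)

    def to_events_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "onset": self.df["onset_seconds"],
                "duration": self.df["duration_seconds"],
                "trial_type": self.df["subtask"],
                "response_time": self.df["rt_ms"],
                "correct": self.df["correct"].astype(int),
                "completed": self.df["completed"].astype(int),
            }
        )
        if "amplitude" in self.df:
            out["amplitude"] = self.df["amplitude"]
        out.to_csv(path, sep="\t", index=False, na_rep="n/a")

    @classmethod
    def from_events_tsv(cls, path: str | Path) -> "TrialTable":
        raw = pd.read_csv(path, sep="\t", na_values=["n/a"])
        missing = [c for c in _EVENT_COLUMNS if c not in raw.columns]
        if missing:
            raise SchemaError(f"events file {path} lacks columns {missing}")
        df = pd.DataFrame(
            {
                "onset_seconds": raw["onset"].astype(float),
                "duration_seconds": raw["duration"].astype(float),
                "subtask": raw["trial_type"].astype(str),
                "rt_ms": raw["response_time"].astype(float),
                "correct": raw["correct"].astype(bool),
                "completed": raw["completed"].astype(bool),
            }
        )
        if "amplitude" in raw:
            df["amplitude"] = raw["amplitude"].astype(float)
        return cls(df)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path: str | Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            row = []
            for j, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell at row {i + 1}, column {j + 1}: {cell!r}"
                    ) from None
            rows.append(row)
    if not rows or len({len(r) for r in rows}) != 1:
        raise ParseError(f"{path}: empty or ragged matrix")
    return np.array(rows, dtype=float)


def read_timeseries(matrix_path: str | Path, sidecar_path: str | Path) -> RoiTimeseries:
    """Read a TSV ROI-by-time matrix plus its JSON sidecar."""
    values = _read_matrix_tsv(matrix_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    try:
        return RoiTimeseries(
            values=values,
            tr_seconds=float(meta["tr_seconds"]),
            roi_labels=list(meta["roi_labels"]),
            hemisphere=list(meta["hemisphere"]),
            condition=str(meta.get("condition", "rest")),
            run_id=str(meta.get("run_id", "run-0")),
        )
    except KeyError as exc:
        raise SchemaError(f"{sidecar_path}: missing sidecar key {exc}") from None


def write_timeseries(ts: RoiTimeseries, matrix_path: str | Path, sidecar_path: str | Path) -> None:
    """Write TSV matrix + JSON sidecar; round-trips bitwise through repr."""
    with open(matrix_path, "w") as fh:
        for row in ts.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    meta = {
        "tr_seconds": ts.tr_seconds,
        "roi_labels": ts.roi_labels,
        "hemisphere": ts.hemisphere,
        "condition": ts.condition,
        "run_id": ts.run_id,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_structural_connectivity(matrix_path: str | Path, sidecar_path: str | Path) -> StructuralConnectivity:
    counts = _read_matrix_tsv(matrix_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return StructuralConnectivity(counts=counts, roi_labels=list(meta["roi_labels"]))


def write_structural_connectivity(sc: StructuralConnectivity, matrix_path: str | Path, sidecar_path: str | Path) -> None:
    with open(matrix_path, "w") as fh:
        for row in sc.counts:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    with open(sidecar_path, "w") as fh:
        json.dump({"roi_labels": sc.roi_labels}, fh, indent=1)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bandpass_zscore(ts: RoiTimeseries, low_hz: float = 0.008, high_hz: float = 0.15) -> RoiTimeseries:
    """Band-pass filter each ROI row and normalise it to zero mean, unit SD.

    The filter is an FFT brick-wall band-pass: Fourier coefficients with
    frequency outside ``[low_hz, high_hz]`` are zeroed.  Being a projection,
    the operation is exactly idempotent, which keeps repeated preprocessing
    harmless.  The default band follows the common fMRI practice of keeping
    0.008-0.15 Hz, below the 0.15-0.3 Hz respiratory/cardiac range.

    A constant ROI row has no defined z-score and is returned as all zeros
    (with a logged warning).
    """
    nyquist = 0.5 / ts.tr_seconds
    if not (0 <= low_hz < high_hz < nyquist):
        raise ConfigurationError(
            f"need 0 <= low_hz < high_hz < Nyquist ({nyquist:.4f} Hz); "
            f"got low={low_hz}, high={high_hz}"
        )
    x = ts.values
    n = ts.n_samples
    freqs = np.fft.rfftfreq(n, d=ts.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(x, axis=1)
    spec[:, ~keep] = 0.0
    filt = np.fft.irfft(spec, n, axis=1)

    out = np.zeros_like(filt)
    sd = filt.std(axis=1, ddof=1)
    const = sd < 1e-15
    if np.any(const):
        logger.warning("z-score undefined for %d constant ROI row(s); returning zeros", int(const.sum()))
    ok = ~const
    out[ok] = (filt[ok] - filt[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    return replace(ts, values=out)


def estimate_derivative(ts: RoiTimeseries, method: str = "spectral",
                        sfd_window: int = 7, sfd_polyorder: int = 3) -> DerivativeMatrix:
    """Estimate the per-sample derivative of every ROI row.

    ``spectral``
        Multiply by ``i 2 pi f`` in the Fourier domain after removing the
        endpoint-matching linear trend and applying a narrow Tukey(0.05)
        taper to suppress wrap-around; the trend slope is added back.
    ``smoothed_finite_difference``
        Savitzky-Golay smoothing followed by central differences; exact for
        polynomials up to the smoothing order, robust to white noise.
    ``forward``
        One-step forward difference (the last sample repeats its
        predecessor).  This is the estimator matched to an Euler-Maruyama
        discretization: the increment over [t, t+1) is the drift at t plus
        noise that is independent of the state at t, so drift regression and
        drift-prediction scoring are unbiased.  Centered or smoothed
        estimators mix in past noise that is correlated with the current
        state and systematically cancel part of the decay term.

    Time is measured in samples, so values are in signal units per sample.
    """
    x = ts.values
    n = ts.n_samples
    if method == "spectral":
        if n < 8:
            raise ValidationError("spectral derivative needs at least 8 samples")
        t = np.arange(n)
        slope = (x[:, -1] - x[:, 0]) / (n - 1)
        detr = x - x[:, :1] - slope[:, None] * t
        detr *= tukey(n, 0.05)
        freqs = np.fft.rfftfreq(n, d=1.0)
        deriv = np.fft.irfft(np.fft.rfft(detr, axis=1) * (2j * np.pi * freqs), n, axis=1)
        deriv += slope[:, None]
    elif method == "smoothed_finite_difference":
        window = min(sfd_window, n if n % 2 else n - 1)
        smooth = savgol_filter(x, window, min(sfd_polyorder, window - 1), axis=1)
        deriv = np.gradient(smooth, axis=1)
    elif method == "forward":
        deriv = np.diff(x, axis=1)
        deriv = np.concatenate([deriv, deriv[:, -1:]], axis=1)
    else:
        raise ConfigurationError(
            f"unknown derivative method {method!r}; "
            "use 'spectral', 'smoothed_finite_difference' or 'forward'"
        )
    return DerivativeMatrix(values=deriv, method=method, source_run=ts.run_id)


def contralateral_pairs(roi_labels: list[str], hemisphere: list[str]) -> set[tuple[int, int]]:
    """Index pairs of homologous regions (same base label, opposite sides)."""
    base: dict[str, list[int]] = {}
    for i, lab in enumerate(roi_labels):
        stem = lab
        for suffix in ("_L", "_R"):
            if lab.endswith(suffix):
                stem = lab[: -len(suffix)]
        base.setdefault(stem, []).append(i)
    pairs = set()
    for idxs in base.values():
        for i in idxs:
            for j in idxs:
                if i != j and {hemisphere[i], hemisphere[j]} == {"left", "right"}:
                    pairs.add((i, j))
    return pairs


def edge_class(a: int, b: int, roi_labels: list[str], hemisphere: list[str]) -> str:
    """Classify edge b->a as diagonal / intrahemispheric / contralateral / interhemispheric."""
    if a == b:
        return "diagonal"
    if hemisphere[a] == hemisphere[b]:
        return "intrahemispheric"
    if (a, b) in contralateral_pairs(roi_labels, hemisphere):
        return "contralateral"
    return "interhemispheric"
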