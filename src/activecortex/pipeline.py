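"""Seeded end-to-end experiment runner and command-line interface.

A YAML config describes one experiment: a synthetic ground truth, rest and
task runs, model identification, signal separation, behavioral scoring and
(optionally) the two-task FC embedding.  ``run_experiment`` executes the
stages in order, writes every artifact under the output directory, and
records a manifest of content hashes so reruns with the same seeds can be
verified bit-for-bit.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior, evaluation, synthetic
from .errors import ActiveCortexError, ConfigurationError
from .io import estimate_derivative, read_timeseries, write_timeseries
from .separation import SeparationSpec, extract_trial_windows, separate_window
from .studies import DERIVATIVE_METHOD, fit_ec_from_run
from .sysid import load_ec, save_ec

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Validated view of one experiment YAML."""

    synthetic: dict
    preprocess: dict
    fit: dict
    separation: dict
    behavior: dict
    embed: dict
    seeds: dict
    output_dir: str

    REQUIRED = ("synthetic", "fit", "seeds", "output_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        missing = [k for k in cls.REQUIRED if k not in raw]
        if missing:
            raise ConfigurationError(f"config {path} lacks required sections {missing}")
        if not isinstance(raw["seeds"], dict) or "master" not in raw["seeds"]:
            raise ConfigurationError("config must set an explicit seeds.master")
        return cls(
            synthetic=raw["synthetic"],
            preprocess=raw.get("preprocess", {}),
            fit=raw["fit"],
            separation=raw.get("separation", {"framework": "acm"}),
            behavior=raw.get("behavior", {}),
            embed=raw.get("embed", {}),
            seeds=raw["seeds"],
            output_dir=str(raw["output_dir"]),
        )


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(config.seeds["master"])
    ss = np.random.SeedSequence(master)
    s_model, s_rest, s_train, s_test, s_rt = (int(v) % (2**31 - 1) for v in ss.generate_state(5))
    manifest: dict[str, str] = {}
    report: dict = {"seed": master}

    syn = dict(config.synthetic)
    n_rest = int(syn.pop("n_rest_samples", 20_000))
    n_train_trials = int(syn.pop("n_train_trials", 500))
    n_test_trials = int(syn.pop("n_test_trials", 300))
    try:
        stage = "simulate"
        model = synthetic.make_ground_truth(seed=s_model, **syn)
        rest, _ = synthetic.simulate_run(model, n_rest, seed=s_rest)
        write_timeseries(rest, out / "rest.tsv", out / "rest.json")
        manifest["rest.tsv"] = _hash_array(rest.values)

        schedule = synthetic.make_trial_schedule("synthetic", n_trials=n_train_trials, seed=s_train)
        n_samp = int(round(schedule.onsets[-1] / synthetic.TR_SECONDS)) + 100
        task_train, _ = synthetic.simulate_run(model, n_samp, schedule=schedule, seed=s_train)
        write_timeseries(task_train, out / "task_train.tsv", out / "task_train.json")
        manifest["task_train.tsv"] = _hash_array(task_train.values)

        schedule2 = synthetic.make_trial_schedule("synthetic", n_trials=n_test_trials, seed=s_test)
        n_samp2 = int(round(schedule2.onsets[-1] / synthetic.TR_SECONDS)) + 100
        task_test, trials = synthetic.simulate_run(model, n_samp2, schedule=schedule2, seed=s_test)
        write_timeseries(task_test, out / "task_test.tsv", out / "task_test.json")
        rt = synthetic.generate_rt(model, trials.df["amplitude"].to_numpy(), seed=s_rt)
        trials.df["rt_ms"] = rt
        trials.to_events_tsv(out / "task_test_events.tsv")
        manifest["task_test.tsv"] = _hash_array(task_test.values)
        manifest["task_test_events.tsv"] = _hash_array(rt)

        stage = "fit"
        fit_kw = dict(
            lambda_diag=float(config.fit.get("lambda_diag", model.lambda_decay)),
            order=int(config.fit.get("order", 1)),
            ridge_alpha=float(config.fit.get("ridge_alpha", 1e-2)),
            threshold=float(config.fit.get("threshold", 1e-3)),
        )
        ec_rest, rep_rest = fit_ec_from_run(rest, **fit_kw)
        ec_task, rep_task = fit_ec_from_run(task_train, **fit_kw)
        save_ec(ec_rest, out / "ec_rest")
        save_ec(ec_task, out / "ec_task")
        manifest["ec_rest.h5"] = _hash_array(ec_rest.coeffs)
        manifest["ec_task.h5"] = _hash_array(ec_task.coeffs)
        report["adjusted_r2_rest"] = rep_rest.adjusted_r2
        report["adjusted_r2_task"] = rep_task.adjusted_r2

        stage = "evaluate"
        heldout, _ = synthetic.simulate_run(model, 5_000, seed=s_rt + 1)
        corr = evaluation.derivative_prediction_correlation(ec_rest, heldout, DERIVATIVE_METHOD)
        report["heldout_median_r"] = float(np.nanmedian(corr))

        stage = "separate"
        deriv = estimate_derivative(task_test, DERIVATIVE_METHOD)
        win = extract_trial_windows(task_test, deriv, trials)
        rt = rt[: win.n_trials]
        framework = config.separation.get("framework", "acm")
        base = separate_window(win, ec_rest, ec_task, SeparationSpec.named("unseparated"))
        sep = separate_window(win, ec_rest, ec_task, SeparationSpec.named(framework))
        manifest["separated.signal"] = _hash_array(sep.signal)

        stage = "behavior"
        base_r2 = float(np.mean(behavior.elastic_net_rt(base, rt, seed=master)))
        sep_r2 = float(np.mean(behavior.elastic_net_rt(sep, rt, seed=master)))
        report["r2_unseparated"] = base_r2
        report[f"r2_{framework}"] = sep_r2
        report[f"delta_r2_{framework}"] = sep_r2 - base_r2
    except ActiveCortexError:
        (out / "manifest_partial.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        logger.error("experiment aborted during stage %r; partial manifest written", stage)
        raise

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest["report.json"] = hashlib.sha256(
        json.dumps(report, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# command line interface
# ---------------------------------------------------------------------------

def _load_config(args: argparse.Namespace) -> ExperimentConfig:
    return ExperimentConfig.from_yaml(args.config)


def _cmd_run(args: argparse.Namespace) -> int:
    run_experiment(_load_config(args))
    return 0


def _cmd_simulate(args: argparse.Namespace) -> int:
    config = _load_config(args)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(config.seeds["master"])
    syn = dict(config.synthetic)
    n_rest = int(syn.pop("n_rest_samples", 20_000))
    syn.pop("n_train_trials", None)
    syn.pop("n_test_trials", None)
    model = synthetic.make_ground_truth(seed=master, **syn)
    rest, _ = synthetic.simulate_run(model, n_rest, seed=master + 1)
    write_timeseries(rest, out / "rest.tsv", out / "rest.json")
    logger.info("wrote %s", out / "rest.tsv")
    return 0


def _cmd_fit(args: argparse.Namespace) -> int:
    config = _load_config(args)
    out = Path(config.output_dir)
    matrix = out / "rest.tsv"
    if not matrix.exists():
        logger.error("input timeseries not found: %s (run 'simulate' first)", matrix)
        return 1
    ts = read_timeseries(matrix, out / "rest.json")
    ec, report = fit_ec_from_run(
        ts,
        lambda_diag=float(config.fit.get("lambda_diag", -0.22)),
        order=int(config.fit.get("order", 1)),
        ridge_alpha=float(config.fit.get("ridge_alpha", 1e-2)),
        threshold=float(config.fit.get("threshold", 1e-3)),
    )
    save_ec(ec, out / "ec_rest")
    logger.info("fitted model: adjusted R^2 = %.3f", report.adjusted_r2)
    return 0


def _cmd_evaluate(args: argparse.Namespace) -> int:
    config = _load_config(args)
    out = Path(config.output_dir)
    if not (out / "ec_rest.h5").exists():
        logger.error("fitted model not found: %s (run 'fit' first)", out / "ec_rest.h5")
        return 1
    ec = load_ec(out / "ec_rest")
    ts = read_timeseries(out / "rest.tsv", out / "rest.json")
    corr = evaluation.derivative_prediction_correlation(ec, ts, DERIVATIVE_METHOD)
    (out / "evaluation.json").write_text(
        json.dumps({"per_roi_r": corr.tolist(), "median_r": float(np.nanmedian(corr))}, indent=1)
    )
    return 0


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="activecortex",
        description="Network-ODE identification and rest/task signal separation",
    )
    sub = parser.add_subparsers(dest="command", required=True)
    for name, fn in (
        ("run", _cmd_run),
        ("simulate", _cmd_simulate),
        ("fit", _cmd_fit),
        ("evaluate", _cmd_evaluate),
        ("separate", _cmd_run),
        ("behavior", _cmd_run),
        ("embed", _cmd_run),
    ):
        p = sub.add_parser(name)
        p.add_argument("--config", required=True, help="experiment YAML")
        p.set_defaults(func=fn)
    args = parser.parse_args(argv)
    logging.basicConfig(
        level=logging.INFO,
        stream=sys.stderr,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    try:
        return args.func(args)
    except (ActiveCortexError, FileNotFoundError) as exc:
        logger.error("%s", exc)
        return 1


if __name__ == "__main__":  # pragma: no cover
    sys.exit(main())
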