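"""Configuration-driven runs with full provenance.

A :class:`RunConfig` captures everything that defines a run — dataset,
preprocessing thresholds, learner and grid, selector, fold/repeat counts and
the base seed — and ``run_from_config`` executes it into a run directory of
JSON/CSV artifacts plus a timestamped log.  No computed number is written
without the protocol that produced it: identical config + seed gives
byte-identical numeric outputs for any worker count, because every repeat's
seed is pre-derived from the base seed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assessment import NestedCVConfig, repeated_nested_cv, summarize_repeats
from .data_model import CLASSIFICATION, REGRESSION, load_dataset
from .learners import (
    get_builder,
    grid_from_values,
    loss_for_task,
    ridge_lambda_grid,
)
from .preprocessing import preprocess
from .selection import (
    CVProtocol,
    PearsonSelector,
    make_selection_grid,
    optimal_param_distribution,
    repeated_grid_search_cv,
)

__all__ = ["RunConfig", "run_from_config", "render_report", "build_grid"]


@dataclass
class RunConfig:
    """Fully serialisable description of one run."""

    dataset_path: str
    output_column: str
    task: str
    learner: str
    mode: str = "select"                 # select | assess | both
    preprocess: bool = True
    freq_ratio_cut: float = 19.0
    unique_pct_cut: float = 10.0
    nzv_mode: str = "both"
    lincomb_tol: float | None = None
    grid: dict = field(default_factory=lambda: {"type": "auto"})
    selector: dict | None = None         # {"type": "pearson", "n_values": [...]}
    V: int = 10
    Nexp: int = 10
    V1: int = 10
    V2: int = 10
    Nexp1: int = 5
    Nexp2: int = 5
    base_seed: int = 0
    n_jobs: int = 1
    output_dir: str = "run"

    def __post_init__(self):
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task {self.task!r}")
        if self.mode not in ("select", "assess", "both"):
            raise ValueError(f"mode must be select/assess/both, got {self.mode!r}")
        if self.learner not in ("ridge", "ridge_logistic", "pls", "knn", "linear_svm"):
            raise ValueError(f"unknown learner {self.learner!r}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def build_grid(config: RunConfig, dataset):
    """Construct the (1-D) parameter grid a config describes."""
    g = config.grid
    kind = g.get("type", "auto")
    if config.learner in ("ridge", "ridge_logistic"):
        if kind == "auto":
            return ridge_lambda_grid(
                dataset, g.get("n_lambda", 100), g.get("min_ratio", 1e-6)
            )
        vals = sorted((float(v) for v in g["values"]), reverse=True)
        return grid_from_values("lambda", vals, "increasing")
    if config.learner == "pls":
        if kind == "auto":
            top = min(g.get("max_components", 60), dataset.n_samples - 1,
                      dataset.n_variables)
            vals = range(1, top + 1)
        else:
            vals = sorted(int(v) for v in g["values"])
        return grid_from_values("n_components", vals, "increasing")
    if config.learner == "knn":
        vals = sorted(int(v) for v in g.get("values", (1, 3, 5, 7, 9)))
        return grid_from_values("k", vals, "decreasing")
    if config.learner == "linear_svm":
        vals = sorted(float(v) for v in g.get("values", (0.5, 1, 2, 4, 8, 16)))
        return grid_from_values("cost", vals, "increasing")
    raise ValueError(config.learner)


def _make_selector(config: RunConfig):
    if config.selector is None:
        return None, None
    if config.selector.get("type") != "pearson":
        raise ValueError("only the 'pearson' selector is available")
    return PearsonSelector(), [int(n) for n in config.selector["n_values"]]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines = []

    def log(self, msg: str):
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        self.lines.append(f"{stamp} {msg}")

    def flush(self):
        self.path.write_text("\n".join(self.lines) + "\n")


def run_from_config(config: RunConfig) -> Path:
    """Execute preprocess → select and/or assess; return the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    log.log(f"cvprotocols {__version__} base_seed={config.base_seed}")
    (out / "config.yaml").write_text(config.to_yaml())

    dataset = load_dataset(config.dataset_path, config.output_column, config.task)
    log.log(f"loaded {dataset.n_samples} x {dataset.n_variables} from "
            f"{config.dataset_path}")
    if config.preprocess:
        dataset, report = preprocess(
            dataset, config.freq_ratio_cut, config.unique_pct_cut,
            config.nzv_mode, config.lincomb_tol,
        )
        (out / "filter_report.json").write_text(report.to_json())
        log.log(f"preprocessing removed {len(report.removed_nzv)} near-zero-variance"
                f" and {len(report.removed_lincomb)} linear-combination columns;"
                f" {len(report.kept)} kept")

    builder = get_builder(config.learner, config.task)
    loss = loss_for_task(config.task)
    selector, n_values = _make_selector(config)
    base_grid = build_grid(config, dataset)
    grid = make_selection_grid(n_values, base_grid) if selector else base_grid

    if config.mode in ("select", "both"):
        protocol = CVProtocol(
            grid=grid, V=config.V, Nexp=config.Nexp, loss=loss,
            builder=builder, selector=selector, base_seed=config.base_seed,
        )
        log.log(f"selection protocol {protocol.identifier}")
        res = repeated_grid_search_cv(dataset, protocol, n_jobs=config.n_jobs)
        _write_selection(out, res)
        log.log(f"chosen {res.chosen.label} at mean loss {res.best_mean_loss:.6g}")

    if config.mode in ("assess", "both"):
        factory = None
        fixed = grid
        if config.learner in ("ridge", "ridge_logistic") and \
                config.grid.get("type", "auto") == "auto" and selector is None:
            # leak-free default: recompute the data-derived path per outer fold
            nl = config.grid.get("n_lambda", 100)
            mr = config.grid.get("min_ratio", 1e-6)
            factory = lambda ds: ridge_lambda_grid(ds, nl, mr)  # noqa: E731
            fixed = None
        ncfg = NestedCVConfig(
            builder=builder, loss=loss, V1=config.V1, Nexp1=config.Nexp1,
            V2=config.V2, Nexp2=config.Nexp2, grid=fixed, grid_factory=factory,
            selector=selector, base_seed=config.base_seed,
        )
        log.log(f"assessment protocol {ncfg.identifier}")
        nres = repeated_nested_cv(dataset, ncfg, n_jobs=config.n_jobs)
        _write_nested(out, nres)
        log.log(f"P-estimate {nres.p_estimate:.6g} interval "
                f"[{nres.interval[0]:.6g}, {nres.interval[1]:.6g}]")

    log.flush()
    return out


def _write_selection(out: Path, res) -> None:
    labels = [pt.label for pt in res.grid]
    pd.DataFrame(res.loss_table, columns=labels).to_csv(
        out / "loss_table.csv", index=False
    )
    optimal_param_distribution(res).to_csv(
        out / "param_distribution.csv", header=True, index_label="parameter"
    )
    summarize_repeats(res.loss_table, res.grid).to_csv(
        out / "loss_summary.csv", index_label="parameter"
    )
    payload = dict(res.summary())
    payload["mean_loss"] = {lab: float(v) for lab, v in zip(labels, res.mean_loss)}
    if res.chosen_columns is not None:
        payload["chosen_columns"] = [int(c) for c in res.chosen_columns]
    (out / "selection.json").write_text(json.dumps(payload, indent=2))


def _write_nested(out: Path, nres) -> None:
    (out / "nested.json").write_text(json.dumps(nres.summary(), indent=2))
    pd.DataFrame({"repeat": np.arange(len(nres.errors)), "error": nres.errors}
                 ).to_csv(out / "nested_errors.csv", index=False)
    # histogram-ready: one error per row, for plotting alongside selection losses
    pd.DataFrame({"error": nres.errors}).to_csv(out / "nested_histogram.csv",
                                                index=False)


_SELECT_ARTIFACTS = ["selection.json", "loss_table.csv", "param_distribution.csv",
                     "loss_summary.csv"]
_ASSESS_ARTIFACTS = ["nested.json", "nested_errors.csv"]


def render_report(run_dir) -> str:
    """One-page human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    cfg_path = run_dir / "config.yaml"
    if not cfg_path.exists():
        return f"incomplete run: missing config.yaml in {run_dir}"
    cfg = yaml.safe_load(cfg_path.read_text())
    mode = cfg.get("mode", "select")
    wanted = []
    if mode in ("select", "both"):
        wanted += _SELECT_ARTIFACTS
    if mode in ("assess", "both"):
        wanted += _ASSESS_ARTIFACTS
    missing = [a for a in wanted if not (run_dir / a).exists()]
    if missing:
        return "incomplete run: missing artifacts: " + ", ".join(missing)

    lines = [
        f"cvprotocols run report — {run_dir}",
        f"dataset: {cfg['dataset_path']} (task: {cfg['task']})",
        f"learner: {cfg['learner']}  base_seed: {cfg['base_seed']}",
    ]
    if (run_dir / "filter_report.json").exists():
        fr = json.loads((run_dir / "filter_report.json").read_text())
        lines.append(
            f"preprocessing: removed {len(fr['removed_nzv'])} near-zero-variance, "
            f"{len(fr['removed_lincomb'])} linear-combination; "
            f"{len(fr['kept'])} descriptors kept"
        )
    if mode in ("select", "both"):
        sel = json.loads((run_dir / "selection.json").read_text())
        labels = list(sel["mean_loss"])
        lines += [
            "",
            f"selection protocol: {sel['protocol']}",
            f"grid: size {sel['grid_size']}, first point {labels[0]}, "
            f"last point {labels[-1]}",
            f"V = {cfg['V']}, Nexp = {cfg['Nexp']}",
            f"lowest average cross-validation loss: {sel['lowest_mean_cv_loss']:.6g}",
            f"optimal parameter: {sel['chosen']}",
        ]
    if mode in ("assess", "both"):
        ne = json.loads((run_dir / "nested.json").read_text())
        lines += [
            "",
            f"assessment protocol: {ne['protocol']}",
            f"P-estimate (mean of {ne['n_repeats']} nested CV errors): "
            f"{ne['p_estimate']:.6g}",
            f"P-estimated interval: [{ne['interval_min']:.6g}, "
            f"{ne['interval_max']:.6g}]  (min <= mean <= max)",
        ]
    return "\n".join(lines)
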