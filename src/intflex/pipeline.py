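"""End-to-end reproducible runs.

Two canonical pipelines compose the library stages:

* ``empirical`` — synthetic (or loaded) state-dependent recording plus a
  wheel-velocity trace: segment -> estimate timescales per window ->
  classify states -> rest-task statistics;
* ``model`` — synthetic (or loaded) connectome: scale -> simulate rest and
  stimulation -> windowed timescales -> rest-stimulation comparison ->
  recurrent-strength sweep.

Every stage writes its table into the run directory and a manifest records
parameters and the per-stage seeds (derived from the master seed with a
counter scheme), so a rerun with the same config reproduces the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classification, segmentation, stats, synthetic, timescales
from . import model as nm
from .containers import Recording, write_connectome_matrix, write_recording

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters for one pipeline run; round-trips losslessly via YAML."""

    seed: int = 0
    # empirical pipeline
    fs: float = 20.0
    n_channels: int = 20
    tau_rest: float = 0.3
    tau_task: float = 0.6
    n_bouts: int = 8
    velocity_threshold: float = 0.25
    window_s: float = 10.0
    cv_outer: int = 10
    cv_inner: int = 10
    cv_n_iter: int = 30
    classifier: str = "svm"
    # model pipeline
    n_regions: int = 360
    n_sims: int = 4
    w_values: list = field(default_factory=lambda: [0.0, 0.5, 1.0, 2.0])
    sim_duration: float = 300.0
    sim_discard: float = 100.0
    mode: str = "fixed_input"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage child seed below 2**31."""
        return int(
            np.random.SeedSequence([self.seed, stage]).generate_state(1)[0]
            % (2**31)
        )


def _empirical(cfg: RunConfig, out: Path) -> dict:
    rng = np.random.default_rng(cfg.stage_seed(0))
    # heterogeneous rest timescales; common task timescale
    tau_rest = cfg.tau_rest * np.exp(rng.normal(0.0, 0.3, size=cfg.n_channels))
    schedule, bout_specs = [], []
    for _ in range(cfg.n_bouts):
        schedule += [("rest", 70.0), ("run", 30.0), ("rest", 70.0)]
        bout_specs.append(synthetic.BoutSpec(70.0, 30.0, 70.0, run_speed=2.0,
                                             noise_sd=0.02))
    rec = synthetic.gen_state_recording(
        schedule, {"rest": tau_rest, "run": np.full(cfg.n_channels, cfg.tau_task)},
        n_channels=cfg.n_channels, fs=cfg.fs, seed=cfg.stage_seed(1),
    )
    velocity = synthetic.gen_wheel_velocity(bout_specs, fs=cfg.fs,
                                            seed=cfg.stage_seed(2))
    write_recording(rec, out / "recording.tsv")

    segments = segmentation.segment_pipeline(velocity, cfg.fs,
                                             threshold=cfg.velocity_threshold)
    segments.to_csv(out / "segments.tsv", sep="\t", index=False)

    int_table = timescales.segment_int(rec, segments)
    int_table.to_csv(out / "int_table.tsv", sep="\t", index=False)

    excluded = int((~int_table["converged"]).sum())
    X, y = classification.build_feature_table(int_table)
    n_per_class = min(np.bincount(np.unique(y, return_inverse=True)[1]))
    report = None
    if len(np.unique(y)) >= 2 and n_per_class >= cfg.cv_outer:
        report = classification.nested_cv_classify(
            X, y, model=cfg.classifier, inner=cfg.cv_inner, outer=cfg.cv_outer,
            n_iter=cfg.cv_n_iter, seed=cfg.stage_seed(3),
        )
        report.confusion.to_csv(out / "confusion.tsv", sep="\t")

    summary = stats.rest_task_summary(int_table, "sustained_rest", "locomotion")
    summary.to_csv(out / "rest_task_summary.tsv", sep="\t")
    rho, p, df = stats.variability_change_correlation(summary)
    t = int_table[int_table["converged"]]
    eff = stats.compare_groups(
        t.loc[t.state == "locomotion", "tau_s"].to_numpy(),
        t.loc[t.state == "sustained_rest", "tau_s"].to_numpy(),
    )
    results = {
        "n_segments": int(len(segments)),
        "n_windows_excluded": excluded,
        "overall_accuracy": None if report is None else report.overall_accuracy,
        "variability_change_rho": rho,
        "variability_change_p": p,
        "variability_change_df": df,
        "locomotion_vs_rest_z": eff.z,
        "locomotion_vs_rest_p": eff.p,
        "locomotion_vs_rest_effect_r": eff.effect_r,
    }
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2)
    return results


def _model(cfg: RunConfig, out: Path) -> dict:
    W = synthetic.gen_connectome(
        synthetic.ConnectomeSpec(n_regions=cfg.n_regions, seed=cfg.stage_seed(10))
    )
    W = nm.set_recurrent(nm.scale_offdiagonal(W), 1.0)
    write_connectome_matrix(W, out / "connectome.csv")
    params = nm.ModelParams(duration=cfg.sim_duration, discard=cfg.sim_discard)
    sweep = nm.sweep_recurrent(
        W, w_values=cfg.w_values, n_sims=cfg.n_sims, mode=cfg.mode,
        params=params, seed=cfg.stage_seed(11),
    )
    sweep.to_csv(out / "sweep_summary.tsv", sep="\t", index=False)
    results = {"sweep": sweep.to_dict(orient="records")}
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2)
    return results


def run_pipeline(
    config: RunConfig, pipeline: str, out_dir: str | Path
) -> dict:
    """Run the ``empirical`` or ``model`` pipeline into ``out_dir``.

    Writes all intermediate tables, a ``results.json`` with the headline
    numbers and a ``manifest.yaml`` with the configuration and per-stage
    seeds; returns the results dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    if pipeline == "empirical":
        results = _empirical(config, out)
    elif pipeline == "model":
        results = _model(config, out)
    else:
        raise ValueError(f"unknown pipeline {pipeline!r}")
    manifest = {
        "pipeline": pipeline,
        "config": asdict(config),
        "stage_seeds": {k: config.stage_seed(k) for k in range(12)},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return results
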