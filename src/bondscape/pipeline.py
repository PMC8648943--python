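"""End-to-end pipeline: simulate → detect → reduce → fit, with a manifest.

The pipeline drives the library modules over a configuration (optionally
loaded from YAML), writes every intermediate table as plain text under an
output directory, and records a manifest (seed, parameter values, package
version, output hashes) from which the whole bundle can be regenerated.
All randomness flows through one seeded generator per run, so a rerun with
the same configuration is numerically identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .core import BondscapeError, Environment
from .detection import DetectionParams, analyze_curve
from .kinetics import dfs_reduce, fit_bell_evans
from .synthetic import BondModel, CurveSynthesisSpec, ExperimentConfig, generate_dfs_dataset


class PipelineError(BondscapeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full simulate–detect–fit run."""

    k0: float = 2.0  # 1/s, generating bond off-rate
    x_beta: float = 0.81  # nm, generating barrier distance
    temperature: float = 298.15  # K
    velocities: tuple[float, ...] = (1.0, 3.1, 6.3, 12.5, 25.0)
    events_per_velocity: int = 92
    noise_sd: float = 3.0  # pN
    nonspecific_prob: float = 0.1
    tau_d: float = 1e-5  # s
    mode: str = "binding"
    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        det = raw.pop("detection", None)
        cfg = cls(**{k: (tuple(v) if k == "velocities" else v) for k, v in raw.items()})
        if det:
            cfg.detection = DetectionParams(**det)
        return cfg

    def experiment_config(self) -> ExperimentConfig:
        env = Environment(temperature=self.temperature)
        bond = BondModel(k0=self.k0, x_beta=self.x_beta, env=env)
        curve_spec = CurveSynthesisSpec(
            noise_sd=self.noise_sd, nonspecific_prob=self.nonspecific_prob, env=env
        )
        return ExperimentConfig(
            bond=bond,
            velocities=self.velocities,
            events_per_velocity=self.events_per_velocity,
            curve_spec=curve_spec,
            seed=self.seed,
        )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run simulate → detect → reduce → fit and write the report bundle.

    Writes curve tables, detected/discarded event tables, the DFS point
    table, the Bell–Evans fit report and a manifest; returns a summary
    dict with the fit and file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    env = Environment(temperature=config.temperature)

    try:
        curves, truth = generate_dfs_dataset(config.experiment_config())
    except Exception as exc:
        raise PipelineError(f"simulate stage failed: {exc}") from exc
    curves_path = outdir / "curves.tsv"
    io.write_curve_table(curves, curves_path)
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)

    try:
        rows, discards = [], []
        for curve in curves:
            event, reason = analyze_curve(curve, config.detection, config.mode)
            if event is None:
                discards.append({"curve_id": curve.curve_id, "reason": reason})
            else:
                rows.append(
                    {
                        "curve_id": curve.curve_id,
                        "velocity": curve.pulling_velocity,
                        "rupture_distance": event.rupture_distance,
                        "rupture_force": event.rupture_force,
                        "loading_rate": event.loading_rate,
                    }
                )
        events = pd.DataFrame(rows)
    except Exception as exc:
        raise PipelineError(f"detect stage failed: {exc}") from exc
    events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    pd.DataFrame(discards).to_csv(outdir / "discards.tsv", sep="\t", index=False)

    try:
        points = dfs_reduce(events)
        fit = fit_bell_evans(points, env, tau_d=config.tau_d)
    except Exception as exc:
        raise PipelineError(f"fit stage failed: {exc}") from exc
    points_df = pd.DataFrame(
        [{"velocity": p.velocity, "mp_force": p.mp_force,
          "mp_loading_rate": p.mp_loading_rate, "n": p.n} for p in points]
    )
    points_df.to_csv(outdir / "dfs_points.tsv", sep="\t", index=False)
    fit_path = outdir / "bell_evans_fit.json"
    io.write_results(fit, fit_path, seed=config.seed, input_hash=io.hash_file(curves_path))

    manifest = {
        "package": "bondscape",
        "version": io.__version__,
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
        "outputs": {
            p.name: io.hash_file(p)
            for p in sorted(outdir.iterdir())
            if p.suffix in (".tsv", ".json") and p.name != "manifest.json"
        },
        "n_curves": len(curves),
        "n_events": int(len(events)),
        "n_discarded": len(discards),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {"fit": fit, "points": points, "events": events, "manifest": manifest,
            "outdir": outdir}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
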