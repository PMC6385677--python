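"""End-to-end orchestration: sample -> simulate -> label -> curate -> train -> interpret.

The configuration is a validated pydantic model loaded from YAML; every run
writes the resolved configuration, a version stamp and per-stage logs beside
its outputs, and re-running with the same seed reproduces every numeric
output.  Stages whose outputs already exist can be skipped with ``resume``.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from modetime.bnn import BNNConfig, BNNResults, DissociationTimeBNN
from modetime.curation import assemble
from modetime.dynamics import default_study_potential, generate_study
from modetime.fixtures import build_synthetic_system
from modetime.harmonic import mode_report, normal_mode_analysis
from modetime.interpret import (
    compare_to_simulation,
    predict_half_times,
    simulate_half_times,
)
from modetime.io import load_system, save_study
from modetime.labels import label_study
from modetime.wigner import VibrationalStateSpec

logger = logging.getLogger("modetime.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class BNNSection(BaseModel):
    hidden_layers: list[int] = [64, 32]
    activation: str = "tanh"
    prior_scale: float = 0.7
    learn_rate: float = 3e-3
    epochs: int = 900
    batch_size: int = 256

    def to_config(self, seed: int) -> BNNConfig:
        return BNNConfig(
            hidden_layers=tuple(self.hidden_layers),
            activation=self.activation,
            prior_scale=self.prior_scale,
            learn_rate=self.learn_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=seed,
        )


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-serialisable)."""

    seed: int = 0
    geometry: str | None = None  # XYZ path; None -> synthetic 8-atom system
    hessian: str | None = None
    n_trajectories: int = Field(250, ge=1)
    dt_au: float = Field(10.0, gt=0)
    max_time_fs: float = Field(250.0, gt=0)
    kick_energy: float = Field(1.0, ge=0)
    stride: int = Field(5, ge=1)
    with_velocities: bool = True
    train_frac: float = 0.80
    val_frac: float = 0.10
    test_frac: float = 0.10
    variance_target: float = 0.90
    bnn: BNNSection = BNNSection()
    interpret_modes: list[int] = [1, 2, 3, 4]
    interpret_n: int = Field(250, ge=1)
    stages: list[str] = ["simulate", "label", "curate", "train", "interpret"]

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: list[str]) -> list[str]:
        known = {"simulate", "label", "curate", "train", "interpret"}
        bad = set(v) - known
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig(**(yaml.safe_load(Path(path).read_text()) or {}))


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, resume: bool = False
) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    from modetime import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.resolved.yaml").write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True)
    )
    (outdir / "version.json").write_text(
        json.dumps({"modetime": __version__, "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S")})
    )
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        _run_stages(config, outdir, resume)
    except Exception as err:
        logger.error("pipeline halted: %s", err)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir


def _run_stages(config: PipelineConfig, outdir: Path, resume: bool) -> None:
    if config.geometry and config.hessian:
        system = load_system(config.geometry, config.hessian)
    else:
        system = build_synthetic_system(8, seed=config.seed)
    basis = normal_mode_analysis(system)
    (outdir / "modes.txt").write_text(mode_report(basis) + "\n")
    potential = default_study_potential(basis)
    logger.info("modes: %d (rc at %s), seed=%d", basis.n_modes, basis.rc_index, config.seed)

    ground = VibrationalStateSpec(
        quanta={}, ensemble_size=config.n_trajectories, kick_energy=config.kick_energy
    )

    study_path = outdir / "study.h5"
    if "simulate" in config.stages and not (resume and study_path.exists()):
        logger.info("simulate: %d trajectories", config.n_trajectories)
        study = generate_study(
            basis, potential, [ground], seed=config.seed,
            dt=config.dt_au, max_time=config.max_time_fs,
        )
        save_study(
            study_path, study,
            manifest={"seed": config.seed, "ensemble": "ground",
                      "planted_modes": list(potential.planted_modes)},
        )

    frames_path = outdir / "frames.csv"
    if "label" in config.stages and not (resume and frames_path.exists()):
        from modetime.io import load_study

        study, _ = load_study(study_path)
        frames = label_study(
            study["ground"], stride=config.stride,
            with_velocities=config.with_velocities,
        )
        frames.to_csv(frames_path, index=False)
        logger.info("label: %d frames", len(frames))

    dataset = None
    if "curate" in config.stages:
        frames = pd.read_csv(frames_path)
        dataset = assemble(
            frames, seed=config.seed,
            train_frac=config.train_frac, val_frac=config.val_frac,
            test_frac=config.test_frac, variance_target=config.variance_target,
        )
        dataset.save(outdir / "dataset")
        logger.info("curate: %s", dataset.manifest()["sizes"])

    model_path = outdir / "model.npz"
    if "train" in config.stages and dataset is not None:
        if resume and model_path.exists():
            results = BNNResults.load(model_path)
            results.model = DissociationTimeBNN(dataset, results.config)
        else:
            results = DissociationTimeBNN(
                dataset, config.bnn.to_config(config.seed)
            ).fit()
            results.save(model_path)
        metrics = {s: vars(results.evaluate(s)) for s in ("train", "val", "test")}
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        results.coefficient_magnitudes().to_frame().to_csv(outdir / "relevance.csv")
        (outdir / "summary.txt").write_text(results.summary() + "\n")
        logger.info("train: %s", results.evaluate("test"))
    elif "interpret" in config.stages and model_path.exists():
        results = BNNResults.load(model_path)
    else:
        results = None

    if "interpret" in config.stages and results is not None:
        specs = [VibrationalStateSpec(quanta={})] + [
            VibrationalStateSpec(quanta={m: 1}) for m in config.interpret_modes
        ]
        predicted = predict_half_times(
            results, basis, specs, n=config.interpret_n, seed=config.seed + 1
        )
        predicted.to_frame().to_csv(outdir / "half_times_predicted.csv", index=False)
        simulated = simulate_half_times(
            basis, potential, specs, n=config.interpret_n, seed=config.seed + 2,
            dt=config.dt_au, max_time=config.max_time_fs,
        )
        simulated.to_frame().to_csv(outdir / "half_times_simulated.csv", index=False)
        report = compare_to_simulation(predicted, simulated)
        (outdir / "half_time_comparison.json").write_text(
            json.dumps(
                {
                    "rmsd_fs": report.rmsd,
                    "kendall_tau": report.kendall_tau,
                    "per_ensemble": report.to_frame().to_dict(orient="records"),
                },
                indent=2,
            )
        )
        logger.info(
            "interpret: RMSD %.2f fs, Kendall tau %.2f", report.rmsd, report.kendall_tau
        )
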