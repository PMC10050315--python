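"""Pipeline configuration and end-to-end orchestration.

A pipeline run covers the full analysis chain on synthetic data:
simulate per-glycan event tables -> apply the unoccupied-pore filter
(I_b/I_0 > 0.99) -> optionally deconvolve a simulated mixture -> optionally
featurize and classify. Every random draw is derived deterministically from
one root seed, every written file is checksummed into a manifest, and every
filled default is recorded, so identical configs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import classify, features, mixture, synth
from .events import EventTable, filter_events, write_event_table

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "stage_seed"]


class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    models: list[str] = Field(min_length=1)
    n_events: int = Field(default=40_000, gt=0)
    mixture_weights: list[float] | None = None  # enables the mixture branch
    mixture_n: int = Field(default=10_000, gt=0)


class GridBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bins: int = Field(default=mixture.DEFAULT_BINS, gt=1)
    eps: float = Field(default=mixture.DEFAULT_EPS, gt=0)


class FeatureBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k: int = Field(default=3, ge=1)
    subset_size: int = Field(default=2000, gt=0)


class ClassifyBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    models: list[str] = Field(default_factory=lambda: list(classify.ALGORITHMS))
    cycles: int = Field(default=100, gt=0)
    replicates: int = Field(default=10, gt=0)
    enabled: bool = True

    @field_validator("models")
    @classmethod
    def _known_algorithms(cls, v: list[str]) -> list[str]:
        unknown = [m for m in v if m not in classify.ALGORITHMS]
        if unknown:
            raise ValueError(f"unknown classifier(s) {unknown}; choose from {classify.ALGORITHMS}")
        return v


class PipelineConfig(BaseModel):
    """Validated configuration of one end-to-end run."""

    model_config = ConfigDict(extra="forbid")

    library: str = "builtin"  # "builtin" or a path to a JSON population library
    simulation: SimulationBlock
    grid: GridBlock = GridBlock()
    features: FeatureBlock = FeatureBlock()
    classify: ClassifyBlock = ClassifyBlock()
    seed: int = Field(default=0, ge=0)
    output_dir: str = "glycopore_run"

    def load_library(self) -> dict[str, synth.GlycanPopulationModel]:
        lib = synth.builtin_library() if self.library == "builtin" else synth.load_library(self.library)
        missing = [m for m in self.simulation.models if m not in lib]
        if missing:
            raise ValueError(f"model(s) {missing} not found in library {self.library!r}")
        return lib


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; unknown keys are errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = yaml.safe_load(path.read_text())
    cfg = PipelineConfig.model_validate(doc)
    if cfg.simulation.mixture_weights is not None:
        w = cfg.simulation.mixture_weights
        if len(w) != len(cfg.simulation.models):
            raise ValueError("mixture_weights must match the number of models")
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("mixture_weights must be non-negative and sum to 1")
    cfg.load_library()  # referenced models must exist
    return cfg


def stage_seed(root_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; return (and write) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    lib = config.load_library()
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "stages": [],
        "files": {},
        "seeds": {},
    }

    def record(path: Path) -> None:
        manifest["files"][path.name] = _sha256(path)

    try:
        # --- simulate + filter -------------------------------------------------
        tables: dict[str, EventTable] = {}
        for i, name in enumerate(config.simulation.models):
            seed = stage_seed(config.seed, "simulate", i)
            manifest["seeds"][f"simulate:{name}"] = seed
            raw = synth.sample_events(lib[name], config.simulation.n_events, seed=seed)
            tab = filter_events(raw)
            tables[name] = tab
            path = outdir / f"{name}.csv"
            write_event_table(tab, path)
            record(path)
        manifest["stages"].append("simulate+filter")

        # --- mixture branch ----------------------------------------------------
        if config.simulation.mixture_weights is not None:
            seed = stage_seed(config.seed, "mixture")
            manifest["seeds"]["mixture"] = seed
            models = [lib[m] for m in config.simulation.models]
            mix = filter_events(
                synth.sample_mixture(
                    models, config.simulation.mixture_weights, config.simulation.mixture_n, seed=seed
                )
            )
            grid = mixture.GridSpec.from_tables(
                [mix, *tables.values()], bins=config.grid.bins, eps=config.grid.eps
            )
            est = mixture.estimate_weights(mix, list(tables.values()), grid=grid)
            weights_doc = {
                "models": config.simulation.models,
                "weights": est.weights.tolist(),
                "objective": est.objective,
                "iterations": est.iterations,
                "converged": est.converged,
                "grid": {"bins": config.grid.bins, "eps": config.grid.eps},
            }
            wpath = outdir / "weights.json"
            wpath.write_text(json.dumps(weights_doc, indent=2))
            record(wpath)
            manifest["stages"].append("fit-mixture")

        # --- featurize + classify ---------------------------------------------
        if config.classify.enabled and len(tables) >= 2:
            seed = stage_seed(config.seed, "features")
            manifest["seeds"]["features"] = seed
            fm = features.build_feature_matrix(
                tables, k=config.features.k, subset_size=config.features.subset_size, seed=seed
            )
            fpath = outdir / "features.csv"
            fm.to_frame().to_csv(fpath, index=False)
            record(fpath)
            specs = [s for s in classify.default_model_specs() if s.algorithm in config.classify.models]
            cseed = stage_seed(config.seed, "classify")
            manifest["seeds"]["classify"] = cseed
            reports = classify.run_replicates(
                tables,
                specs,
                k=config.features.k,
                subset_size=config.features.subset_size,
                replicates=config.classify.replicates,
                cycles=config.classify.cycles,
                base_seed=cseed,
            )
            rpath = outdir / "report.json"
            rpath.write_text(json.dumps([r.to_dict() for r in reports], indent=2))
            record(rpath)
            manifest["stages"].append("featurize+classify")
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "simulate"
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed after {manifest['failed_stage']}: {exc}") from exc

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest
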