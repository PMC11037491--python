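"""Run configuration, orchestration, and output plumbing.

A :class:`RunConfig` captures everything needed to reproduce a run:
observer parameters, experiment design, optional population specification,
simulation mode and seeds.  Configs round-trip losslessly through YAML,
unknown keys are rejected, and every omitted field falls back to the
baseline observer.  :func:`run_pipeline` executes prior -> observer ->
experiment/population -> effects end to end and writes plain CSV/JSON
artifacts plus a manifest with the package version and a config hash, so
identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .effects import correlate_effects, estimate_effects
from .errors import ConfigurationError, DotLatticeError
from .experiment import (
    DEFAULT_ASPECT_RATIOS,
    ExperimentDesign,
    predict_experiment,
    sample_experiment,
    summarize_logit,
)
from .observer import BASELINE, ObserverParams
from .population import (
    DEFAULT_COVARIANCE,
    PopulationSpec,
    draw_individuals,
    individuals_manifest,
    simulate_population,
)


class ObserverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    c_stim: float = BASELINE["c_stim"]
    kappa_stimL1: float = BASELINE["kappa_stimL1"]
    kappa_sensL1: float = BASELINE["kappa_sensL1"]
    kappa_stimL2: float = BASELINE["kappa_stimL2"]
    kappa_sensL2: float = BASELINE["kappa_sensL2"]
    kappa_percL1: float = BASELINE["kappa_percL1"]
    w_stimL1: float = Field(BASELINE["w_stimL1"], ge=0.0, le=1.0)
    w_percL1: float = Field(BASELINE["w_percL1"], ge=0.0, le=1.0)
    prior_kind: str = "uniform"
    variant: str = "hierarchical"

    def to_params(self) -> ObserverParams:
        return ObserverParams(**self.model_dump())


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    aspect_ratios: list[float] = Field(
        default_factory=lambda: list(DEFAULT_ASPECT_RATIOS)
    )
    orientations: list[float] | None = None
    n_per_condition: int = Field(100, ge=1)

    def to_design(self, seed: int | None = None) -> ExperimentDesign:
        return ExperimentDesign(
            tuple(self.aspect_ratios),
            tuple(self.orientations) if self.orientations is not None else None,
            self.n_per_condition,
            seed,
        )


class PopulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_individuals: int = Field(75, ge=1)
    means: list[float] = Field(default_factory=lambda: [5.0, 6.5, 5.0])
    covariance: list[list[float]] = Field(
        default_factory=lambda: DEFAULT_COVARIANCE.tolist()
    )
    lower: list[float] = Field(default_factory=lambda: [0.0, 0.0, 0.0])
    upper: list[float] = Field(default_factory=lambda: [float("inf"), 10.0, 10.0])
    weight_rescale: float = 10.0

    def to_spec(self, seed: int | None = None) -> PopulationSpec:
        return PopulationSpec(
            self.n_individuals,
            tuple(self.means),
            np.asarray(self.covariance, dtype=float),
            tuple(self.lower),
            tuple(self.upper),
            self.weight_rescale,
            seed,
        )


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    observer: ObserverConfig = Field(default_factory=ObserverConfig)
    design: DesignConfig = Field(default_factory=DesignConfig)
    population: PopulationConfig | None = None
    mode: str = "expected"  # "expected" | "sampled"
    seed: int = 0
    bootstrap: int = Field(2000, ge=1)
    bootstrap_seed: int = 0

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    An empty file yields the full baseline defaults; unknown keys raise a
    :class:`ConfigurationError` naming the offending key.
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        keys = ", ".join(
            "->".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ConfigurationError(f"invalid configuration ({keys}): {err}") from err


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full simulation + analysis pipeline into ``out_dir``.

    Writes per-run CSV tables (responses, logit summaries, effects), a
    correlation report (population runs), and ``manifest.json``.  Returns
    the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.mode not in ("expected", "sampled"):
        raise ConfigurationError(f"mode must be 'expected' or 'sampled', got {config.mode!r}")

    artifacts: list[str] = []

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except DotLatticeError as err:
            raise type(err)(f"[stage {name}] {err}") from err

    design = config.design.to_design(seed=config.seed)
    if config.population is None:
        params = config.observer.to_params()
        if config.mode == "expected":
            table = _stage("experiment", predict_experiment, params, design)
        else:
            table = _stage("experiment", sample_experiment, params, design)
        table.to_csv(out / "responses.csv")
        artifacts.append("responses.csv")
        summary = _stage("summary", summarize_logit, table)
        tables = {0: table}
    else:
        spec = config.population.to_spec(seed=config.seed)
        shared = config.observer.to_params()
        individuals = _stage("population", draw_individuals, spec, shared)
        individuals_manifest(individuals).to_csv(out / "individuals.csv", index=False)
        artifacts.append("individuals.csv")
        tables = _stage(
            "population", simulate_population, individuals, design, config.mode
        )
        resp_dir = out / "responses"
        resp_dir.mkdir(exist_ok=True)
        for ind_id, table in tables.items():
            table.to_csv(resp_dir / f"individual_{ind_id:03d}.csv")
        artifacts.append("responses/")
        summary = _stage("summary", summarize_logit, tables[next(iter(tables))])

    summary["l1"].to_csv(out / "logit_l1.csv", index=False)
    summary["l2"].to_csv(out / "logit_l2.csv", index=False)
    artifacts += ["logit_l1.csv", "logit_l2.csv"]

    estimates = _stage("effects", estimate_effects, tables)
    estimates.to_csv(out / "effects.csv", index=False)
    artifacts.append("effects.csv")

    manifest = {
        "package": "dotlattice",
        "version": __version__,
        "config": config.model_dump(),
        "config_hash": config.hash(),
        "mode": config.mode,
        "seed": config.seed,
        "artifacts": artifacts,
    }

    if len(estimates) >= 3:
        report = _stage(
            "correlation",
            correlate_effects,
            estimates,
            n_boot=config.bootstrap,
            seed=config.bootstrap_seed,
        )
        (out / "correlations.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )
        manifest["artifacts"].append("correlations.json")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
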