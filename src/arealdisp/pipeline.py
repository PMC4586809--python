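"""End-to-end orchestration: standardize, fit, compare, export.

``run_pipeline`` sequences the full analysis for each requested cancer
stratum and writes tidy CSV outputs plus a manifest recording the seed,
configuration hash and every file produced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diagnostics import compare_models, dic, exceedence, prior_sensitivity
from .graph import read_adjacency
from .mcmc import FitResult, McmcConfig, disparity_surface, fit_model, fitted_sir
from .models import ModelSpec, build_design
from .panel import read_panel
from .standardize import expected_counts, sir, sir_ratio_by_year, statewide_rates


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, model menu and sampler settings for one pipeline run."""

    panel_path: str
    covariates_path: str
    adjacency_path: str
    out_dir: str
    seed: int = 0
    models: tuple = (1, 2, 3)
    cancers: tuple | None = None  # None = all strata in the panel
    mcmc: McmcConfig | None = None
    spec: ModelSpec | None = None
    complete_grid: bool = False
    run_sensitivity: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        _validate_config_doc(doc)
        mcmc = McmcConfig(**doc.pop("mcmc", {}))
        spec = ModelSpec.from_dict(doc.pop("spec", {})) if "spec" in doc else None
        doc["models"] = tuple(doc.get("models", (1, 2, 3)))
        if doc.get("cancers") is not None:
            doc["cancers"] = tuple(doc["cancers"])
        return cls(mcmc=mcmc, spec=spec, **doc)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "panel": self.panel_path,
                "covariates": self.covariates_path,
                "adjacency": self.adjacency_path,
                "seed": self.seed,
                "models": list(self.models),
                "cancers": list(self.cancers) if self.cancers else None,
                "mcmc": (self.mcmc or McmcConfig(seed=self.seed)).to_dict(),
                "spec": (self.spec or ModelSpec()).to_dict(),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SCHEMA = {
    "required": ["panel_path", "covariates_path", "adjacency_path", "out_dir"],
    "optional": [
        "seed", "models", "cancers", "mcmc", "spec", "complete_grid", "run_sensitivity",
    ],
}


def _validate_config_doc(doc: dict) -> None:
    if not isinstance(doc, dict):
        raise ValueError("run config must be a mapping")
    missing = [k for k in _SCHEMA["required"] if k not in doc]
    if missing:
        raise ValueError(f"run config missing keys: {missing}")
    unknown = set(doc) - set(_SCHEMA["required"]) - set(_SCHEMA["optional"])
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute standardize -> fit (per model) -> compare -> map exports.

    Returns the manifest dict (also written to ``manifest.json``).  A
    failing stage aborts with :class:`PipelineError` naming the stage;
    files written by completed stages are left in place.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
        "files": [],
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        manifest["files"].append(name)

    def _stage(name: str):
        log(f"[stage] {name}")
        manifest["stages"].append(name)

    # ---- load ------------------------------------------------------------
    try:
        _stage("load")
        for p in (config.panel_path, config.covariates_path, config.adjacency_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        panel = read_panel(
            config.panel_path, covariates=config.covariates_path,
            complete=config.complete_grid,
        )
        graph = read_adjacency(config.adjacency_path, areas=panel.areas())
    except Exception as err:
        raise PipelineError("load", err) from err

    # configuration errors before any compute
    needs_graph = any(m >= 3 for m in config.models)
    if needs_graph and graph.n_areas == 0:
        raise PipelineError("load", ValueError("Model 3 requires adjacency input"))

    mcmc = config.mcmc or McmcConfig(seed=config.seed)
    base_spec = config.spec or ModelSpec()
    cancers = config.cancers or tuple(panel.cancers())

    # ---- standardize -----------------------------------------------------
    try:
        _stage("standardize")
        rates = statewide_rates(panel)
        expected = expected_counts(panel, rates)
        sirs = sir(panel, expected)
        _write(rates, "rates.csv")
        _write(
            sirs.data, "sir.csv"
        )
        _write(sir_ratio_by_year(sirs), "sir_ratio_by_year.csv")
    except Exception as err:
        raise PipelineError("standardize", err) from err

    # ---- fit / compare per cancer ---------------------------------------
    for cancer in cancers:
        fits: list[FitResult] = []
        for model_id in config.models:
            stage = f"fit-m{model_id}-{cancer}"
            try:
                _stage(stage)
                d = base_spec.to_dict()
                d["model_id"] = model_id
                spec = ModelSpec.from_dict(d)
                fit = fit_model(spec, panel, expected, graph, mcmc, cancer=cancer)
                fits.append(fit)
                _write(fit.summaries().assign(cancer=cancer, model=model_id),
                       f"summary_m{model_id}_{cancer}.csv")
                rep = dic(fit)
                log(f"  model {model_id} ({cancer}): DIC={rep.dic:.1f} pD={rep.pd:.1f} "
                    f"acceptance={ {k: round(v, 2) for k, v in fit.acceptance.items()} }")
            except Exception as err:
                raise PipelineError(stage, err) from err
        try:
            _stage(f"compare-{cancer}")
            _write(compare_models(fits).assign(cancer=cancer), f"dic_{cancer}.csv")
            best = fits[-1]
            _write(fitted_sir(best), f"fitted_sir_{cancer}.csv")
            _write(disparity_surface(best), f"disparity_surface_{cancer}.csv")
            _write(exceedence(best).data, f"exceedence_{cancer}.csv")
        except Exception as err:
            raise PipelineError(f"compare-{cancer}", err) from err
        if config.run_sensitivity:
            try:
                _stage(f"sensitivity-{cancer}")
                spec3 = ModelSpec.from_dict({**base_spec.to_dict(), "model_id": max(config.models)})
                design = build_design(panel, expected, cancer, spec3)
                _write(prior_sensitivity(spec3, design, graph, mcmc),
                       f"sensitivity_{cancer}.csv")
            except Exception as err:
                raise PipelineError(f"sensitivity-{cancer}", err) from err

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
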