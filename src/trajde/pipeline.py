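"""End-to-end pipeline orchestration with config files and run manifests.

A run executes the requested stages in order -- simulate (or load), bin, fit,
cluster, evaluate -- writing each stage's outputs under the configured output
directory and recording a manifest (config snapshot with all defaults echoed,
seed, per-stage outputs with checksums, gene/cell/bin counts and wall times).
Re-running with an identical config and seed reproduces identical result
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from .binning import STRATEGIES, squeeze
from .data import load_cell_experiment, write_results
from .simulate import PRESETS, SimConfig, scenario_presets, simulate_bifurcation
from .workflow import WorkflowConfig, cluster_trends, run_workflow

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "run_pipeline", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails schema validation."""


DEFAULT_CONFIG = {
    "seed": None,
    "outdir": "trajde_run",
    "simulate": None,   # {"preset": name, **SimConfig overrides} or SimConfig fields
    "input": None,      # {"matrix":..., "cell_metadata":..., "pseudotime_column":..., "path_column":...}
    "binning": {
        "strategy": "sturges",
        "drop_factor": 1.0,
        "split_bin": True,
        "prune_bin": False,
        "drop_tails": False,
        "range_mode": "global",
        "max_iterations": 10,
    },
    "fit": {
        "degree": 3,
        "alpha_screen": 0.05,
        "p_adjust": "fdr_bh",
        "alpha_step": 0.05,
        "rsq_threshold": 0.6,
        "family": "nb",
        "theta": "estimate",
        "use_offset": True,
        "reference_path": None,
        "workers": 1,
    },
    "cluster": {"n_clusters": 0},
    "evaluate": {"enabled": True, "alpha": 0.05},
}

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def _merge_section(name: str, defaults: dict, given: dict | None) -> dict:
    given = given or {}
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    return out


def validate_config(config: dict) -> dict:
    """Validate a raw config dict against the schema, filling all defaults."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    out = {
        "seed": config.get("seed"),
        "outdir": config.get("outdir", DEFAULT_CONFIG["outdir"]),
    }
    sim = config.get("simulate")
    if sim is not None:
        sim = dict(sim)
        preset = sim.pop("preset", None)
        if preset is not None and preset not in PRESETS:
            raise ConfigError(f"unknown simulation preset {preset!r}")
        bad = set(sim) - _SIM_FIELDS
        if bad:
            raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
        sim["preset"] = preset
        # tuples survive YAML round-trips as lists
        for key in ("path_skew", "path_nsteps"):
            if key in sim:
                sim[key] = tuple(sim[key])
    out["simulate"] = sim
    inp = config.get("input")
    if inp is not None:
        inp = _merge_section(
            "input",
            {
                "matrix": None,
                "cell_metadata": None,
                "pseudotime_column": "pseudotime",
                "path_column": "path",
                "transpose": False,
            },
            inp,
        )
        if not inp["matrix"] or not inp["cell_metadata"]:
            raise ConfigError("input section requires 'matrix' and 'cell_metadata'")
    out["input"] = inp
    if out["simulate"] is None and out["input"] is None:
        raise ConfigError("config must provide either 'simulate' or 'input'")

    out["binning"] = _merge_section(
        "binning", DEFAULT_CONFIG["binning"], config.get("binning")
    )
    if out["binning"]["strategy"] not in STRATEGIES:
        raise ConfigError(f"unknown binning strategy {out['binning']['strategy']!r}")
    if out["binning"]["drop_factor"] < 0.3:
        raise ConfigError("binning drop_factor must be >= 0.3")
    if out["binning"]["range_mode"] not in ("global", "path"):
        raise ConfigError("binning range_mode must be 'global' or 'path'")
    out["fit"] = _merge_section("fit", DEFAULT_CONFIG["fit"], config.get("fit"))
    out["cluster"] = _merge_section(
        "cluster", DEFAULT_CONFIG["cluster"], config.get("cluster")
    )
    out["evaluate"] = _merge_section(
        "evaluate", DEFAULT_CONFIG["evaluate"], config.get("evaluate")
    )
    try:
        WorkflowConfig(**{k: v for k, v in out["fit"].items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid fit section: {exc}") from exc
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _register(manifest: dict, stage: str, t0: float, outputs: list, **counts) -> None:
    manifest["stages"].append(
        {
            "name": stage,
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "counts": counts,
        }
    )


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured stages end to end; returns the run manifest.

    ``config`` is a YAML file path or an equivalent dict.  Any stage failure
    propagates after the partial manifest is written to the output directory.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _jsonable(cfg), "seed": cfg["seed"], "stages": []}
    manifest_path = outdir / "manifest.json"

    try:
        # --- stage: obtain the experiment ------------------------------
        t0 = time.perf_counter()
        truth = None
        if cfg["simulate"] is not None:
            sim = dict(cfg["simulate"])
            preset = sim.pop("preset", None)
            if preset:
                sim_config = scenario_presets(preset, seed=cfg["seed"], **sim)
            else:
                sim.setdefault("seed", cfg["seed"])
                sim_config = SimConfig(**sim)
            experiment, truth = simulate_bifurcation(sim_config)
            sim_dir = outdir / "simulated"
            experiment.write(sim_dir)
            truth.to_frame().to_csv(
                outdir / "truth.tsv", sep="\t", index=False, float_format="%.17g"
            )
            _register(
                manifest, "simulate", t0,
                [sim_dir / "matrix.mtx", sim_dir / "cell_metadata.tsv",
                 outdir / "truth.tsv"],
                n_genes=experiment.n_genes, n_cells=experiment.n_cells,
                sparsity=round(experiment.sparsity(), 4),
            )
        else:
            inp = cfg["input"]
            experiment = load_cell_experiment(
                inp["matrix"], inp["cell_metadata"],
                pseudotime_column=inp["pseudotime_column"],
                path_column=inp["path_column"], transpose=inp["transpose"],
            )
            _register(manifest, "load", t0, [],
                      n_genes=experiment.n_genes, n_cells=experiment.n_cells)

        # --- stage: binning --------------------------------------------
        t0 = time.perf_counter()
        b = cfg["binning"]
        binned = squeeze(
            experiment, strategy=b["strategy"], k=b["drop_factor"],
            split_bin=b["split_bin"], prune_bin=b["prune_bin"],
            drop_tails_flag=b["drop_tails"], range_mode=b["range_mode"],
            max_iterations=b["max_iterations"],
        )
        bin_dir = outdir / "binned"
        binned.write(bin_dir)
        _register(
            manifest, "bin", t0,
            [bin_dir / "pseudobulk.mtx", bin_dir / "bin_metadata.tsv"],
            n_bins=binned.n_bins,
            cells_binned=int(binned.bin_meta["size"].sum()),
            cells_pruned=experiment.n_cells - int(binned.bin_meta["size"].sum()),
        )

        # --- stage: fit --------------------------------------------------
        t0 = time.perf_counter()
        wf = WorkflowConfig(seed=cfg["seed"], **cfg["fit"])
        results = run_workflow(binned, wf)
        results_path = outdir / "results.tsv"
        write_results(results, results_path)
        n_selected = int((results["classification"] != "not significant").sum())
        _register(
            manifest, "fit", t0, [results_path],
            genes_screened=int((results["adjusted_p"] <= wf.alpha_screen).sum()),
            genes_selected=n_selected,
        )

        # --- stage: cluster ----------------------------------------------
        n_clusters = cfg["cluster"]["n_clusters"]
        if n_clusters and n_selected >= n_clusters:
            t0 = time.perf_counter()
            labels, trends = cluster_trends(results, binned, n_clusters, wf)
            labels.rename_axis("gene").reset_index().to_csv(
                outdir / "clusters.tsv", sep="\t", index=False
            )
            trends.to_csv(outdir / "trends.tsv", sep="\t", index=False,
                          float_format="%.17g")
            _register(manifest, "cluster", t0,
                      [outdir / "clusters.tsv", outdir / "trends.tsv"],
                      n_clusters=int(labels.nunique()))

        # --- stage: evaluate ----------------------------------------------
        if truth is not None and cfg["evaluate"]["enabled"]:
            t0 = time.perf_counter()
            truth_vec = truth.de_label.loc[results["gene"]].to_numpy()
            alpha = cfg["evaluate"]["alpha"]
            calls = ev.classify(results, alpha=alpha,
                                rsq_threshold=wf.rsq_threshold)
            metrics = ev.confusion_metrics(calls, truth_vec)
            roc = ev.roc_over_rsq(results, truth_vec, alpha=alpha)
            ranking = ev.export_ranking(results, wf.rsq_threshold, alpha=alpha)
            pd.DataFrame([metrics]).to_csv(outdir / "metrics.tsv", sep="\t",
                                           index=False, float_format="%.17g")
            roc.to_csv(outdir / "roc.tsv", sep="\t", index=False,
                       float_format="%.17g")
            ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False,
                           float_format="%.17g")
            _register(manifest, "evaluate", t0,
                      [outdir / "metrics.tsv", outdir / "roc.tsv",
                       outdir / "ranking.tsv"],
                      **{k: metrics[k] for k in ("TP", "FP", "TN", "FN")})
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
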