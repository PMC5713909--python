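"""End-to-end pipeline: simulate/load -> describe -> fit -> RR -> krige.

Driven by a YAML/JSON config; every stage writes its artifacts into the run
directory and a JSON manifest records versions, the seed, a hash of the
config and per-outcome record accounting.  Two runs with the same config
and seed produce identical manifests.  One county per run; multiple
outcomes are looped through the full stage chain with derived sub-seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import __version__, io
from .descriptives import weighted_chisq, weighted_crosstab
from .graph import build_graph
from .kriging import krige_rr, plot_surface, spatial_rr
from .model import ALL_COVARIATES, ModelConfig, build_design, fit_star, summarize_fixed
from .recovery import run_recovery
from .simulate import SimulationConfig, simulate_county

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outcomes": ["cigarette"],
    "data": {"source": "synthetic", "simulation": {}},
    "exclusions": {"drop_counties": []},
    "graph": {"method": "delaunay", "k": 4},
    "model": {},
    "kriging": {
        "model": "exponential",
        "n_bins": 10,
        "max_dist_frac": 0.5,
        "grid_res": 100,
        "threshold": 1.0,
    },
    "plot": False,
}


def load_config(path_or_dict) -> dict:
    """Merge a YAML/JSON config (path or dict) over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        text = Path(path_or_dict).read_text()
        import yaml

        user = yaml.safe_load(text) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _sub_seed(seed: int, idx: int) -> int:
    return (seed * 1009 + 17 * idx + 1) % 2**31


class PipelineError(RuntimeError):
    def __init__(self, stage: str, outcome: str, cause: Exception):
        super().__init__(f"stage {stage!r} (outcome {outcome!r}) failed: {cause}")
        self.stage, self.outcome = stage, outcome


def run_pipeline(config, outdir=None) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    cfg = load_config(config)
    out = Path(outdir if outdir is not None else cfg.get("outdir", "trostar_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    manifest: dict = {
        "package": "trostar",
        "package_version": __version__,
        "versions": _lib_versions(),
        "seed": seed,
        "config_hash": config_hash(cfg),
        "outcomes": {},
    }

    for idx, outcome in enumerate(cfg["outcomes"]):
        manifest["outcomes"][outcome] = _run_outcome(
            cfg, outcome, _sub_seed(seed, idx), out
        )

    if cfg.get("recovery"):
        rcfg = cfg["recovery"]
        from .recovery import harness_sim_config

        sim_cfg = harness_sim_config()
        if rcfg.get("simulation"):
            sim_cfg = replace(sim_cfg, **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in rcfg["simulation"].items()
            })
        model_cfg = ModelConfig(**rcfg.get("model", {})) if rcfg.get("model") else None
        summary = run_recovery(
            n_replicates=int(rcfg.get("n_replicates", 20)),
            base_seed=seed,
            sim_config=sim_cfg,
            model_config=model_cfg,
        )
        rec_path = out / "recovery_summary.json"
        rec_path.write_text(json.dumps(summary.as_dict(), indent=1, sort_keys=True))
        manifest["recovery"] = {
            "artifact": rec_path.name,
            "coverage_beta": summary.coverage_beta,
            "mean_f_corr_tro1": summary.mean_f_corr_tro1,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _lib_versions() -> dict:
    import pandas
    import scipy

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__}


def _run_outcome(cfg: dict, outcome: str, seed: int, out: Path) -> dict:
    artifacts: list[str] = []
    entry: dict = {"seed": seed, "artifacts": artifacts}

    def _art(p: Path) -> Path:
        artifacts.append(p.name)
        return p

    # ---- stage: data
    stage = "data"
    try:
        if cfg["data"]["source"] == "synthetic":
            sim = SimulationConfig(**cfg["data"].get("simulation", {}))
            sim = replace(sim, seed=seed)
            county = simulate_county(sim)
            students, schools = county.students, county.schools
            prefix = out / outcome
            prefix.mkdir(exist_ok=True)
            for p in county.write(prefix).values():
                artifacts.append(str(Path(p).relative_to(out)))
        elif cfg["data"]["source"] == "files":
            students = io.load_students(cfg["data"]["students"])
            schools = io.load_schools(cfg["data"]["schools"])
            county = None
        else:
            raise ValueError(f"unknown data source {cfg['data']['source']!r}")
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, outcome, e) from e

    # ---- stage: exclusions
    stage = "exclusions"
    try:
        retained, report = io.apply_exclusions(
            students, drop_counties=cfg["exclusions"].get("drop_counties", ())
        )
        entry.update(
            n_input=report.n_input,
            n_excluded_missing=report.n_excluded_missing,
            n_excluded_county=report.n_excluded_county,
            n_retained=report.n_retained,
        )
    except Exception as e:
        raise PipelineError(stage, outcome, e) from e

    # ---- stage: describe
    stage = "describe"
    try:
        model_cfg = ModelConfig(**cfg.get("model", {}))
        stats = {}
        for cov in model_cfg.covariate_set:
            tab = weighted_crosstab(retained, cov)
            tab.to_frame().to_csv(_art(out / f"{outcome}_crosstab_{cov}.csv"))
            s, df, p = weighted_chisq(tab)
            stats[cov] = {"statistic": s, "df": df, "p": p}
        (_art(out / f"{outcome}_descriptives.json")).write_text(
            json.dumps(stats, indent=1, sort_keys=True)
        )
    except Exception as e:
        raise PipelineError(stage, outcome, e) from e

    # ---- stage: fit
    stage = "fit"
    try:
        graph = build_graph(
            schools, method=cfg["graph"]["method"], k=int(cfg["graph"].get("k", 4))
        )
        graph.to_edge_csv(_art(out / f"{outcome}_graph_edges.csv"))
        model_cfg = replace(model_cfg, seed=seed)
        design = build_design(retained, schools, model_cfg)
        draws = fit_star(design, graph, model_cfg)
        io.write_posterior(draws, _art(out / f"{outcome}_posterior.csv.gz"))
        (_art(out / f"{outcome}_summary.json")).write_text(
            json.dumps(io.summaries_json(summarize_fixed(draws)), indent=1)
        )
        entry["n_schools"] = len(schools)
        entry["n_draws"] = draws.n_draws
        entry["max_rhat"] = draws.accept_info.get("max_rhat")
    except Exception as e:
        raise PipelineError(stage, outcome, e) from e

    # ---- stage: rr + krige
    stage = "krige"
    try:
        rr = spatial_rr(draws, schools)
        io.write_rr(rr, _art(out / f"{outcome}_rr.csv"))
        k = cfg["kriging"]
        vg, surface = krige_rr(
            rr,
            model=k.get("model", "exponential"),
            n_bins=int(k.get("n_bins", 10)),
            max_dist_frac=float(k.get("max_dist_frac", 0.5)),
            grid_res=int(k.get("grid_res", 100)),
            threshold=float(k.get("threshold", 1.0)),
        )
        io.write_surface_csv(surface, _art(out / f"{outcome}_surface.csv"))
        (_art(out / f"{outcome}_surface.geojson")).write_text(
            json.dumps(io.surface_geojson(surface))
        )
        entry["variogram"] = {
            "model": vg.model, "nugget": vg.nugget,
            "partial_sill": vg.partial_sill, "range_param": vg.range_param,
        }
        entry["n_hotspot_cells"] = int(surface.hotspot.sum())
        if cfg.get("plot"):
            plot_surface(
                surface, schools, path=_art(out / f"{outcome}_surface.png"),
                title=f"kriged RR ({outcome})",
            )
    except Exception as e:
        raise PipelineError(stage, outcome, e) from e

    return entry
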