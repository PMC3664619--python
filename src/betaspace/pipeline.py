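"""End-to-end orchestration of the beta-diversity analysis.

Stages: partition the incidence matrix into the three beta components;
assemble the environmental predictor matrix; distance-decay/Mantel tests for
each component; forward selection of environmental predictors and AICc
selection of a spatial eigenvector model for the replacement and richness
components; and two-set variation partitioning of each.  The report is a
plain dict (JSON-serialisable) with a flat ``metrics`` map for the headline
numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beta_partition import beta_matrices, summarize_beta
from .cap_ordination import forward_select
from .core_data import IncidenceMatrix, SiteTable, align, read_incidence, read_sites
from .distance_decay import geo_distance, mantel
from .env_features import build_env_matrix
from .spatial_mem import select_mem_model
from .varpart import varpart2

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "run_from_files"]

# fixed per-stage seed offsets so stages reproduce when run standalone
STAGE_SEED_OFFSET = {"mantel": 101, "select_env": 211, "varpart": 307}


@dataclass
class RunConfig:
    alpha: float = 0.1
    n_perm_selection: int = 9999
    n_perm_mantel: int = 1000
    seed: int = 0
    out_dir: Path | None = None
    climate_columns: list[str] | None = None

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if min(self.n_perm_selection, self.n_perm_mantel) < 99:
            raise ValueError("permutation counts must be >= 99")


def _stage_seed(cfg: RunConfig, stage: str, k: int = 0) -> int:
    return (cfg.seed + STAGE_SEED_OFFSET[stage] + 10007 * k) % (2**31)


def run_all(inc: IncidenceMatrix, sites: SiteTable, cfg: RunConfig) -> dict:
    """Run the full analysis and return the structured report."""
    inc, sites = align(inc, sites)
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "n_sites": inc.n_sites, "n_species": inc.n_species,
                    "stages": {}, "metrics": {}}
    metrics = report["metrics"]

    logger.info("stage: beta partition")
    bt = beta_matrices(inc)
    summary = summarize_beta(bt)
    report["stages"]["beta_partition"] = summary
    metrics["mean_richness"] = float(inc.richness().mean())
    for comp, st in summary.items():
        metrics[f"mean_{comp}"] = st["mean"]
        metrics[f"sd_{comp}"] = st["sd"]

    logger.info("stage: env_features")
    try:
        env = build_env_matrix(sites.env, cfg.climate_columns)
    except Exception as e:
        raise RuntimeError(f"stage 'env_features' failed: {e}") from e
    report["stages"]["env_features"] = {"columns": list(env.columns)}

    logger.info("stage: distance decay")
    gd = geo_distance(sites)
    decay = {}
    comps = {"beta_total": bt.beta_total, "beta_repl": bt.beta_repl,
             "beta_rich": bt.beta_rich}
    for k, (name, dm) in enumerate(comps.items()):
        res = mantel(dm, gd, n_perm=cfg.n_perm_mantel,
                     seed=_stage_seed(cfg, "mantel", k))
        decay[name] = {"intercept": res.intercept, "slope": res.slope,
                       "mantel_r": res.mantel_r, "p": res.perm_p}
        metrics[f"mantel_r_{name.removeprefix('beta_')}"] = res.mantel_r
        metrics[f"decay_slope_{name.removeprefix('beta_')}"] = res.slope
    report["stages"]["distance_decay"] = decay

    for k, name in enumerate(("beta_repl", "beta_rich")):
        short = name.removeprefix("beta_")
        dm = comps[name]
        logger.info("stage: forward selection (%s)", name)
        sel = forward_select(dm, env, alpha=cfg.alpha,
                             n_perm=cfg.n_perm_selection,
                             seed=_stage_seed(cfg, "select_env", k))
        report["stages"][f"env_selection_{short}"] = {
            "selected": sel.selected, "reason": sel.stopping_reason,
            "global_adj_r2": sel.global_fit.adj_r2,
            "global_p": sel.global_fit.perm_p,
        }
        logger.info("stage: MEM selection (%s)", name)
        mem = select_mem_model(dm, sites)
        report["stages"][f"mem_selection_{short}"] = {
            "graph_type": mem.graph_type, "weight_kind": mem.weight_kind,
            "retained": [int(i) for i in mem.retained],
            "aicc": mem.aicc, "r2": mem.r2,
        }
        logger.info("stage: variation partitioning (%s)", name)
        X_env = env[sel.variables] if sel.variables else None
        X_spa = (pd.DataFrame(mem.basis.eigenvectors[:, mem.retained],
                              index=sites.site_ids,
                              columns=[f"MEM{i + 1}" for i in mem.retained])
                 if mem.retained else None)
        if X_env is None and X_spa is None:
            report["stages"][f"varpart_{short}"] = None
            continue
        vp = varpart2(dm, X_env, X_spa, n_perm=0,
                      seed=_stage_seed(cfg, "varpart", k))
        report["stages"][f"varpart_{short}"] = vp.as_dict()
        metrics[f"pure_env_{short}"] = vp.pure_env
        metrics[f"shared_{short}"] = vp.shared
        metrics[f"pure_spatial_{short}"] = vp.pure_spatial
        metrics[f"unexplained_{short}"] = vp.unexplained
        metrics[f"adj_r2_both_{short}"] = vp.adj_r2_both

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bt.beta_total.write_csv(out / "beta_total.csv")
        bt.beta_repl.write_csv(out / "beta_repl.csv")
        bt.beta_rich.write_csv(out / "beta_rich.csv")
        env.to_csv(out / "env_matrix.csv", index_label="site")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def run_from_files(incidence_path, sites_path, cfg: RunConfig) -> dict:
    try:
        inc = read_incidence(incidence_path)
    except FileNotFoundError as e:
        raise RuntimeError(f"stage 'read_incidence' failed: {e}") from e
    try:
        sites = read_sites(sites_path)
    except FileNotFoundError as e:
        raise RuntimeError(f"stage 'env_features' failed: missing site table: {e}") from e
    return run_all(inc, sites, cfg)
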