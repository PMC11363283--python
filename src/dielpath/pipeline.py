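"""Pipeline orchestration: config, staged execution, provenance.

A run executes simulate/ingest -> rhythm -> stm -> llmx -> ccm as configured,
writes per-stage CSV/JSON outputs, and records a provenance JSON holding
every seed and a hash of the resolved config, sufficient to reproduce every
number in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ccm import ccm_test
from .dataio import read_env_table, read_timeseries_table, write_env_table, write_timeseries_table, aggregate_env
from .exceptions import DielPathError
from .llmx import LocalLevelExogModel, upstream_regressor
from .rhythm import diel_fold_change, jtk_cycle, rhythm_table
from .stm import SmoothTrendModel
from .synthetic_data import CascadeParams, two_season_scenario

logger = logging.getLogger(__name__)

_REQUIRED = ("seed", "out_dir")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int
    out_dir: str
    input_csv: str | None = None           # None -> simulate the bundled scenario
    scenario: str = "two-season"
    n_hours: float = 48.0
    genes: tuple[str, str, str] = ("CLOCK", "SIG", "PSB")
    stages: tuple[str, ...] = ("simulate", "rhythm", "stm", "llmx", "ccm")
    n_chains: int = 4
    n_warmup: int = 1000
    n_iter: int = 1000
    trend_order: int = 2
    rhat_threshold: float = 1.1
    force_significance: bool = False
    tp_grid: tuple[int, ...] = tuple(range(-8, 3))
    e_range: tuple[int, ...] = tuple(range(1, 11))
    n_surrogates: int = 1000
    samples_per_day: int = 12

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        missing = [k for k in _REQUIRED if k not in raw]
        if missing:
            raise DielPathError(f"config missing required fields: {missing}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DielPathError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("genes", "stages", "tp_grid", "e_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("genes", "stages", "tp_grid", "e_range"):
            d[name] = list(d[name])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _spawn_seeds(seed: int, names: list[str]) -> dict[str, int]:
    """One deterministic child seed per stage from the run seed."""
    ss = np.random.SeedSequence(seed)
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the report dict (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed, ["simulate", "rhythm", "stm", "llmx", "ccm"])
    report: dict = {"stages": {}, "seed": config.seed}
    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
    }

    try:
        # ---- simulate / ingest ------------------------------------------
        gC, gS, gP = config.genes
        if config.input_csv is None:
            scen = two_season_scenario(seed=seeds["simulate"], n_hours=config.n_hours)
            series = []
            envs = scen.pop("_env")
            for prof, d in scen.items():
                for g, s in d.items():
                    series.append(s)
            if "simulate" in config.stages:
                write_timeseries_table(series, out / "simulated_data.csv")
                for prof, env in envs.items():
                    write_env_table(env, out / f"env_{prof}.csv")
            by_key = {(s.gene_id, s.condition): s for s in series}
            conditions = sorted({s.condition for s in series})
            env_by_cond = envs
        else:
            series = read_timeseries_table(config.input_csv)
            by_key = {(s.gene_id, s.condition): s for s in series}
            conditions = sorted({s.condition for s in series})
            env_by_cond = {}

        # ---- rhythm ------------------------------------------------------
        if "rhythm" in config.stages:
            results = [jtk_cycle(s) for s in series]
            tab = rhythm_table(results)
            tab["condition"] = [s.condition for s in series]
            tab["fold_change"] = [diel_fold_change(s) for s in series]
            tab.to_csv(out / "rhythm.csv", index=False)
            report["stages"]["rhythm"] = {
                "n_rhythmic": int(tab["rhythmic"].sum()),
                "n_genes": len(tab),
            }

        # ---- stm ---------------------------------------------------------
        if "stm" in config.stages:
            stm_report = {}
            for g in config.genes:
                per_cond = [by_key[(g, c)] for c in conditions if (g, c) in by_key]
                if len(per_cond) < 2:
                    continue
                model = SmoothTrendModel(
                    trend_order=config.trend_order,
                    n_chains=config.n_chains,
                    n_warmup=config.n_warmup,
                    n_iter=config.n_iter,
                    seed=seeds["stm"],
                    rhat_threshold=config.rhat_threshold,
                ).fit(per_cond)
                if not model.draws_.converged(config.rhat_threshold) and not config.force_significance:
                    raise DielPathError(
                        f"stage stm: Rhat above threshold for {g}: {model.draws_.max_rhat:.3f}"
                    )
                model.summary_.to_csv(out / f"stm_{g}_summary.csv", index=False)
                windows = model.difference_significance(force=config.force_significance)
                diag = model.residual_diagnostics()
                diag["fitted_vs_residual"].to_csv(out / f"stm_{g}_residuals.csv", index=False)
                diag["qq"].to_csv(out / f"stm_{g}_qq.csv", index=False)
                stm_report[g] = {
                    "fit_correlation": model.fit_correlation(),
                    "significant_windows": windows,
                    "max_rhat": model.draws_.max_rhat,
                }
            with open(out / "stm_windows.json", "w") as fh:
                json.dump(stm_report, fh, indent=2, default=float)
            report["stages"]["stm"] = stm_report

        # ---- llmx --------------------------------------------------------
        if "llmx" in config.stages and env_by_cond:
            llmx_report = {}
            for gene, upstream in ((gS, gC), (gP, gS)):
                resp = [by_key[(gene, c)] for c in conditions if (gene, c) in by_key]
                grids = [s.grid for s in resp]
                T = len(grids[0])
                temp = np.array(
                    [aggregate_env(env_by_cond[c], g, 60.0)["temperature"].to_numpy()
                     for c, g in zip(conditions, grids)]
                )
                irr = np.array(
                    [aggregate_env(env_by_cond[c], g, 60.0)["irradiance"].to_numpy()
                     for c, g in zip(conditions, grids)]
                )
                up = np.array(
                    [upstream_regressor(by_key[(upstream, c)]) for c in conditions]
                )
                model = LocalLevelExogModel(
                    n_chains=config.n_chains,
                    n_warmup=config.n_warmup,
                    n_iter=config.n_iter,
                    seed=seeds["llmx"],
                    rhat_threshold=config.rhat_threshold,
                ).fit(resp, {"temperature": temp, "irradiance": irr, "upstream": up})
                coef = model.coefficient_summary()
                coef.to_csv(out / f"llmx_{gene}_coefficients.csv", index=False)
                llmx_report[gene] = {
                    "fit_correlation": model.fit_correlation(),
                    "coefficients": coef.to_dict(orient="records"),
                    "max_rhat": model.draws_.max_rhat,
                }
            report["stages"]["llmx"] = llmx_report

        # ---- ccm ---------------------------------------------------------
        if "ccm" in config.stages:
            ccm_report = {}
            for cause, effect in ((gC, gS), (gS, gP)):
                eff = [by_key[(effect, c)] for c in conditions if (effect, c) in by_key]
                cau = [by_key[(cause, c)] for c in conditions if (cause, c) in by_key]
                res = ccm_test(
                    eff,
                    cau,
                    tp_grid=config.tp_grid,
                    E_range=config.e_range,
                    n_surrogates=config.n_surrogates,
                    samples_per_day=config.samples_per_day,
                    seed=seeds["ccm"],
                )
                pd.DataFrame(
                    {
                        "tp": list(res.tp_grid),
                        "rho": [res.rho_full[tp] for tp in res.tp_grid],
                        "surrogate_lo": [res.surrogate_lo[tp] for tp in res.tp_grid],
                        "surrogate_hi": [res.surrogate_hi[tp] for tp in res.tp_grid],
                        "significant": [res.significant[tp] for tp in res.tp_grid],
                        "convergent": [res.convergent[tp] for tp in res.tp_grid],
                    }
                ).to_csv(out / f"ccm_{cause}_to_{effect}.csv", index=False)
                ccm_report[f"{cause}->{effect}"] = {
                    "E": res.E,
                    "significant_tp": res.significant_tps,
                    "convergent_tp": [tp for tp in res.tp_grid if res.convergent[tp]],
                }
            report["stages"]["ccm"] = ccm_report
    except DielPathError:
        with open(out / "report_partial.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        raise

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=float)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
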