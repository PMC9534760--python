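"""End-to-end orchestration: climate -> vulnerability -> F_ST -> P_ST ->
critical ratio -> Mantel -> inferential battery -> plasticity.

Stages communicate only through serialized outputs in the run directory,
so any stage can be re-run from intermediates with identical downstream
results. Stages whose inputs are absent are skipped and recorded in the
manifest, never silently dropped; a stage error aborts the run with the
manifest marking what completed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import divergence, microclimate, popgen, stats, thermal

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = [
    "climate",
    "vulnerability",
    "fst",
    "pst",
    "critical_ratio",
    "mantel",
    "stats",
    "plasticity",
]


@dataclass
class RunConfig:
    """Validated inputs and knobs for one pipeline run.

    Paths may be omitted (None): stages needing them are skipped. All
    seeds are explicit — there is no wall-clock seeding anywhere.
    """

    out_dir: str | Path
    genotypes: str | Path | None = None
    traits: str | Path | None = None
    acclimation: str | Path | None = None
    loggers_dir: str | Path | None = None
    macro: str | Path | None = None
    phenology: str | Path | None = None
    elevations: str | Path | None = None
    logger_alias: dict[str, str] = field(default_factory=dict)
    n_boot_fst: int = 10_000
    n_boot_pst: int = 2000
    n_permutations: int = 999
    ratio: float = 1.0  # c/h2 for pairwise matrices (null hypothesis c = h2)
    ratio_grid: list[float] | None = None
    seed: int = 1
    min_coverage_hours: float = 20.0
    min_month_days: int = 20
    min_macro_days: int = 15

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("genotypes", "traits", "acclimation", "loggers_dir",
                     "macro", "phenology", "elevations"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def _seeds(seed: int) -> dict[str, int]:
    """Fixed per-stage child seeds derived from the run seed (all < 2^31)."""
    children = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    return {
        "fst": int(children[0]),
        "pst": int(children[1]),
        "mantel": int(children[2]),
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage whose inputs are present; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, status: str, outputs: list[str], t0: float, note: str = "") -> None:
        manifest["stages"][stage] = {
            "status": status,
            "outputs": outputs,
            "seconds": round(time.perf_counter() - t0, 3),
            **({"note": note} if note else {}),
        }
        manifest["outputs"].extend(outputs)
        logger.info("stage %-14s %s (%d output(s))", stage, status, len(outputs))

    def finish() -> dict[str, Any]:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    climate_df: pd.DataFrame | None = None
    traits_df: pd.DataFrame | None = None
    fst_res: popgen.FstResult | None = None
    pst_grids: dict[str, divergence.PstGridResult] = {}
    vuln_df: pd.DataFrame | None = None

    if config.traits is not None:
        traits_df = pd.read_csv(config.traits)

    try:
        # ---- climate -----------------------------------------------------
        t0 = time.perf_counter()
        if config.loggers_dir and config.macro and config.phenology:
            loggers = {
                p.stem: microclimate.read_logger_csv(p)
                for p in sorted(Path(config.loggers_dir).glob("*.csv"))
            }
            macros = microclimate.read_macro_csv(config.macro)
            windows = microclimate.read_phenology_csv(config.phenology)
            climate_df = microclimate.summarize_populations(
                loggers, macros, windows,
                alias=config.logger_alias,
                min_coverage_hours=config.min_coverage_hours,
                min_month_days=config.min_month_days,
                min_macro_days=config.min_macro_days,
            )
            path = out / "climate.csv"
            climate_df.to_csv(path, index=False)
            record("climate", "ok", [path.name], t0)
        else:
            record("climate", "skipped", [], t0, "logger/macro/phenology inputs missing")

        # ---- vulnerability ----------------------------------------------
        t0 = time.perf_counter()
        if climate_df is not None and traits_df is not None and {
            "CTmax", "CTmin"
        } <= set(traits_df["trait"].unique()):
            tols = thermal.tolerance_summaries(traits_df)
            vuln_df = thermal.vulnerability_table(tols, climate_df)
            path = out / "vulnerability.csv"
            vuln_df.to_csv(path, index=False)
            record("vulnerability", "ok", [path.name], t0)
        else:
            record("vulnerability", "skipped", [], t0,
                   "needs climate plus CTmax and CTmin trait rows")

        # ---- fst ---------------------------------------------------------
        t0 = time.perf_counter()
        if config.genotypes is not None:
            ds = popgen.read_genepop(config.genotypes)
            fst_res = popgen.fst_analysis(ds, n_boot=config.n_boot_fst, seed=seeds["fst"])
            jpath = out / "fst.json"
            fst_res.to_json(jpath)
            cpath = out / "fst_per_locus.csv"
            fst_res.per_locus_frame().to_csv(cpath, index=False)
            record("fst", "ok", [jpath.name, cpath.name], t0)
        else:
            record("fst", "skipped", [], t0, "no genotype file")

        # ---- pst ----------------------------------------------------------
        t0 = time.perf_counter()
        if traits_df is not None:
            outputs = []
            for trait in sorted(traits_df["trait"].unique()):
                grid = divergence.pst_bootstrap_ci(
                    traits_df, trait=trait,
                    ratios=config.ratio_grid,
                    n_boot=config.n_boot_pst, seed=seeds["pst"],
                )
                pst_grids[trait] = grid
                path = out / f"pst_{trait}.csv"
                grid.frame().to_csv(path, index=False)
                outputs.append(path.name)
            record("pst", "ok", outputs, t0)
        else:
            record("pst", "skipped", [], t0, "no trait table")

        # ---- critical ratio ----------------------------------------------
        t0 = time.perf_counter()
        if pst_grids and fst_res is not None:
            summary = {}
            for trait, grid in pst_grids.items():
                crit = divergence.critical_ch2_ratio(grid, fst_upper=fst_res.ci_high)
                vc = grid.components
                summary[trait] = {
                    "sigma_b2": vc.sigma_b2,
                    "sigma_w2": vc.sigma_w2,
                    "pst_at_ratio_1": divergence.compute_pst(vc, 1.0),
                    "fst_upper": fst_res.ci_high,
                    "critical_ratio": crit,
                }
            path = out / "critical_ratio.json"
            path.write_text(json.dumps(summary, indent=2))
            record("critical_ratio", "ok", [path.name], t0)
        else:
            record("critical_ratio", "skipped", [], t0, "needs pst and fst stages")

        # ---- mantel --------------------------------------------------------
        t0 = time.perf_counter()
        if traits_df is not None and fst_res is not None:
            results = {}
            for trait in sorted(traits_df["trait"].unique()):
                pmat = divergence.pairwise_pst_matrix(
                    traits_df, trait=trait, ratio=config.ratio
                )
                shared = [p for p in pmat.index if p in fst_res.pairwise.index]
                if len(shared) < 3:
                    continue
                res = divergence.mantel_test(
                    pmat.loc[shared, shared],
                    fst_res.pairwise.loc[shared, shared],
                    n_permutations=config.n_permutations,
                    seed=seeds["mantel"],
                )
                results[trait] = {
                    "r": res.r, "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "n_populations": len(shared),
                }
            path = out / "mantel.json"
            path.write_text(json.dumps(results, indent=2))
            record("mantel", "ok", [path.name], t0)
        else:
            record("mantel", "skipped", [], t0, "needs traits and fst stages")

        # ---- stats ----------------------------------------------------------
        t0 = time.perf_counter()
        if vuln_df is not None:
            payload: dict[str, Any] = {}
            for hot, cold in (("WT", "wt"), ("CT", "ct")):
                t_res = stats.paired_t(vuln_df[hot], vuln_df[cold])
                ks_res = stats.ks_two_sample(vuln_df[hot], vuln_df[cold])
                payload[f"{hot}_vs_{cold}"] = {
                    "paired_t": {"t": t_res.statistic, "df": t_res.df, "p": t_res.p_value},
                    "ks": {"D": ks_res.statistic, "p": ks_res.p_value},
                }
            if config.elevations is not None:
                elev = pd.read_csv(config.elevations).set_index("population")["elevation_m"]
                merged = vuln_df.set_index("population").join(elev, how="inner")
                for col in ("WT", "wt", "CT", "ct"):
                    for degree in (1, 2):
                        fit = stats.ols_fit(merged[col], merged["elevation_m"], degree=degree)
                        payload[f"{col}~elevation_deg{degree}"] = {
                            "r2": fit.r2, "f": fit.f_stat, "df": fit.df, "p": fit.p_value,
                        }
            path = out / "stats.json"
            path.write_text(json.dumps(payload, indent=2))
            record("stats", "ok", [path.name], t0)
        else:
            record("stats", "skipped", [], t0, "needs the vulnerability stage")

        # ---- plasticity ------------------------------------------------------
        t0 = time.perf_counter()
        if config.acclimation is not None:
            acc = pd.read_csv(config.acclimation)
            if "censored" not in acc.columns:
                acc["censored"] = False
            rows = []
            for trait in sorted(acc["trait"].unique()):
                sub = acc[acc["trait"] == trait]
                if trait == "CTmin":
                    sub = thermal.censor_ctmin_trials(sub)
                for pop, grp in sub.groupby("population"):
                    means = grp.groupby("acclimation_c")["value_c"].mean().to_dict()
                    high, low = thermal.PLASTICITY_PAIRS.get(trait, (None, None))
                    if high is None or high not in means or low not in means:
                        continue
                    rows.append(
                        {
                            "population": pop,
                            "trait": trait,
                            "plasticity_range": thermal.plasticity_range(means, trait),
                            "arr": thermal.arr(means[high], means[low], high - low),
                        }
                    )
            path = out / "plasticity.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            record("plasticity", "ok", [path.name], t0)
        else:
            record("plasticity", "skipped", [], t0, "no acclimation table")

    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        finish()
        raise

    return finish()
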