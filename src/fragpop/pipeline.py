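"""Configuration-driven orchestration of the full analysis.

A single YAML config names the inputs (genotype table, capture and trap
files, cover raster) and all stage parameters; :func:`run` executes the
requested stages in dependency order, isolates failures per stage, and
writes the four result tables (genetics summary, per-sex model
selection, realized estimates, fragmentation metrics) plus the FCA
coordinate table into the output directory.  The report layer only
formats module outputs; it computes nothing itself.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fragpop import __version__
from fragpop import bottleneck_fca, diversity, effective_size, landscape, scr
from fragpop.core_data import (
    build_mask,
    read_detections,
    read_esri_ascii,
    read_genotype_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotypes: str | None = None
    captures: str | None = None
    traps: str | None = None
    raster: str | None = None
    output_dir: str = "fragpop_out"
    # stage toggles
    do_popgen: bool = True
    do_ne: bool = True
    do_bottleneck: bool = True
    do_fca: bool = True
    do_scr: bool = True
    do_frag: bool = True
    # parameters (defaults follow the bear study design)
    buffer: float = 12.0
    spacing: float = 1.0
    window_radius: float = 3.2
    maf: float = 0.05
    alpha: float = 4.0
    max_age: float = 24.0
    tpm_p_multistep: float = 0.30
    bottleneck_reps: int = 10000
    n_boot: int = 1000
    hwe_permutations: int = 1000
    models: list[dict] = field(
        default_factory=lambda: [{"density": "~1", "g0": "~bk"}]
    )
    sexes: list[str] = field(default_factory=lambda: ["F", "M"])
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            logger.warning("ignoring unknown config keys: %s", sorted(unknown))
        return cls(**known)


def validate_config(config: RunConfig) -> list[str]:
    """Human-readable config problems; never raises."""
    problems: list[str] = []
    for name in ("genotypes", "captures", "traps", "raster"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name} file does not exist: {p}")
    if not 0 <= config.maf < 0.5:
        problems.append("maf must be in [0, 0.5)")
    if config.alpha >= config.max_age:
        problems.append(
            f"alpha ({config.alpha}) must be below max_age ({config.max_age})"
        )
    if config.alpha < 1:
        problems.append("alpha must be >= 1 year")
    if config.buffer <= 0 or config.spacing <= 0:
        problems.append("buffer and spacing must be positive")
    if not 0 <= config.tpm_p_multistep <= 1:
        problems.append("tpm_p_multistep must be in [0, 1]")
    if config.bottleneck_reps < 1 or config.n_boot < 1:
        problems.append("replicate counts must be >= 1")
    if not isinstance(config.seed, (int, np.integer)):
        problems.append("seed must be an integer")
    return problems


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    log: dict = field(default_factory=dict)

    def ok(self, stage: str) -> bool:
        return stage not in self.failures and stage not in self.skipped


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: getattr(config, k) for k in config.__dataclass_fields__},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run(config: RunConfig) -> RunReport:
    """Execute the requested stages; failures are isolated per stage."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    report = RunReport()
    t0 = time.time()
    report.log = {
        "fragpop_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "timings": {},
    }
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str, enabled: bool, deps: list[str], func) -> None:
        if not enabled:
            report.skipped.append(name)
            return
        for d in deps:
            if d in report.failures or d in report.skipped:
                report.skipped.append(name)
                logger.warning("stage %s skipped (dependency %s unavailable)", name, d)
                return
        t = time.time()
        try:
            func()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.exception("stage %s failed", name)
            report.failures[name] = f"{type(exc).__name__}: {exc}"
        finally:
            report.log["timings"][name] = round(time.time() - t, 3)

    state: dict = {}

    def load_genotypes():
        if config.genotypes is None:
            raise FileNotFoundError("no genotype table configured")
        state["gt"] = read_genotype_table(config.genotypes)

    def popgen():
        gt = state["gt"]
        table = diversity.diversity_report(
            gt, n_boot=config.n_boot, seed=config.seed
        )
        report.tables["genetics"] = table
        table.to_csv(out / "genetics_table.csv", index=False)

    def ne():
        res = effective_size.effective_size_report(
            state["gt"], maf=config.maf, alpha=config.alpha, max_age=config.max_age
        )
        rows = []
        for per, r in res.items():
            rows.append(
                {
                    "period": per,
                    "raw_Nb": r.raw_nb.point, "raw_Nb_lo": r.raw_nb.lower,
                    "raw_Nb_hi": r.raw_nb.upper,
                    "adj_Nb": r.adjusted_nb.point, "adj_Nb_lo": r.adjusted_nb.lower,
                    "adj_Nb_hi": r.adjusted_nb.upper,
                    "adj_Ne": r.adjusted_ne.point, "adj_Ne_lo": r.adjusted_ne.lower,
                    "adj_Ne_hi": r.adjusted_ne.upper,
                    "r2_mean": r.r2_mean, "r2_drift": r.r2_drift,
                    "n_locus_pairs": r.n_locus_pairs,
                }
            )
        df = pd.DataFrame(rows)
        report.tables["effective_size"] = df
        df.to_csv(out / "effective_size.csv", index=False)

    def bottleneck():
        gt = state["gt"]
        rows = []
        for per in gt.periods():
            for model in ("SMM", "TPM"):
                res = bottleneck_fca.bottleneck_test(
                    gt.for_period(per), model=model,
                    p_multistep=config.tpm_p_multistep,
                    reps=config.bottleneck_reps, seed=config.seed,
                )
                rows.append(
                    {
                        "period": per, "model": model,
                        "p_multistep": res.p_multistep,
                        "wilcoxon_p_excess": res.wilcoxon_p_excess,
                    }
                )
        df = pd.DataFrame(rows)
        report.tables["bottleneck"] = df
        df.to_csv(out / "bottleneck.csv", index=False)

    def fca_stage():
        gt = state["gt"]
        frames = []
        for per in gt.periods():
            res, df = bottleneck_fca.fca_report(gt.for_period(per))
            df.insert(0, "period", per)
            df["total_inertia"] = res.total_inertia
            df["axes12_share"] = float(res.axis_shares[: 2].sum()) if len(
                res.axis_shares
            ) else np.nan
            frames.append(df)
            bottleneck_fca.plot_fca(res, out / f"fca_{per}.svg")
        df = pd.concat(frames, ignore_index=True)
        report.tables["fca"] = df
        df.to_csv(out / "fca_coordinates.csv", index=False)

    def load_raster():
        if config.raster is None:
            raise FileNotFoundError("no raster configured")
        state["raster"] = read_esri_ascii(config.raster)

    def frag():
        metrics = landscape.frag_metrics(state["raster"])
        df = metrics.to_frame()
        report.tables["fragmentation"] = df
        df.to_csv(out / "fragmentation.csv", index=False)

    def scr_stage():
        if config.captures is None or config.traps is None:
            raise FileNotFoundError("captures/traps not configured")
        data = read_detections(config.captures, config.traps)
        pnat = None
        cover = state.get("raster")
        if cover is not None:
            pnat = landscape.focal_percent_cover(cover, config.window_radius)
        all_traps = pd.concat([data.traps[s] for s in data.sessions])
        try:
            mask = build_mask(
                all_traps, config.buffer, config.spacing, cover=cover, pnat=pnat
            )
        except ValueError as exc:
            if cover is None:
                raise
            logger.warning(
                "cover raster does not span the buffered state space (%s); "
                "fitting without habitat covariates", exc,
            )
            mask = build_mask(all_traps, config.buffer, config.spacing)
        sel_rows = []
        ests = {}
        for sex in config.sexes:
            fits = []
            for m in config.models:
                spec = scr.SCRModelSpec(
                    m.get("density", "~1"), m.get("g0", "~1"), sex=sex
                )
                fits.append(scr.fit(spec, data, mask, seed=config.seed))
            tbl = scr.model_table(fits)
            tbl.insert(0, "sex", sex)
            sel_rows.append(tbl)
            best = min(
                (f for f in fits if f.converged), key=lambda f: f.AICc
            )
            ests[sex] = scr.realized_estimates(best, mask)
        sel = pd.concat(sel_rows, ignore_index=True)
        report.tables["model_selection"] = sel
        sel.to_csv(out / "model_selection.csv", index=False)

        rows = []
        for sex, e in ests.items():
            rows.append(
                {"sex": sex, "D": e.D[0], "D_lo": e.D[1], "D_hi": e.D[2],
                 "g0": e.g0[0], "sigma": e.sigma[0], "N": e.N[0],
                 "N_lo": e.N[1], "N_hi": e.N[2],
                 "habitat_area_km2": e.habitat_area}
            )
        if {"F", "M"} <= set(ests):
            comb, biased = scr.combine_sexes(ests["F"], ests["M"])
            rows.append(
                {"sex": "combined", "D": comb.D[0], "D_lo": comb.D[1],
                 "D_hi": comb.D[2], "g0": np.nan, "sigma": np.nan,
                 "N": comb.N[0], "N_lo": comb.N[1], "N_hi": comb.N[2],
                 "habitat_area_km2": comb.habitat_area}
            )
            report.log["female_biased"] = bool(biased)
        df = pd.DataFrame(rows)
        report.tables["estimates"] = df
        df.to_csv(out / "estimates.csv", index=False)

    need_gt = config.do_popgen or config.do_ne or config.do_bottleneck or config.do_fca
    stage("load_genotypes", need_gt, [], load_genotypes)
    stage("popgen", config.do_popgen, ["load_genotypes"], popgen)
    stage("ne", config.do_ne, ["load_genotypes"], ne)
    stage("bottleneck", config.do_bottleneck, ["load_genotypes"], bottleneck)
    stage("fca", config.do_fca, ["load_genotypes"], fca_stage)
    need_raster = config.do_frag or (config.do_scr and config.raster is not None)
    stage("load_raster", need_raster, [], load_raster)
    stage("frag", config.do_frag, ["load_raster"], frag)
    scr_deps = ["load_raster"] if config.raster is not None else []
    stage("scr", config.do_scr, scr_deps, scr_stage)

    report.log["total_seconds"] = round(time.time() - t0, 3)
    (out / "run_log.json").write_text(json.dumps(report.log, indent=2, default=str))
    if report.failures:
        (out / "failures.json").write_text(json.dumps(report.failures, indent=2))
    return report
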