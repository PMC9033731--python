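"""End-to-end pipeline: simulate -> covariates -> fit -> scan -> report.

A single structured-text (YAML) config drives the whole run; every stage
writes delimited artefacts into the run directory so stages can be re-run
individually from the CLI. Randomness is seeded once and split per stage
with ``numpy.random.SeedSequence``, so a run is reproducible from
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from . import markers as mk
from . import phenology as ph
from . import report as rep
from . import scan as sc
from . import simdata as sd
from .melmm import REMLOptions, build_design, genetic_correlations, reml_fit
from .types import (
    FAParams,
    QTLEffect,
    QTLSpec,
    SpatialParams,
    TemperatureSeries,
)

__all__ = ["validate_config", "load_config", "run_pipeline", "PipelineError"]

log = logging.getLogger("heatqtl")

REQUIRED_KEYS = {
    "population": ["n_lines"],
    "map": ["n_chromosomes", "markers_per_chromosome", "chromosome_length"],
    "trial": ["years", "checks", "check_reps", "grid_columns"],
    "weather": ["n_days"],
    "phenology": [],
    "trait": ["env_means", "fa", "spatial"],
    "qtl": [],
    "analysis": ["covariates"],
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs stay in the run directory."""


def validate_config(config: dict) -> None:
    for block, keys in REQUIRED_KEYS.items():
        if block not in config:
            raise KeyError(f"config missing required block {block!r}")
        for key in keys:
            if key not in config[block]:
                raise KeyError(f"config block {block!r} missing key {key!r}")


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
            log.info("stage %s: done", name)
            return out
        inner.__name__ = fn.__name__
        inner.__doc__ = fn.__doc__
        return inner
    return wrap


# ----------------------------------------------------------------------
@_stage("simulate")
def stage_simulate(config: dict, outdir: Path, seed: int) -> dict:
    """Map, DH genotypes, p-rep trial, weather, phenotypes, emergence data."""
    s_map, s_pop, s_design, s_weather, s_pheno, s_emerge = _subseeds(seed, 6)
    mp = config["map"]
    linkage_map = sd.simulate_linkage_map(
        mp["n_chromosomes"], mp["markers_per_chromosome"],
        mp["chromosome_length"], s_map)
    pop = config["population"]
    geno = sd.simulate_dh_population(linkage_map, pop["n_lines"], s_pop)
    miss = config.get("genotypes", {}).get("missing_rate", 0.0)
    geno_obs = sd.mask_missing(geno, miss, s_pop + 1) if miss else geno
    trial = config["trial"]
    years = {int(y): list(envs) for y, envs in trial["years"].items()}
    design = sd.generate_prep_design(
        list(geno.lines), years, list(trial["checks"]), trial["check_reps"],
        trial["grid_columns"], s_design, grid_rows=trial.get("grid_rows"))
    envs = design.environments

    wx = config["weather"]
    temps, rains = {}, {}
    wseeds = _subseeds(s_weather, 2 * len(envs))
    env_over = wx.get("envs", {})
    for i, env in enumerate(envs):
        prm = {
            "n_days": wx["n_days"],
            "base_mean": wx.get("base_mean", 15.0),
            "seasonal_amplitude": wx.get("seasonal_amplitude", 6.0),
            "diurnal_range": wx.get("diurnal_range", 12.0),
            "heatwave_rate": wx.get("heatwave_rate", 4.0),
            "heatwave_boost": wx.get("heatwave_boost", 7.0),
            "noise_sd": wx.get("noise_sd", 2.0),
            "start_date": wx.get("start_date", "2015-05-01"),
        }
        prm.update(env_over.get(env, {}))
        series = sd.simulate_temperature_series(seed=wseeds[2 * i], env=env, **prm)
        temps[env] = series.temps[env]
        rains[env] = sd.simulate_rainfall_series(
            wx["n_days"], env_over.get(env, {}).get(
                "mean_daily_rain_mm", wx.get("mean_daily_rain_mm", 1.5)),
            wseeds[2 * i + 1], start_date=prm["start_date"])
    weather = TemperatureSeries(temps, rains)

    # line maturity: spike-emergence thermal time, optionally marker-driven
    phe = config.get("phenology", {})
    rng = np.random.default_rng(s_emerge)
    emergence = pd.Series(
        rng.normal(phe.get("emergence_ccd_mean", 1100.0),
                   phe.get("emergence_ccd_sd", 40.0), geno.n_lines),
        index=geno.lines, name="emergence_ccd")
    for mq in phe.get("maturity_qtl", []):
        emergence += geno.scores[mq["marker"]] * float(mq["size"])

    # covariates must exist before phenotypes when responsiveness QTL planted
    covs = _compute_covariates(config, weather, emergence)

    trait_cfg = config["trait"]
    fa = FAParams(np.array(trait_cfg["fa"]["loadings"], float),
                  np.array(trait_cfg["fa"]["specific"], float))
    sp_cfg = trait_cfg["spatial"]
    if isinstance(sp_cfg, dict) and "sigma2" in sp_cfg:
        spatial = SpatialParams({e: (sp_cfg["sigma2"], sp_cfg["rho_row"],
                                     sp_cfg["rho_col"]) for e in envs})
    else:
        spatial = SpatialParams({e: tuple(sp_cfg[e]) for e in envs})
    effects = [
        QTLEffect(q["marker"], q["kind"], float(q["size"]), q.get("covariate"))
        for q in config.get("qtl", [])
    ]
    qtl = QTLSpec(effects)
    env_means = {e: float(config["trait"]["env_means"][e]) for e in envs}
    obs = sd.simulate_phenotypes(
        design, geno, qtl, covs, env_means, fa, spatial, s_pheno,
        trait=trait_cfg.get("name", "yield"))

    hio.write_linkage_map(linkage_map, outdir / "map.csv")
    hio.write_genotypes(geno_obs, outdir / "genotypes.csv")
    hio.write_trial(obs, outdir / "trial.csv")
    hio.write_weather(weather, outdir / "weather")
    emergence.to_csv(outdir / "emergence.csv")
    hio.write_covariates(covs, outdir / "covariates.csv")
    return {"map": linkage_map, "geno": geno_obs, "design": design, "obs": obs,
            "weather": weather, "emergence": emergence, "covariates": covs}


def _compute_covariates(config, weather, emergence) -> dict:
    phe = config.get("phenology", {})
    sowing = config["weather"].get("start_date", "2015-05-01")
    thermal = ph.thermal_time(weather, phe.get("sowing_date", sowing))
    schedule = ph.estimate_anthesis(
        emergence, phe.get("anthesis_offset_ccd", 100.0), thermal)
    return ph.make_covariates(weather, schedule, thermal,
                              rainfall=weather.rainfall)


@_stage("covariates")
def stage_covariates(config: dict, outdir: Path, state: dict) -> dict:
    """Degree-day windows and climatic covariates from stored weather."""
    covs = _compute_covariates(config, state["weather"], state["emergence"])
    hio.write_covariates(covs, outdir / "covariates.csv")
    state["covariates"] = covs
    return state


@_stage("fit")
def stage_fit(config: dict, outdir: Path, state: dict) -> dict:
    """Baseline ME-LMM fit; parameter table and genetic correlations."""
    ana = config["analysis"]
    spec = build_design(state["obs"], state["design"],
                        dh_lines=state["geno"].lines)
    options = REMLOptions(tol=float(ana.get("reml_tol", 1e-6)),
                          max_iter=int(ana.get("reml_max_iter", 80)))
    fit = reml_fit(spec, options=options, fa_order=ana.get("fa_order"))
    params = pd.DataFrame({"parameter": fit.param_names, "estimate": fit.theta,
                           "se": fit.theta_se})
    params.to_csv(outdir / "baseline_params.csv", index=False)
    genetic_correlations(fit).to_csv(outdir / "genetic_correlations.csv")
    with open(outdir / "baseline_log.txt", "w") as fh:
        fh.write(f"loglik {fit.loglik:.6f} converged {fit.converged} "
                 f"iters {fit.n_iter}\n")
        for it, ll, note in fit.iter_log:
            fh.write(f"iter {it}: loglik {ll:.6f} ({note})\n")
    state["spec"] = spec
    state["baseline"] = fit
    return state


@_stage("scan")
def stage_scan(config: dict, outdir: Path, state: dict) -> dict:
    """Performance run plus one responsiveness run per requested covariate."""
    ana = config["analysis"]
    cfg = sc.ScanConfig(
        alpha=float(ana.get("alpha", 0.05)),
        vc_mode=ana.get("vc_mode", "chromosome"),
        fa_order=ana.get("fa_order"),
    )
    geno_c, map_c = mk.collapse_unique(
        mk.impute_missing(state["geno"], state["map"]), state["map"])
    M = mk.make_interval_markers(geno_c, map_c)
    hio.write_interval_markers(M, outdir / "interval_markers.csv",
                               outdir / "interval_marker_info.csv")
    runs = [("performance", None)]
    for name in ana["covariates"]:
        cov = state["covariates"][name]
        if cov.range() <= 0:
            log.warning("covariate %s is constant in this run; "
                        "responsiveness scan skipped", name)
            continue
        runs.append(("responsiveness", cov))
    results, null_theta = sc.scan_genome_multi(
        state["spec"], M, runs, state.get("baseline"), cfg)
    for res in results:
        tag = res.kind if res.covariate is None else f"{res.kind}_{res.covariate}"
        res.table.to_csv(outdir / f"scan_{tag}.csv", index=False)
    threshold = sc.li_ji_threshold(M, cfg.alpha)
    with open(outdir / "threshold.json", "w") as fh:
        json.dump({"alpha": threshold.alpha, "m_eff": threshold.m_eff,
                   "per_test_alpha": threshold.per_test_alpha,
                   "wald_threshold": threshold.wald_threshold}, fh, indent=2)
    state.update({"M": M, "scans": results, "threshold": threshold,
                  "scan_config": cfg, "null_theta": null_theta})
    return state


@_stage("finalize")
def stage_finalize(config: dict, outdir: Path, state: dict) -> dict:
    """Prune each run and fit the joint final models."""
    ana = config["analysis"]
    trait = config["trait"].get("name", "yield")
    popname = config["population"].get("name", "POP")
    parents = tuple(config["population"].get("parents", ("A", "B")))
    records = []
    for res in state["scans"]:
        selected = sc.prune_30cM(res, state["threshold"],
                                 state["scan_config"].prune_window_cM)
        cov = None
        if res.kind == "responsiveness":
            cov = state["covariates"][res.covariate]
        records += sc.fit_final_model(
            state["spec"], state["M"], selected, res.kind, cov,
            state["scan_config"], state.get("baseline"), trait=trait,
            population=popname, parents=parents,
            start_theta=state.get("null_theta"))
    table = rep.qtl_summary_table(records)
    table.to_csv(outdir / "qtl_table.csv", index=False)
    state["records"] = records
    return state


@_stage("report")
def stage_report(config: dict, outdir: Path, state: dict) -> dict:
    """Cluster QTL, classify the adaptation framework, draw effect plots."""
    records = state["records"]
    clusters = rep.cluster_qtl(records)
    anthesis = [r for r in records if r.trait == "anthesis"]
    rep.flag_anthesis_association(clusters, anthesis)
    rows = []
    for i, cl in enumerate(clusters, start=1):
        labels = rep.classify_framework(cl)
        for trait, lab in labels.items():
            rows.append({
                "cluster": i, "chrom": cl.chrom,
                "start_cM": round(cl.span_cM[0], 2),
                "end_cM": round(cl.span_cM[1], 2),
                "n_members": cl.n_members,
                "contains_anthesis_qtl": cl.contains_anthesis_qtl,
                "trait": trait,
                "performance": lab.performance,
                "responsiveness": lab.responsiveness,
                "rainfall_response": lab.rainfall_response,
                "linkage": lab.linkage,
                "description": lab.describe(),
            })
    pd.DataFrame(rows).to_csv(outdir / "clusters.csv", index=False)
    _effect_plots(state, outdir)
    return state


def _effect_plots(state: dict, outdir: Path) -> None:
    """Allele-class trait difference vs covariate mean, per responsiveness QTL."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    resp = [r for r in state.get("records", []) if r.qtl_type == "responsiveness"]
    if not resp:
        return
    obs = state["obs"]
    frame = obs.frame()
    frame = frame[~frame["is_check"]]
    geno = state["geno"]
    trait_col = obs.trait
    for rec in resp:
        cov = state["covariates"][rec.covariate]
        # nearest original marker to the detected interval marker position
        info = state["M"].info.loc[rec.marker]
        scores = state["M"].scores[rec.marker]
        alleles = np.sign(scores).replace(0, np.nan)
        xs, ys = [], []
        for env, grp in frame.groupby("env"):
            cls = grp["genotype"].map(alleles)
            hi = grp.loc[cls > 0, trait_col].mean()
            lo = grp.loc[cls < 0, trait_col].mean()
            xs.append(cov.wide[env].mean())
            ys.append(hi - lo)
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(xs, ys, color="tab:red")
        xg = np.linspace(min(xs), max(xs), 10)
        ax.plot(xg, 2 * rec.effect * xg + (np.mean(ys) - 2 * rec.effect * np.mean(xs)),
                color="grey", ls="--", label=f"2b = {2 * rec.effect:.3g}/unit")
        ax.set_xlabel(f"{rec.covariate} (environment mean)")
        ax.set_ylabel(f"{trait_col}: allele class difference")
        ax.set_title(rec.name, fontsize=9)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / f"effect_{rec.name.replace('.', '_')}.png", dpi=110)
        plt.close(fig)


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute every stage; artefacts, logs and plots land in ``outdir``."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    with open(outdir / "run_info.json", "w") as fh:
        json.dump({"seed": seed, "config_hash": _config_hash(config)}, fh, indent=2)
    with open(outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    state = stage_simulate(config, outdir, seed)
    state = stage_covariates(config, outdir, state)
    state = stage_fit(config, outdir, state)
    state = stage_scan(config, outdir, state)
    state = stage_finalize(config, outdir, state)
    state = stage_report(config, outdir, state)
    return state
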