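"""Canonical simulation scenarios for calibrating and validating the scan.

Two fixed study designs are used throughout the package's self-checks:

* the *calibration* scenario — 150 DH lines, 3 environments in one year,
  3 chromosomes of 120 cM with 40 markers each — for null false-positive
  rates of the genome-wide threshold;
* the *recovery* scenario — 400 DH lines, 6 environments over two years —
  with one planted performance QTL of 0.4 phenotypic SD and one planted
  responsiveness QTL whose covariate-range-normalised effect is 0.35
  phenotypic SD on the anthesis average-maximum covariate.

Genetic and residual parameters mimic a grain-yield trial: per-environment
genetic variance about 0.3 (trait units squared) with cross-environment
genetic correlations around 0.8, spatial variance 0.3 with moderate AR1
autocorrelation, and environment mean maxima spanning roughly the 19.5 to
24.3 degC spread of contrasting field seasons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import markers as mk
from . import scan as sc
from . import simdata as sd
from .melmm import build_design
from .phenology import ClimaticCovariate
from .types import FAParams, QTLEffect, QTLSpec, SpatialParams

__all__ = ["make_dataset", "calibration_dataset", "recovery_dataset",
           "null_false_positive", "recovery_detection"]

#: environment mean anthesis average-maximum temperatures (degC), spanning
#: the mild-maritime to hot-inland contrast of the six trial environments
ENV_COV_MEANS = (24.3, 22.8, 21.5, 20.8, 19.5, 23.1)


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def make_dataset(
    seed: int,
    n_lines: int,
    envs_by_year: dict,
    n_chromosomes: int = 3,
    markers_per_chromosome: int = 40,
    chromosome_length: float = 120.0,
    perf_marker: str | None = None,
    resp_marker: str | None = None,
    perf_sd: float = 0.4,
    resp_norm_sd: float = 0.35,
    fa_order_truth: int = 1,
):
    """One simulated trial with optional planted QTL.

    Effect sizes are expressed in phenotypic SD units: the performance
    allele effect is ``perf_sd`` x SD, the responsiveness slope is chosen so
    that slope x covariate range equals ``resp_norm_sd`` x SD.
    Returns a dict with the design spec, interval markers, covariate, truth
    positions and simulation parameters.
    """
    seeds = _subseeds(seed, 6)
    envs = [e for year in envs_by_year.values() for e in year]
    t = len(envs)
    lm = sd.simulate_linkage_map(n_chromosomes, markers_per_chromosome,
                                 chromosome_length, seeds[0])
    geno = sd.simulate_dh_population(lm, n_lines, seeds[1])
    design = sd.generate_prep_design(
        list(geno.lines), envs_by_year, ["CHK1", "CHK2"], 1,
        grid_columns=8 if n_lines <= 200 else 12, seed=seeds[2])

    rng = np.random.default_rng(seeds[3])
    if fa_order_truth == 1 or t < 3:
        lam = np.full((t, 1), 0.5) + rng.normal(0, 0.04, (t, 1))
    else:
        lam = np.column_stack([
            np.full(t, 0.5) + rng.normal(0, 0.04, t),
            np.concatenate([[0.0], rng.normal(0, 0.12, t - 1)]),
        ])
    fa = FAParams(lam, np.full(t, 0.06))
    spatial = SpatialParams({e: (0.3, 0.35, 0.25) for e in envs})
    sd_p = float(np.sqrt(np.mean(np.sum(lam ** 2, axis=1)) + 0.06 + 0.3))

    cov_means = dict(zip(envs, ENV_COV_MEANS))
    cov = ClimaticCovariate(
        "anthesis_avg_max",
        pd.DataFrame({e: cov_means[e] + rng.normal(0, 0.3, n_lines)
                      for e in envs}, index=geno.lines))

    effects = []
    truth = {}
    if perf_marker:
        effects.append(QTLEffect(perf_marker, "performance", perf_sd * sd_p))
        truth["performance"] = (lm.chrom_of()[perf_marker],
                                float(lm.pos_of()[perf_marker]))
    if resp_marker:
        b = resp_norm_sd * sd_p / cov.range()
        effects.append(QTLEffect(resp_marker, "responsiveness", b,
                                 "anthesis_avg_max"))
        truth["responsiveness"] = (lm.chrom_of()[resp_marker],
                                   float(lm.pos_of()[resp_marker]))
    env_means = {e: 3.0 + 0.15 * i for i, e in enumerate(envs)}
    obs = sd.simulate_phenotypes(
        design, geno, QTLSpec(effects), {"anthesis_avg_max": cov},
        env_means, fa, spatial, seeds[4])
    spec = build_design(obs, design, dh_lines=geno.lines)
    geno_c, lm_c = mk.collapse_unique(geno, lm)
    M = mk.make_interval_markers(geno_c, lm_c)
    return {"map": lm, "geno": geno, "design": design, "obs": obs,
            "spec": spec, "M": M, "cov": cov, "truth": truth, "sd_p": sd_p,
            "fa": fa, "spatial": spatial}


def calibration_dataset(seed: int, **kwargs):
    """Null 150-line x 3-environment trial (no planted QTL)."""
    return make_dataset(seed, 150, {2015: ["E1", "E2", "E3"]}, **kwargs)


def recovery_dataset(seed: int, **kwargs):
    """400-line x 6-environment trial with both planted QTL."""
    kwargs.setdefault("perf_marker", "c1m20")
    kwargs.setdefault("resp_marker", "c2m20")
    return make_dataset(
        seed, 400,
        {2015: ["E1", "E2", "E3"], 2016: ["E4", "E5", "E6"]}, **kwargs)


def null_false_positive(seed: int, config: sc.ScanConfig | None = None) -> bool:
    """Whether any marker clears the genome-wide threshold on null data."""
    data = calibration_dataset(seed)
    config = config or sc.ScanConfig()
    results, _ = sc.scan_genome_multi(
        data["spec"], data["M"], [("performance", None)], None, config)
    thr = sc.li_ji_threshold(data["M"], config.alpha)
    tab = results[0].table
    mx = tab.loc[~tab["untestable"], "wald"].max()
    return bool(mx >= thr.wald_threshold)


def recovery_detection(seed: int, config: sc.ScanConfig | None = None,
                       window_cM: float = 15.0) -> tuple[bool, bool]:
    """(performance detected, responsiveness detected) for one replicate.

    Detection: after thresholding and pruning, a selected marker lies within
    ``window_cM`` of the planted position with the planted effect sign.
    """
    data = recovery_dataset(seed)
    config = config or sc.ScanConfig(vc_mode="global")
    runs = [("performance", None), ("responsiveness", data["cov"])]
    results, _ = sc.scan_genome_multi(data["spec"], data["M"], runs, None, config)
    thr = sc.li_ji_threshold(data["M"], config.alpha)
    out = []
    for res, key in zip(results, ["performance", "responsiveness"]):
        chrom, pos = data["truth"][key]
        sel = sc.prune_30cM(res, thr, config.prune_window_cM)
        hit = any(
            (row.chrom == chrom) and abs(row.pos_cM - pos) <= window_cM
            and row.effect > 0
            for row in sel.itertuples(index=False)
        )
        out.append(bool(hit))
    return tuple(out)
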