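"""Synthetic doubled-haploid multi-environment trial generator.

Every downstream stage of the pipeline (marker preparation, climatic
covariates, the multi-environment mixed model, the genome scans) is exercised
on data from this module: biparental DH genotypes on a linkage map, partially
replicated (p-rep) field layouts, daily weather series, and plot-level
phenotypes with planted performance / responsiveness QTL, factor-analytic
G x E structure and AR1 x AR1 spatial residuals.

Meiosis uses Haldane's map function with no interference, so every simulated
recombination fraction has a closed form that tests can check against.
Temperature is generated at daily resolution (min/max); all climatic
covariates used downstream are daily summaries, for which daily min/max is a
sufficient record.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import (
    FAParams,
    FieldDesign,
    GenotypeMatrix,
    LinkageMap,
    QTLSpec,
    SpatialParams,
    TemperatureSeries,
    TraitObservations,
)

__all__ = [
    "haldane",
    "simulate_linkage_map",
    "simulate_dh_population",
    "generate_prep_design",
    "FIELD_GRID_PRESETS",
    "simulate_temperature_series",
    "simulate_rainfall_series",
    "draw_gxe_deviations",
    "draw_spatial_residuals",
    "simulate_phenotypes",
]


def haldane(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


def simulate_linkage_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chromosome_length: float,
    seed: int,
) -> LinkageMap:
    """Uniform random marker positions on equal-length chromosomes.

    Marker names are ``c<chrom>m<index>``; positions are sorted uniform draws
    on [0, chromosome_length].
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    if chromosome_length <= 0:
        raise ValueError("chromosome length must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        pos = np.sort(rng.uniform(0.0, chromosome_length, markers_per_chromosome))
        for j, p in enumerate(pos, start=1):
            rows.append((f"c{c}m{j}", f"{c}", float(p)))
    return LinkageMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"]))


def simulate_dh_population(
    linkage_map: LinkageMap,
    n_lines: int,
    seed: int,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Doubled gametes from an F1 of two fully informative inbreds.

    Per chromosome each line is a two-state Markov chain over {+1, -1}: the
    first marker is a fair coin, and the phase switches between adjacent
    markers with probability equal to the Haldane recombination fraction of
    their map distance. Chromosomes segregate independently.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    if linkage_map.n_markers == 0:
        raise ValueError("empty linkage map")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    blocks = []
    for chrom in linkage_map.chromosomes:
        pos = linkage_map.positions(chrom)
        p = len(pos)
        geno = np.empty((n_lines, p))
        geno[:, 0] = rng.choice([-1.0, 1.0], size=n_lines)
        theta = haldane(np.diff(pos))
        for j in range(1, p):
            switch = rng.random(n_lines) < theta[j - 1]
            geno[:, j] = np.where(switch, -geno[:, j - 1], geno[:, j - 1])
        blocks.append(geno)
    scores = np.hstack(blocks)
    if missing_rate > 0.0:
        mask = rng.random(scores.shape) < missing_rate
        scores = np.where(mask, np.nan, scores)
    lines = [f"L{i + 1:04d}" for i in range(n_lines)]
    frame = pd.DataFrame(scores, index=pd.Index(lines, name="line"),
                         columns=list(linkage_map.markers))
    return GenotypeMatrix(frame, linkage_map)


def mask_missing(genotypes: GenotypeMatrix, missing_rate: float, seed: int) -> GenotypeMatrix:
    """Observed-call copy of a genotype matrix with random missing calls.

    The generative truth stays complete; this models array no-calls on the
    exported data that imputation must recover.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if missing_rate == 0.0:
        return genotypes
    rng = np.random.default_rng(seed)
    vals = genotypes.values().copy()
    mask = rng.random(vals.shape) < missing_rate
    # never blank out a line's whole chromosome: keep the first marker
    vals = np.where(mask, np.nan, vals)
    for chrom in genotypes.map.chromosomes:
        cols = np.flatnonzero((genotypes.map.table["chrom"] == chrom).to_numpy())
        gone = np.isnan(vals[:, cols]).all(axis=1)
        if gone.any():
            vals[np.flatnonzero(gone), cols[0]] = genotypes.values()[
                np.flatnonzero(gone), cols[0]]
    frame = pd.DataFrame(vals, index=genotypes.lines,
                         columns=genotypes.scores.columns)
    return GenotypeMatrix(frame, genotypes.map)


#: Field grid dimensions of the published experiments (columns x rows).
FIELD_GRID_PRESETS = {
    "GSM_2015": {"columns": 12, "rows": 108},
    "GSM_2016": {"columns": 24, "rows": 14},
    "X32_2015": {"columns": 12, "rows": 18},
    "X32_2016": {"columns": 24, "rows": 6},
    "X4_2015": {"columns": 12, "rows": 20},
    "X4_2016": {"columns": 24, "rows": 8},
}


def generate_prep_design(
    dh_lines,
    environments: dict,
    check_lines,
    check_reps: int,
    grid_columns: int,
    seed: int,
    grid_rows: int | None = None,
) -> FieldDesign:
    """Partially replicated (p-rep) multi-environment layout.

    Every DH line is sown once in every environment of its year and receives
    exactly one duplicate plot in one uniformly chosen environment of that
    year, so with three environments lines average 4/3 plots per environment.
    Checks appear ``check_reps`` times in every environment. Plots fill a
    complete column x row grid; spare grid cells are filled with extra check
    plots (fillers), mirroring how real trials pad their grids.

    ``environments`` maps year -> list of environment ids. ``grid_rows`` is
    optional; when omitted the smallest row count that fits is used.
    """
    dh_lines = list(dh_lines)
    check_lines = list(check_lines)
    if check_reps < 0:
        raise ValueError("check_reps must be >= 0")
    if not check_lines and check_reps > 0:
        raise ValueError("check_reps > 0 but no check lines given")
    rng = np.random.default_rng(seed)
    rows_out = []
    for year, envs in environments.items():
        envs = list(envs)
        # one duplicate environment per line, uniform over the year's envs
        dup_env = rng.integers(0, len(envs), size=len(dh_lines))
        for e_idx, env in enumerate(envs):
            entries = list(dh_lines)
            entries += [dh_lines[i] for i in np.flatnonzero(dup_env == e_idx)]
            entries += [c for c in check_lines for _ in range(check_reps)]
            required = len(entries)
            n_rows = grid_rows if grid_rows is not None else math.ceil(required / grid_columns)
            capacity = grid_columns * n_rows
            if capacity < required:
                raise ValueError(
                    f"grid {grid_columns}x{n_rows} in {env!r} holds {capacity} plots "
                    f"but {required} are required"
                )
            # pad to a complete grid with filler check plots
            fill = capacity - required
            fillers = [check_lines[i % len(check_lines)] for i in range(fill)] if fill else []
            if fill and not check_lines:
                raise ValueError(
                    f"grid {grid_columns}x{n_rows} in {env!r} leaves {fill} spare plots "
                    "and no check lines to fill them"
                )
            entries += fillers
            order = rng.permutation(len(entries))
            is_check = {c for c in check_lines}
            for k, plot in enumerate(order):
                geno = entries[plot]
                col, row = divmod(k, n_rows)
                rows_out.append(
                    (env, year, col + 1, row + 1, geno, geno in is_check)
                )
    frame = pd.DataFrame(
        rows_out, columns=["env", "year", "column", "row", "genotype", "is_check"]
    )
    return FieldDesign(frame)


def simulate_temperature_series(
    n_days: int,
    base_mean: float,
    seasonal_amplitude: float,
    diurnal_range: float,
    heatwave_rate: float,
    heatwave_boost: float,
    noise_sd: float,
    seed: int,
    start_date: str = "2015-05-01",
    trough_day: int = 75,
    env: str = "E1",
) -> TemperatureSeries:
    """Daily min/max temperatures: sinusoidal seasonal mean plus noise.

    The daily mean follows ``base_mean - amplitude * cos(2 pi (d - trough) /
    365)`` (southern-hemisphere winter trough mid-season) plus Gaussian noise;
    min/max sit half the diurnal range either side of the mean. Heatwave
    events (Poisson ``heatwave_rate`` per season, 1-5 consecutive days) add
    ``heatwave_boost`` to the daily maximum.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if diurnal_range < 0:
        raise ValueError("diurnal_range must be >= 0")
    if heatwave_boost < 0 or heatwave_rate < 0:
        raise ValueError("heatwave parameters must be >= 0")
    rng = np.random.default_rng(seed)
    d = np.arange(n_days)
    mean = base_mean - seasonal_amplitude * np.cos(2 * np.pi * (d - trough_day) / 365.0)
    if noise_sd > 0:
        mean = mean + rng.normal(0.0, noise_sd, n_days)
    tmin = mean - diurnal_range / 2.0
    tmax = mean + diurnal_range / 2.0
    n_events = rng.poisson(heatwave_rate)
    for _ in range(n_events):
        start = int(rng.integers(0, n_days))
        length = int(rng.integers(1, 6))
        tmax[start:start + length] += heatwave_boost
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    frame = pd.DataFrame({"date": dates, "tmin": tmin, "tmax": tmax})
    return TemperatureSeries({env: frame})


def simulate_rainfall_series(
    n_days: int,
    mean_daily_mm: float,
    seed: int,
    start_date: str = "2015-05-01",
) -> pd.DataFrame:
    """Skewed daily rainfall (gamma bursts) with the requested daily mean."""
    if mean_daily_mm < 0:
        raise ValueError("mean_daily_mm must be >= 0")
    rng = np.random.default_rng(seed)
    shape = 0.3  # many dry-ish days, occasional heavy falls
    mm = rng.gamma(shape, mean_daily_mm / shape, size=n_days) if mean_daily_mm > 0 else np.zeros(n_days)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    return pd.DataFrame({"date": dates, "mm": mm})


def draw_gxe_deviations(n_lines: int, fa: FAParams, rng: np.random.Generator) -> np.ndarray:
    """Line-by-environment genetic deviations with covariance LL^T + Psi.

    Returns an (n_lines, t) array: common factors times loadings plus
    environment-specific noise, independent across lines.
    """
    t, k = fa.loadings.shape
    factors = rng.standard_normal((n_lines, k))
    specific = rng.standard_normal((n_lines, t)) * np.sqrt(fa.specific)
    return factors @ fa.loadings.T + specific


def _ar1_chol(rho: float, n: int) -> np.ndarray:
    idx = np.arange(n)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def draw_spatial_residuals(
    design_env: pd.DataFrame,
    sigma2: float,
    rho_row: float,
    rho_col: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """AR1 x AR1 correlated residuals for one environment's plots.

    Simulated on the bounding column x row grid and read off at the observed
    plot addresses (the marginal over a sub-grid of a separable AR1 field is
    the sub-grid's own AR1 field).
    """
    cols = np.sort(design_env["column"].unique())
    rows = np.sort(design_env["row"].unique())
    lc = _ar1_chol(rho_col, len(cols))
    lr = _ar1_chol(rho_row, len(rows))
    z = rng.standard_normal((len(cols), len(rows)))
    field = math.sqrt(sigma2) * (lc @ z @ lr.T)
    ci = {c: i for i, c in enumerate(cols)}
    ri = {r: i for i, r in enumerate(rows)}
    return np.array([field[ci[c], ri[r]] for c, r in
                     zip(design_env["column"], design_env["row"])])


def simulate_phenotypes(
    design: FieldDesign,
    genotypes: GenotypeMatrix,
    qtl: QTLSpec,
    covariates: dict,
    env_means: dict,
    fa: FAParams,
    spatial: SpatialParams,
    seed: int,
    check_effects: dict | None = None,
    trait: str = "yield",
) -> TraitObservations:
    """Plot-level responses: the generative twin of the analysis model.

    value = environment mean (+ fixed check effect for check plots)
          + sum over performance QTL of m * a
          + sum over responsiveness QTL of c * m * b
          + line-by-environment deviation with covariance LL^T + Psi
          + AR1 x AR1 spatial residual with per-environment variance.

    Duplicate plots of a line share its genetic value; checks carry fixed
    effects only (no random genetic deviation). ``covariates`` maps covariate
    name -> wide DataFrame (lines x environments).
    """
    qtl.validate_against(genotypes.map)
    envs = design.environments
    if fa.n_env != len(envs):
        raise ValueError("FA parameters disagree with the number of environments")
    for eff in qtl.responsiveness:
        if eff.covariate not in covariates:
            raise ValueError(
                f"covariate {eff.covariate!r} needed by a planted responsiveness "
                "QTL is not provided"
            )
    rng = np.random.default_rng(seed)
    lines = genotypes.lines
    line_pos = {l: i for i, l in enumerate(lines)}
    scores = genotypes.values()
    if np.isnan(scores).any():
        raise ValueError("phenotype simulation needs complete genotypes")
    marker_pos = {m: j for j, m in enumerate(genotypes.scores.columns)}

    # genetic value components per line
    perf = np.zeros(len(lines))
    for eff in qtl.performance:
        perf += scores[:, marker_pos[eff.marker]] * eff.size
    gxe = draw_gxe_deviations(len(lines), fa, rng)  # lines x t

    check_effects = check_effects or {}
    # accept ClimaticCovariate objects or plain wide DataFrames
    cov_wide = {name: getattr(c, "wide", c) for name, c in covariates.items()}
    values = np.empty(design.n_plots)
    values[:] = np.nan
    tbl = design.table
    for e_idx, env in enumerate(envs):
        sel = (tbl["env"] == env).to_numpy()
        sub = tbl[sel]
        s2, rr, rc = spatial.for_env(env)
        resid = draw_spatial_residuals(sub, s2, rr, rc, rng)
        out = np.full(len(sub), float(env_means[env]))
        for i, (geno, is_check) in enumerate(zip(sub["genotype"], sub["is_check"])):
            if is_check:
                out[i] += float(check_effects.get((geno, env), 0.0))
                continue
            li = line_pos[geno]
            out[i] += perf[li] + gxe[li, e_idx]
            for eff in qtl.responsiveness:
                c = cov_wide[eff.covariate].loc[geno, env]
                out[i] += float(c) * scores[li, marker_pos[eff.marker]] * eff.size
        values[sel] = out + resid
    return TraitObservations(design, pd.Series(values), trait=trait)
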