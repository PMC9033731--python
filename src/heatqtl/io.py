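"""Delimited-text readers and writers for every pipeline artefact.

All formats are plain CSV so a run directory can be inspected, diffed and
version-controlled: linkage map (marker, chrom, pos_cM), genotype calls
(lines x markers, A/B/NA), tidy field design + phenotypes (one row per
plot), per-environment weather (date, tmin, tmax) and rainfall (date, mm),
the interval-marker matrix with its column metadata, covariate tables and
QTL reports.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .markers import IntervalMarkerMatrix
from .phenology import ClimaticCovariate
from .types import (
    FieldDesign,
    GenotypeMatrix,
    LinkageMap,
    TemperatureSeries,
    TraitObservations,
)

__all__ = [
    "write_linkage_map", "read_linkage_map",
    "write_genotypes", "read_genotypes",
    "write_trial", "read_trial",
    "write_weather", "read_weather",
    "write_interval_markers",
    "write_covariates", "read_covariates",
    "write_map_summaries",
]


def write_linkage_map(linkage_map: LinkageMap, path) -> None:
    linkage_map.table.to_csv(path, index=False)


def read_linkage_map(path) -> LinkageMap:
    t = pd.read_csv(path, dtype={"marker": str, "chrom": str})
    return LinkageMap(t[["marker", "chrom", "pos_cM"]])


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Lines x markers with alleles coded A / B / NA."""
    vals = genotypes.values()
    out = np.full(vals.shape, "NA", dtype=object)
    out[vals == 1.0] = "A"
    out[vals == -1.0] = "B"
    frame = pd.DataFrame(out, index=genotypes.lines, columns=genotypes.scores.columns)
    frame.index.name = "line"
    frame.to_csv(path)


def read_genotypes(path, linkage_map: LinkageMap) -> GenotypeMatrix:
    raw = pd.read_csv(path, index_col="line", dtype=str, keep_default_na=False)
    from .markers import encode_alleles  # local import: markers depends on types only
    return encode_alleles(raw, linkage_map)


def write_trial(obs: TraitObservations, path) -> None:
    """Tidy plot table: design columns plus the trait column."""
    obs.frame().to_csv(path, index=False)


def read_trial(path, trait: str | None = None) -> TraitObservations:
    t = pd.read_csv(path, dtype={"env": str, "genotype": str})
    design_cols = ["env", "year", "column", "row", "genotype", "is_check"]
    design = FieldDesign(t[design_cols])
    if trait is None:
        extra = [c for c in t.columns if c not in design_cols]
        if len(extra) != 1:
            raise ValueError(f"specify the trait column; candidates: {extra}")
        trait = extra[0]
    return TraitObservations(design, t[trait], trait=trait)


def write_weather(series: TemperatureSeries, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for env, frame in series.temps.items():
        frame.to_csv(outdir / f"temperature_{env}.csv", index=False)
    for env, frame in series.rainfall.items():
        frame.to_csv(outdir / f"rainfall_{env}.csv", index=False)


def read_weather(outdir, envs) -> TemperatureSeries:
    outdir = Path(outdir)
    temps, rain = {}, {}
    for env in envs:
        temps[env] = pd.read_csv(outdir / f"temperature_{env}.csv")
        rp = outdir / f"rainfall_{env}.csv"
        if rp.exists():
            rain[env] = pd.read_csv(rp)
    return TemperatureSeries(temps, rain)


def write_interval_markers(M: IntervalMarkerMatrix, path, meta_path=None) -> None:
    scores = M.scores.copy()
    scores.index.name = "line"
    scores.to_csv(path)
    if meta_path is not None:
        M.info.to_csv(meta_path)


def write_map_summaries(summaries: dict, path) -> None:
    """Map-summary report: one row per population, published-table columns."""
    rows = []
    for name, s in summaries.items():
        rows.append({
            "population": name,
            "n_markers": s.n_markers,
            "n_unique_positions": s.n_unique_positions,
            "genetic_length_cM": round(s.length_cM, 0),
            "mean_interval_cM": round(s.mean_interval_cM, 1),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_covariates(covariates: dict, path) -> None:
    """Tidy (line, env, covariate, value) table for a covariate set."""
    rows = []
    for name, cov in covariates.items():
        long = cov.wide.stack().reset_index()
        long.columns = ["line", "env", "value"]
        long.insert(2, "covariate", name)
        rows.append(long)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_covariates(path) -> dict:
    t = pd.read_csv(path, dtype={"line": str, "env": str, "covariate": str})
    out = {}
    for name, grp in t.groupby("covariate"):
        wide = grp.pivot(index="line", columns="env", values="value")
        out[name] = ClimaticCovariate(name, wide)
    return out
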