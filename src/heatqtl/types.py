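"""Core data containers for the QTL heat-adaptation pipeline.

Thin, validated wrappers around pandas/numpy objects. Conventions used
throughout the package:

* DH genotype scores live in ``{+1.0, -1.0, nan}`` (AA = +1, BB = -1,
  nan = missing call); doubled-haploid material carries no heterozygotes.
* Linkage-map positions are centimorgans (cM), non-negative and
  non-decreasing within a chromosome.
* Field plots are addressed by (environment, column, row); a design is one
  tidy table with one row per plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LinkageMap",
    "GenotypeMatrix",
    "FieldDesign",
    "TemperatureSeries",
    "QTLEffect",
    "QTLSpec",
    "TraitObservations",
    "FAParams",
    "SpatialParams",
]


@dataclass(frozen=True)
class LinkageMap:
    """Genetic map: one row per marker with chromosome and position (cM).

    ``table`` columns: ``marker``, ``chrom``, ``pos_cM``. Markers are kept in
    map order (chromosome blocks, non-decreasing position within each).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "pos_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"linkage map needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name {dup!r}")
        if (t["pos_cM"] < 0).any():
            raise ValueError("map positions must be non-negative")
        for chrom, grp in t.groupby("chrom", sort=False):
            if grp.empty:
                raise ValueError(f"chromosome {chrom!r} has no markers")
            if not grp["pos_cM"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on chromosome {chrom!r}")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def positions(self, chrom) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos_cM"].to_numpy(float)

    def chrom_of(self) -> pd.Series:
        """marker -> chromosome lookup."""
        return self.table.set_index("marker")["chrom"]

    def pos_of(self) -> pd.Series:
        """marker -> position (cM) lookup."""
        return self.table.set_index("marker")["pos_cM"]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Lines x markers score matrix aligned to a :class:`LinkageMap`.

    ``scores`` is a DataFrame indexed by line id with one column per marker
    in map order. Raw DH calls are +1 (AA), -1 (BB) or nan (missing) — no
    heterozygotes; after imputation entries are conditional expectations in
    [-1, +1].
    """

    scores: pd.DataFrame
    map: LinkageMap

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(self.map.markers):
            raise ValueError("genotype columns must match map markers in order")
        vals = self.scores.to_numpy(float)
        ok = np.isnan(vals) | (np.abs(vals) <= 1.0 + 1e-12)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid score {vals[i, j]!r} at line {self.scores.index[i]!r}, "
                f"marker {self.scores.columns[j]!r} (scores live in [-1, +1] "
                "or missing)"
            )

    @property
    def lines(self) -> pd.Index:
        return self.scores.index

    @property
    def n_lines(self) -> int:
        return len(self.scores.index)

    @property
    def n_markers(self) -> int:
        return self.scores.shape[1]

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(float)


@dataclass(frozen=True)
class FieldDesign:
    """Plot-level field layout for one or more environments.

    ``table`` columns: ``env``, ``year``, ``column``, ``row``, ``genotype``,
    ``is_check``. (env, column, row) is unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"env", "year", "column", "row", "genotype", "is_check"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"field design needs columns {sorted(required)}")
        if self.table.duplicated(subset=["env", "column", "row"]).any():
            raise ValueError("duplicate (env, column, row) plot address")

    @property
    def environments(self) -> list:
        return list(dict.fromkeys(self.table["env"]))

    @property
    def n_plots(self) -> int:
        return len(self.table)

    def env_table(self, env) -> pd.DataFrame:
        return self.table[self.table["env"] == env]

    def dh_lines(self) -> pd.Index:
        t = self.table
        return pd.Index(dict.fromkeys(t.loc[~t["is_check"], "genotype"]).keys())


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily min/max temperature (and optional rainfall) per environment.

    ``temps`` maps env -> DataFrame(date, tmin, tmax) with strictly increasing
    dates and tmin <= tmax; ``rainfall`` maps env -> DataFrame(date, mm).
    """

    temps: dict
    rainfall: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for env, t in self.temps.items():
            if not {"date", "tmin", "tmax"}.issubset(t.columns):
                raise ValueError(f"temperature table for {env!r} needs date/tmin/tmax")
            d = pd.to_datetime(t["date"])
            if not d.is_monotonic_increasing or d.duplicated().any():
                raise ValueError(f"dates not strictly increasing for {env!r}")
            if (t["tmin"] > t["tmax"]).any():
                bad = t.loc[t["tmin"] > t["tmax"], "date"].iloc[0]
                raise ValueError(f"tmin > tmax on {bad} in {env!r}")

    def env_temps(self, env) -> pd.DataFrame:
        return self.temps[env]


@dataclass(frozen=True)
class QTLEffect:
    """One planted locus effect for simulation.

    ``kind`` is ``"performance"`` (stable additive effect, trait units per
    allele score) or ``"responsiveness"`` (trait units per allele score per
    covariate unit, requires ``covariate``).
    """

    marker: str
    kind: str
    size: float
    covariate: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("performance", "responsiveness"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "responsiveness" and not self.covariate:
            raise ValueError("responsiveness effect needs a covariate name")
        if self.kind == "performance" and self.covariate:
            raise ValueError("performance effect takes no covariate")
        if not np.isfinite(self.size):
            raise ValueError("effect size must be finite")


@dataclass(frozen=True)
class QTLSpec:
    """Collection of planted QTL effects, validated against a map."""

    effects: Sequence[QTLEffect]

    def validate_against(self, linkage_map: LinkageMap) -> None:
        known = set(linkage_map.markers)
        for e in self.effects:
            if e.marker not in known:
                raise ValueError(f"planted QTL marker {e.marker!r} not on the map")

    @property
    def performance(self) -> list[QTLEffect]:
        return [e for e in self.effects if e.kind == "performance"]

    @property
    def responsiveness(self) -> list[QTLEffect]:
        return [e for e in self.effects if e.kind == "responsiveness"]


@dataclass(frozen=True)
class TraitObservations:
    """Plot-aligned trait values: one response per design row (nan allowed)."""

    design: FieldDesign
    values: pd.Series
    trait: str = "yield"

    def __post_init__(self) -> None:
        if len(self.values) != self.design.n_plots:
            raise ValueError("one response per design plot required")
        v = self.values.to_numpy(float)
        if np.isinf(v).any():
            raise ValueError("responses must be finite where present")

    def frame(self) -> pd.DataFrame:
        out = self.design.table.copy()
        out[self.trait] = self.values.to_numpy(float)
        return out


@dataclass(frozen=True)
class FAParams:
    """Factor-analytic G x E covariance: Delta = Lambda Lambda^T + Psi.

    ``loadings`` is t x k (environment loadings), ``specific`` the t
    environment-specific variances (diagonal of Psi).
    """

    loadings: np.ndarray
    specific: np.ndarray

    def __post_init__(self) -> None:
        lam = np.atleast_2d(np.asarray(self.loadings, float))
        psi = np.asarray(self.specific, float)
        if lam.shape[0] != psi.shape[0]:
            raise ValueError("loadings and specific variances disagree on t")
        if (psi < 0).any():
            raise ValueError("specific variances must be non-negative")
        object.__setattr__(self, "loadings", lam)
        object.__setattr__(self, "specific", psi)

    @property
    def n_env(self) -> int:
        return self.loadings.shape[0]

    @property
    def order(self) -> int:
        return self.loadings.shape[1]

    def covariance(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.specific)

    def correlations(self) -> np.ndarray:
        cov = self.covariance()
        sd = np.sqrt(np.diag(cov))
        if (sd == 0).any():
            raise ValueError("zero genetic variance environment: correlations undefined")
        return cov / np.outer(sd, sd)


@dataclass(frozen=True)
class SpatialParams:
    """Per-environment residual variance and AR1 autocorrelations.

    Maps env -> (sigma2, rho_row, rho_col); |rho| < 1, sigma2 > 0.
    """

    params: dict

    def __post_init__(self) -> None:
        for env, (s2, rr, rc) in self.params.items():
            if s2 <= 0:
                raise ValueError(f"sigma2 must be positive in {env!r}")
            if not (abs(rr) < 1 and abs(rc) < 1):
                raise ValueError(f"|rho| must be < 1 in {env!r}")

    def for_env(self, env) -> tuple[float, float, float]:
        return self.params[env]
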