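"""QTL clustering and the adaptation framework.

Detected loci are grouped into clusters by single-linkage chaining of
positions within 10 cM on a chromosome, flagged when they co-locate with
anthesis-date QTL (so maturity-driven escape can be separated from intrinsic
tolerance), and classified on two axes:

* performance: the sign of a co-located stable (performance) effect —
  high / neutral / low for the reference parent's allele;
* responsiveness: the sign of co-located marker-by-temperature-covariate
  effects — positive / non-responsive / negative, with the rainfall
  covariate's sign reported separately (temperature and rainfall responses
  of opposite sign are the classic drought/heat G x E pattern).

A locus whose favourable performance allele is also the more heat-sensitive
one is in repulsion (selecting performance buys sensitivity); matching signs
are in coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .scan import QTLRecord

__all__ = [
    "QTLCluster",
    "FrameworkLabel",
    "cluster_qtl",
    "flag_anthesis_association",
    "classify_framework",
    "qtl_summary_table",
]

#: temperature-based covariates (rainfall is classified separately)
TEMPERATURE_COVARIATES = (
    "anthesis_avg_max",
    "anthesis_days_gt30",
    "grainfill_avg_max",
    "grainfill_days_gt30",
    "grainfill_days_gt35",
)


@dataclass
class QTLCluster:
    """Single-linkage cluster of QTL within a chaining window on one chromosome."""

    chrom: str
    members: list
    contains_anthesis_qtl: bool = False
    labels: dict = field(default_factory=dict)

    @property
    def span_cM(self) -> tuple[float, float]:
        pos = [m.pos_cM for m in self.members]
        return (min(pos), max(pos))

    @property
    def position_cM(self) -> float:
        lo, hi = self.span_cM
        return (lo + hi) / 2.0

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FrameworkLabel:
    """Two-axis adaptation label for a locus (one trait)."""

    performance: str       # "high" | "neutral" | "low"
    responsiveness: str    # "positive" | "non-responsive" | "negative" | "mixed"
    rainfall_response: str  # "positive" | "none" | "negative"
    linkage: str           # "coupling" | "repulsion" | "n/a"

    def describe(self) -> str:
        perf = {"high": "high-performance value", "low": "low-performance value",
                "neutral": "mean performance value"}[self.performance]
        resp = {"positive": "positive response", "negative": "negative response",
                "non-responsive": "non-responsive", "mixed": "mixed response"}[
            self.responsiveness]
        return f"{resp} with {perf}"


def cluster_qtl(records: list, window_cM: float = 10.0) -> list[QTLCluster]:
    """Single-linkage clusters: members chained by <= window_cM gaps.

    Order of the input records does not affect membership; singletons come
    back as one-member clusters.
    """
    by_chrom: dict = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    clusters = []
    for chrom in sorted(by_chrom, key=str):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.pos_cM, r.name))
        current = [recs[0]]
        for rec in recs[1:]:
            if rec.pos_cM - current[-1].pos_cM <= window_cM:
                current.append(rec)
            else:
                clusters.append(QTLCluster(chrom, current))
                current = [rec]
        clusters.append(QTLCluster(chrom, current))
    return clusters


def flag_anthesis_association(
    clusters: list[QTLCluster],
    anthesis_qtl: list,
    window_cM: float = 10.0,
) -> list[QTLCluster]:
    """Mark clusters with any member within window_cM of an anthesis-date QTL."""
    for cl in clusters:
        hits = [
            a for a in anthesis_qtl
            if a.chrom == cl.chrom and any(
                abs(a.pos_cM - m.pos_cM) <= window_cM for m in cl.members
            )
        ]
        cl.contains_anthesis_qtl = bool(hits)
    return clusters


def _sign_label(effects: list[float], pos: str, none: str, neg: str) -> str:
    if not effects:
        return none
    signs = {e > 0 for e in effects if e != 0}
    if len(signs) > 1:
        return "mixed"
    return pos if effects[0] > 0 else neg


def classify_framework(cluster: QTLCluster) -> dict:
    """Per-trait two-axis labels for one cluster.

    Effects must already be oriented to a common reference parent (the
    package reports effects on the +1 allele of parent A throughout).
    Conflicting signs among co-located temperature-responsiveness QTL yield
    the explicit label "mixed" rather than a silent resolution.
    """
    traits = sorted({m.trait for m in cluster.members})
    labels = {}
    for trait in traits:
        perf = [m.effect for m in cluster.members
                if m.trait == trait and m.qtl_type == "performance"]
        temp = [m.effect for m in cluster.members
                if m.trait == trait and m.qtl_type == "responsiveness"
                and m.covariate in TEMPERATURE_COVARIATES]
        rain = [m.effect for m in cluster.members
                if m.trait == trait and m.qtl_type == "responsiveness"
                and m.covariate == "gs_rainfall"]
        perf_label = _sign_label(perf, "high", "neutral", "low")
        resp_label = _sign_label(temp, "positive", "non-responsive", "negative")
        rain_label = _sign_label(rain, "positive", "none", "negative")
        if perf_label in ("high", "low") and resp_label in ("positive", "negative"):
            same = (perf_label == "high") == (resp_label == "positive")
            linkage = "coupling" if same else "repulsion"
        else:
            linkage = "n/a"
        labels[trait] = FrameworkLabel(perf_label, resp_label, rain_label, linkage)
    cluster.labels = labels
    return labels


def qtl_summary_table(records: list) -> pd.DataFrame:
    """Flat report table: one row per detected QTL."""
    rows = []
    for r in records:
        rows.append({
            "name": r.name,
            "trait": r.trait,
            "population": r.population,
            "type": r.qtl_type,
            "covariate": r.covariate or "",
            "chrom": r.chrom,
            "pos_cM": round(r.pos_cM, 2),
            "marker": r.marker or "",
            "effect": r.effect,
            "se": r.se,
            "normalised_effect": "" if r.normalised_effect is None
            else r.normalised_effect,
            "pvalue": r.pvalue,
            "LOD": round(r.lod, 2),
            "positive_allele_parent": r.positive_allele_parent or "",
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["trait", "chrom", "pos_cM"]).reset_index(drop=True)
    return out
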