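"""Marker preparation: encoding, imputation, interval markers, GRMs.

Raw biparental allele calls become the analysis-ready real-valued interval
marker matrix M in four steps:

1. encode AA -> +1, BB -> -1 (missing preserved);
2. impute missing scores by their conditional expectation given the nearest
   observed flanking markers under the no-interference DH Markov chain
   (Haldane distances from the map);
3. collapse markers that are identical in both map position and score vector;
4. build one pseudo-marker per interval between adjacent unique positions
   (mean of the flanking scores, placed at the interval midpoint), keeping
   chromosome-terminal markers as their own scannable columns.

Leave-one-chromosome-out genomic relationship matrices G_{-i} = M_{-i}
M_{-i}^T (no marker-count scaling; the additive variance component absorbs
scale) feed the genome scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import haldane
from .types import GenotypeMatrix, LinkageMap

__all__ = [
    "IntervalMarkerMatrix",
    "GenomicRelationship",
    "MapSummary",
    "encode_alleles",
    "impute_missing",
    "collapse_unique",
    "make_interval_markers",
    "compute_map_summary",
    "compute_grm",
]


@dataclass(frozen=True)
class IntervalMarkerMatrix:
    """Lines x interval-marker scores in [-1, +1], with column metadata.

    ``info`` has one row per column of ``scores``: ``chrom``, ``pos_cM``,
    ``left``/``right`` flank marker names and ``kind`` ("interval" for the
    flanking-mean pseudo-markers, "marker" for carried-through terminals), so
    an alternative interval-marker algebra can be swapped in without losing
    the flank bookkeeping.
    """

    scores: pd.DataFrame
    info: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(self.info.index):
            raise ValueError("interval-marker metadata must align with columns")
        vals = self.scores.to_numpy(float)
        if np.isnan(vals).any():
            raise ValueError("interval markers must be complete")
        if (np.abs(vals) > 1.0 + 1e-12).any():
            raise ValueError("interval scores must lie in [-1, +1]")

    @property
    def lines(self) -> pd.Index:
        return self.scores.index

    @property
    def n_markers(self) -> int:
        return self.scores.shape[1]

    def chrom_markers(self, chrom) -> list:
        return list(self.info.index[self.info["chrom"] == chrom])

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(float)


@dataclass(frozen=True)
class GenomicRelationship:
    """r x r relationship matrix M M^T with a record of what was excluded."""

    matrix: np.ndarray
    lines: pd.Index
    excluded: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.lines):
            raise ValueError("GRM must be square and match the line index")
        if not np.allclose(m, m.T, atol=1e-8 * (1 + np.abs(m).max())):
            raise ValueError("GRM must be symmetric")
        object.__setattr__(self, "matrix", m)

    def is_psd(self, rtol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh(self.matrix)
        return bool(w.min() >= -rtol * max(np.trace(self.matrix), 1.0))


@dataclass(frozen=True)
class MapSummary:
    """Per-map counts and lengths mirroring a published map-summary table."""

    n_markers: int
    n_unique_positions: int
    length_cM: float
    mean_interval_cM: float

    def report(self) -> dict:
        return {
            "n_markers": self.n_markers,
            "n_unique_positions": self.n_unique_positions,
            "length_cM": round(self.length_cM, 0),
            "mean_interval_cM": round(self.mean_interval_cM, 1),
        }


_MISSING_TOKENS = {"", "NA", "na", "-", None}


def encode_alleles(raw_calls: pd.DataFrame, linkage_map: LinkageMap) -> GenotypeMatrix:
    """Numeric encoding of DH allele calls: A -> +1, B -> -1, missing -> nan."""
    out = np.empty(raw_calls.shape)
    arr = raw_calls.to_numpy(object)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            v = arr[i, j]
            if isinstance(v, float) and np.isnan(v):
                out[i, j] = np.nan
            elif v in _MISSING_TOKENS:
                out[i, j] = np.nan
            elif v == "A":
                out[i, j] = 1.0
            elif v == "B":
                out[i, j] = -1.0
            else:
                raise ValueError(
                    f"invalid allele call {v!r} at line {raw_calls.index[i]!r}, "
                    f"marker {raw_calls.columns[j]!r} (expected A/B/missing)"
                )
    frame = pd.DataFrame(out, index=raw_calls.index, columns=raw_calls.columns)
    return GenotypeMatrix(frame, linkage_map)


def _dh_flank_expectation(x_left, th_left, x_right, th_right):
    """E[score] for a missing DH locus given both observed flanks.

    Path probabilities of the two-state chain: the locus agrees with a flank
    with probability (1 - theta) and disagrees with probability theta.
    """
    a_plus = np.where(x_left > 0, 1 - th_left, th_left)
    a_minus = np.where(x_left > 0, th_left, 1 - th_left)
    b_plus = np.where(x_right > 0, 1 - th_right, th_right)
    b_minus = np.where(x_right > 0, th_right, 1 - th_right)
    num = a_plus * b_plus - a_minus * b_minus
    den = a_plus * b_plus + a_minus * b_minus
    return num / den


def impute_missing(genotypes: GenotypeMatrix, linkage_map: LinkageMap) -> GenotypeMatrix:
    """Fill missing scores with flanking-marker conditional expectations.

    Both flanks observed: expectation of the two-state DH chain conditioned
    on the nearest observed markers either side (Haldane recombination
    fractions from map distances). One flank only: x * (1 - 2 theta). A line
    with a fully missing chromosome cannot be imputed and is reported.
    """
    scores = genotypes.values().copy()
    cols = list(genotypes.scores.columns)
    col_idx = {m: j for j, m in enumerate(cols)}
    failures = []
    for chrom in linkage_map.chromosomes:
        sub = linkage_map.table[linkage_map.table["chrom"] == chrom]
        idx = np.array([col_idx[m] for m in sub["marker"]])
        pos = sub["pos_cM"].to_numpy(float)
        block = scores[:, idx]
        miss = np.isnan(block)
        if not miss.any():
            continue
        for i in np.flatnonzero(miss.any(axis=1)):
            obs = np.flatnonzero(~miss[i])
            if obs.size == 0:
                failures.append((genotypes.lines[i], chrom))
                continue
            gaps = np.flatnonzero(miss[i])
            # nearest observed flank on each side, by map order
            right_ptr = np.searchsorted(obs, gaps)
            has_right = right_ptr < obs.size
            has_left = right_ptr > 0
            left = obs[np.clip(right_ptr - 1, 0, obs.size - 1)]
            right = obs[np.clip(right_ptr, 0, obs.size - 1)]
            th_l = haldane(pos[gaps] - pos[left])
            th_r = haldane(pos[right] - pos[gaps])
            both = has_left & has_right
            est = np.empty(gaps.size)
            est[both] = _dh_flank_expectation(
                block[i, left[both]], th_l[both], block[i, right[both]], th_r[both]
            )
            only_l = has_left & ~has_right
            est[only_l] = block[i, left[only_l]] * (1 - 2 * th_l[only_l])
            only_r = has_right & ~has_left
            est[only_r] = block[i, right[only_r]] * (1 - 2 * th_r[only_r])
            block[i, gaps] = est
        scores[:, idx] = block
    if failures:
        listed = ", ".join(f"{l}/{c}" for l, c in failures[:5])
        raise ValueError(
            f"{len(failures)} line x chromosome blocks fully missing "
            f"(cannot impute): {listed}"
        )
    frame = pd.DataFrame(scores, index=genotypes.lines, columns=cols)
    return GenotypeMatrix(frame, linkage_map)


def collapse_unique(
    genotypes: GenotypeMatrix, linkage_map: LinkageMap
) -> tuple[GenotypeMatrix, LinkageMap]:
    """Drop markers duplicating both map position and score vector.

    Among markers sharing a chromosome, position and an identical score
    vector, the first in map order is retained. Co-located markers with
    differing score vectors are all kept. Idempotent.
    """
    vals = genotypes.values()
    if np.isnan(vals).any():
        raise ValueError("collapse requires complete genotypes (impute first)")
    seen: dict = {}
    keep = []
    for j, row in enumerate(linkage_map.table.itertuples(index=False)):
        key = (row.chrom, float(row.pos_cM), vals[:, j].tobytes())
        if key not in seen:
            seen[key] = j
            keep.append(j)
    new_map = LinkageMap(linkage_map.table.iloc[keep].reset_index(drop=True))
    new_scores = genotypes.scores.iloc[:, keep]
    return GenotypeMatrix(new_scores, new_map), new_map


def make_interval_markers(
    genotypes: GenotypeMatrix, linkage_map: LinkageMap
) -> IntervalMarkerMatrix:
    """Flanking-mean pseudo-markers at interval midpoints.

    For each pair of adjacent unique positions the interval marker scores the
    mean of the two flanking markers and sits at the midpoint. Terminal
    markers of each chromosome are carried through unchanged so chromosome
    ends remain scannable; a single-marker chromosome passes its marker
    through with no interval.
    """
    vals = genotypes.values()
    if np.isnan(vals).any():
        raise ValueError("interval markers require complete genotypes")
    cols, infos, datas = [], [], []
    col_idx = {m: j for j, m in enumerate(genotypes.scores.columns)}
    for chrom in linkage_map.chromosomes:
        sub = linkage_map.table[linkage_map.table["chrom"] == chrom]
        names = list(sub["marker"])
        pos = sub["pos_cM"].to_numpy(float)
        # one representative per unique position (first in map order)
        uniq_idx = np.flatnonzero(np.concatenate([[True], np.diff(pos) > 0]))
        rep = [names[i] for i in uniq_idx]
        upos = pos[uniq_idx]
        # terminal markers carried through
        for term, label in ((0, "start"), (len(rep) - 1, "end")):
            name = f"{chrom}_t{label}_{rep[term]}"
            if len(rep) == 1 and label == "end":
                continue
            cols.append(name)
            infos.append((chrom, float(upos[term]), rep[term], rep[term], "marker"))
            datas.append(vals[:, col_idx[rep[term]]])
        for j in range(len(rep) - 1):
            left, right = rep[j], rep[j + 1]
            name = f"{chrom}_iv{j + 1}"
            cols.append(name)
            infos.append(
                (chrom, float((upos[j] + upos[j + 1]) / 2.0), left, right, "interval")
            )
            datas.append((vals[:, col_idx[left]] + vals[:, col_idx[right]]) / 2.0)
    info = pd.DataFrame(
        infos, index=pd.Index(cols, name="interval_marker"),
        columns=["chrom", "pos_cM", "left", "right", "kind"],
    )
    # keep columns in chromosome/position order
    order = info.sort_values(["chrom", "pos_cM"], kind="stable").index
    scores = pd.DataFrame(np.column_stack(datas), index=genotypes.lines, columns=cols)
    return IntervalMarkerMatrix(scores[order], info.loc[order])


def compute_map_summary(linkage_map: LinkageMap, genotypes: GenotypeMatrix | None = None) -> MapSummary:
    """Marker count, unique positions, genetic length and mean interval.

    Length is the sum over chromosomes of (max - min position); the mean
    interval divides the length by the unique-position count.
    """
    if linkage_map.n_markers == 0:
        raise ValueError("empty linkage map")
    t = linkage_map.table
    length = float(sum(g["pos_cM"].max() - g["pos_cM"].min()
                       for _, g in t.groupby("chrom", sort=False)))
    n_unique = int(t.drop_duplicates(subset=["chrom", "pos_cM"]).shape[0])
    return MapSummary(
        n_markers=linkage_map.n_markers,
        n_unique_positions=n_unique,
        length_cM=length,
        mean_interval_cM=length / n_unique,
    )


def compute_grm(
    M: IntervalMarkerMatrix,
    exclude_chrom=None,
    exclude_windows=None,
) -> GenomicRelationship:
    """G = M M^T over the retained interval-marker columns.

    ``exclude_chrom`` drops a whole chromosome (the leave-one-chromosome-out
    G_{-i} of the scan); ``exclude_windows`` is a list of (chrom, start_cM,
    end_cM) spans to drop (the G_{-s} of the final model). No division by
    marker count: the additive variance component carries the scale.
    """
    info = M.info
    keep = np.ones(len(info), bool)
    tags = []
    if exclude_chrom is not None:
        keep &= (info["chrom"] != exclude_chrom).to_numpy()
        tags.append(f"chrom {exclude_chrom}")
    for chrom, lo, hi in exclude_windows or []:
        inside = (info["chrom"] == chrom) & (info["pos_cM"] >= lo) & (info["pos_cM"] <= hi)
        keep &= ~inside.to_numpy()
        tags.append(f"{chrom}:[{lo:g},{hi:g}]cM")
    if not keep.any():
        raise ValueError("exclusion leaves no interval markers")
    X = M.values()[:, keep]
    return GenomicRelationship(X @ X.T, M.lines, "; ".join(tags) or "none")
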