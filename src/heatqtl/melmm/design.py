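"""Design matrices for the multi-environment linear mixed model.

The fixed component holds environment means and environment-specific check
(parent / control variety) effects; the genetic indicator Z_g maps DH plots
to environment-major genotype-by-environment effects (checks are excluded
from Z_g and handled as fixed levels). Optional independent random design
terms (replicate blocks, row and column effects within each environment)
absorb extraneous field trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from ..types import FieldDesign, TraitObservations

__all__ = ["IIDTerm", "ModelSpec", "build_design"]


@dataclass
class IIDTerm:
    """One independent random design term with a single variance parameter."""

    name: str
    Z: sparse.csr_matrix
    n_levels: int


@dataclass
class ModelSpec:
    """Analysis-ready arrays for one trait's ME-LMM.

    Plots with missing responses are dropped before assembly. Environments
    are ordered as in the field design; u_g is environment-major.
    """

    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    Zg: sparse.csr_matrix
    lines: pd.Index
    envs: list
    env_of_plot: np.ndarray
    layout: dict  # env -> (cols array, rows array) in plot order
    extra_terms: list = field(default_factory=list)
    design: FieldDesign | None = None
    plot_index: np.ndarray | None = None

    @property
    def n_plots(self) -> int:
        return len(self.y)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_env(self) -> int:
        return len(self.envs)

    def env_rows(self, e_idx: int) -> np.ndarray:
        return np.flatnonzero(self.env_of_plot == e_idx)


def build_design(
    observations: TraitObservations,
    design: FieldDesign,
    dh_lines=None,
    row_effects: bool = False,
    col_effects: bool = False,
    block_factor: str | None = None,
) -> ModelSpec:
    """Assemble the ME-LMM design from plot observations and the field layout.

    ``dh_lines`` fixes the genotype index (e.g. the genotyped lines); by
    default the design's non-check genotypes in order of appearance. Checks
    become per-environment fixed levels. ``row_effects`` / ``col_effects``
    add per-environment iid random row/column terms; ``block_factor`` names a
    design column holding replicate blocks (one random term per
    environment).
    """
    if observations.design is not design and observations.design.n_plots != design.n_plots:
        raise ValueError("observations and design do not align plot-for-plot")
    tbl = design.table.reset_index(drop=True)
    y_all = observations.values.to_numpy(float)
    keep = ~np.isnan(y_all)
    tbl = tbl[keep].reset_index(drop=True)
    y = y_all[keep]
    envs = list(dict.fromkeys(tbl["env"]))
    env_idx = {e: i for i, e in enumerate(envs)}
    if dh_lines is None:
        dh_lines = pd.Index(dict.fromkeys(tbl.loc[~tbl["is_check"], "genotype"]).keys())
    else:
        dh_lines = pd.Index(dh_lines)
    line_idx = {l: i for i, l in enumerate(dh_lines)}
    checks = list(dict.fromkeys(tbl.loc[tbl["is_check"], "genotype"]))
    for row in tbl.itertuples():
        if not row.is_check and row.genotype not in line_idx:
            raise ValueError(
                f"genotype {row.genotype!r} at plot ({row.env}, c{row.column}, "
                f"r{row.row}) is neither a DH line nor a check"
            )
    n = len(tbl)
    r, t = len(dh_lines), len(envs)
    env_of_plot = tbl["env"].map(env_idx).to_numpy()

    # fixed: environment means, then check x environment levels
    fixed_cols = []
    fixed_names = []
    for e in envs:
        fixed_cols.append((tbl["env"] == e).to_numpy(float))
        fixed_names.append(f"mean({e})")
    for c in checks:
        for e in envs:
            col = ((tbl["genotype"] == c) & (tbl["env"] == e)).to_numpy(float)
            if col.any():
                fixed_cols.append(col)
                fixed_names.append(f"check({c},{e})")
    X = np.column_stack(fixed_cols)

    # genetic indicator: plot -> (env-major) genotype-by-environment effect
    dh_mask = ~tbl["is_check"].to_numpy()
    rows_i = np.flatnonzero(dh_mask)
    cols_i = np.array(
        [env_of_plot[i] * r + line_idx[tbl["genotype"].iloc[i]] for i in rows_i],
        dtype=int,
    )
    Zg = sparse.csr_matrix(
        (np.ones(len(rows_i)), (rows_i, cols_i)), shape=(n, r * t)
    )

    layout = {}
    for e in envs:
        sel = tbl["env"] == e
        layout[e] = (tbl.loc[sel, "column"].to_numpy(), tbl.loc[sel, "row"].to_numpy())

    extra = []
    def _add_factor_terms(label: str, series: pd.Series) -> None:
        for e in envs:
            sel = (tbl["env"] == e).to_numpy()
            vals = series[sel]
            levels = {v: i for i, v in enumerate(dict.fromkeys(vals))}
            if len(levels) < 2:
                continue
            rows_f = np.flatnonzero(sel)
            cols_f = np.array([levels[v] for v in vals])
            Z = sparse.csr_matrix(
                (np.ones(len(rows_f)), (rows_f, cols_f)), shape=(n, len(levels))
            )
            extra.append(IIDTerm(f"{label}({e})", Z, len(levels)))

    if block_factor is not None:
        if block_factor not in tbl.columns:
            raise ValueError(f"design has no column {block_factor!r}")
        _add_factor_terms(block_factor, tbl[block_factor])
    if row_effects:
        _add_factor_terms("row", tbl["row"])
    if col_effects:
        _add_factor_terms("column", tbl["column"])

    return ModelSpec(
        y=y, X=X, fixed_names=fixed_names, Zg=Zg, lines=dh_lines, envs=envs,
        env_of_plot=env_of_plot, layout=layout, extra_terms=extra,
        design=design, plot_index=np.flatnonzero(keep),
    )
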