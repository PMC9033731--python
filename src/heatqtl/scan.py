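"""Two-run whole-genome QTL scan over the multi-environment mixed model.

Run 1 (performance) tests, at every interval marker, a fixed marker effect
that is constant across environments. Run 2 (responsiveness) replaces the
regressor by the elementwise product of a climatic covariate and the marker
score, so the tested effect is a trait response per covariate unit. Both
runs extend the baseline model with two polygenic guards: a marker-based
additive G x E term with covariance Delta_a (x) G_{-i} (genomic relationship
of all chromosomes except the scanned one, avoiding proximal contamination)
and a residual polygenic G x E term with covariance Delta_p (x) I.

Marker significance uses Wald statistics against a genome-wide threshold
from the effective number of independent tests (eigenvalues of the marker
correlation matrix, summed per chromosome). Significant markers within
30 cM of a more significant one are pruned, and survivors enter a joint
final model whose genomic term excludes all markers within 30 cM of any
selected marker. Responsiveness effects are additionally reported on the
scale of the covariate's observed numerical range.

Variance parameters are re-estimated once per chromosome under the null and
held fixed across that chromosome's markers (``vc_mode="chromosome"``, the
default); ``"global"`` estimates them once genome-wide, ``"per_marker"``
re-fits REML at every marker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .markers import IntervalMarkerMatrix, compute_grm
from .melmm import (
    FitResult,
    GxECov,
    MixedModel,
    ModelSpec,
    REMLOptions,
    default_delta,
)
from .melmm.gxe import DiagDelta
from .phenology import ClimaticCovariate

__all__ = [
    "ScanConfig",
    "ScanResult",
    "ThresholdSpec",
    "QTLRecord",
    "lod_from_wald",
    "li_ji_threshold",
    "scan_genome",
    "scan_genome_multi",
    "prune_30cM",
    "fit_final_model",
    "normalise_effect",
    "qtl_analysis",
]


@dataclass
class ScanConfig:
    """Controls for a genome-scan run."""

    alpha: float = 0.05
    prune_window_cM: float = 30.0
    grm_exclusion_cM: float = 30.0
    vc_mode: str = "chromosome"  # "chromosome" | "global" | "per_marker"
    fa_order: int | None = None  # None = baseline rule (1 if t<=4 else 2)
    reml: REMLOptions = field(default_factory=lambda: REMLOptions(tol=1e-5, max_iter=60))


@dataclass(frozen=True)
class ScanResult:
    """Per-marker scan statistics for one run.

    ``table`` columns: marker, chrom, pos_cM, kind, covariate, effect, se,
    wald, pvalue, untestable.
    """

    table: pd.DataFrame
    kind: str
    covariate: str | None = None

    def max_wald(self) -> pd.Series:
        ok = self.table[~self.table["untestable"]]
        return ok.loc[ok["wald"].idxmax()]


@dataclass(frozen=True)
class ThresholdSpec:
    """Genome-wide significance threshold from effective test count."""

    alpha: float
    m_eff: float
    per_test_alpha: float
    wald_threshold: float
    per_chromosome: dict


@dataclass(frozen=True)
class QTLRecord:
    """One detected locus, typed as performance or responsiveness."""

    name: str
    trait: str
    population: str
    qtl_type: str
    covariate: str | None
    chrom: str
    pos_cM: float
    effect: float
    se: float
    wald: float
    pvalue: float
    lod: float
    normalised_effect: float | None = None
    positive_allele_parent: str | None = None
    marker: str | None = None

    def __post_init__(self):
        if self.qtl_type == "responsiveness" and self.covariate is None:
            raise ValueError("responsiveness record needs a covariate")
        if self.qtl_type == "performance" and (
            self.covariate is not None or self.normalised_effect is not None
        ):
            raise ValueError("performance record carries no covariate or "
                             "normalised effect")


def lod_from_wald(wald: float) -> float:
    """LOD support from a 1-df Wald statistic: wald / (2 ln 10)."""
    if wald < 0:
        raise ValueError("Wald statistic must be >= 0")
    return wald / (2.0 * math.log(10.0))


def li_ji_threshold(M: IntervalMarkerMatrix, alpha: float = 0.05) -> ThresholdSpec:
    """Effective-test-count threshold from marker-correlation eigenvalues.

    Per chromosome, eigenvalues of the interval-marker correlation matrix
    contribute 1(lambda >= 1) + (lambda - floor(lambda)); summing over
    chromosomes gives the genome-wide effective test count M_eff, the
    per-test level 1 - (1-alpha)^(1/M_eff), and the chi-square(1) Wald
    threshold at that level.
    """
    if M.n_markers < 2:
        raise ValueError("need at least 2 interval markers")
    per_chrom = {}
    for chrom in dict.fromkeys(M.info["chrom"]):
        cols = M.chrom_markers(chrom)
        X = M.scores[cols].to_numpy(float)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"{(~keep).sum()} zero-variance interval markers on "
                f"chromosome {chrom} excluded from the threshold calculation"
            )
        X = X[:, keep]
        if X.shape[1] == 0:
            per_chrom[chrom] = 0.0
            continue
        corr = np.corrcoef(X, rowvar=False)
        corr = np.atleast_2d(corr)
        lam = np.linalg.eigvalsh(corr)
        # round before the integer-part rule: an eigenvalue a hair below an
        # exact integer (e.g. 2 - 1e-10 from a duplicated marker) must not
        # contribute a spurious fractional part of ~1
        lam = np.clip(np.round(lam, 8), 0.0, None)
        per_chrom[chrom] = float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    m_eff = float(sum(per_chrom.values()))
    per_test = 1.0 - (1.0 - alpha) ** (1.0 / m_eff)
    wald_thr = float(stats.chi2.isf(per_test, df=1))
    return ThresholdSpec(alpha, m_eff, per_test, wald_thr, per_chrom)


# ----------------------------------------------------------------------
def _dh_incidence(spec: ModelSpec) -> np.ndarray:
    """n x r incidence of plots onto DH lines (checks: zero rows)."""
    r, t = spec.n_lines, spec.n_env
    Zg = spec.Zg
    A = np.zeros((spec.n_plots, r))
    rows, cols = Zg.nonzero()
    A[rows, cols % r] = 1.0
    return A


def _plot_covariate(spec: ModelSpec, cov: ClimaticCovariate) -> np.ndarray:
    """Covariate value per plot (0 on check plots)."""
    r = spec.n_lines
    c = np.zeros(spec.n_plots)
    rows, cols = spec.Zg.nonzero()
    for i, j in zip(rows, cols):
        env = spec.envs[j // r]
        line = spec.lines[j % r]
        c[i] = cov.loc(line, env)
    return c


def _scan_gxe(spec: ModelSpec, G: np.ndarray | None, config: ScanConfig) -> GxECov:
    """Additive + polygenic G x E pair for the scan's null model.

    Delta_p follows the baseline FA-order rule: it must carry the
    cross-environment genetic covariance, which a constant-across-
    environments marker effect otherwise mimics (a diagonal Delta_p inflates
    the scan's false-positive rate badly). Delta_a is kept diagonal: the
    additive kernel term often sits at or near its zero boundary, where a
    factor-analytic surface is a saddle.
    """
    t = spec.n_env
    dp = default_delta(t, config.fa_order)
    if G is None:
        return GxECov([("p", dp, None)], spec.n_lines)
    terms = [("a", DiagDelta(t), G), ("p", dp, None)]
    return GxECov(terms, spec.n_lines)


def _start_from(model: MixedModel, baseline: FitResult | None,
                prev_theta: np.ndarray | None) -> np.ndarray | None:
    """Warm start: previous chromosome's estimates, else baseline residuals."""
    if prev_theta is not None and len(prev_theta) == len(model.init_theta()):
        return prev_theta
    if baseline is None:
        return None
    theta = model.init_theta()
    nres = model.n_resid_params
    b_nres = baseline.model.n_resid_params
    if nres == b_nres:
        theta[len(theta) - nres:] = baseline.theta[len(baseline.theta) - nres:]
    return theta


def _marker_stats(m: np.ndarray, v: np.ndarray, S: np.ndarray) -> tuple:
    denom = float(m @ S @ m)
    if denom <= 1e-10 * max(np.trace(S), 1e-300):
        return np.nan, np.nan, np.nan, np.nan, True
    num = float(m @ v)
    effect = num / denom
    se = 1.0 / math.sqrt(denom)
    wald = num * num / denom
    return effect, se, wald, float(stats.chi2.sf(wald, df=1)), False


def _check_run(spec: ModelSpec, kind: str, covariate) -> None:
    if kind not in ("performance", "responsiveness"):
        raise ValueError(f"unknown scan kind {kind!r}")
    if kind == "responsiveness":
        if covariate is None:
            raise ValueError("responsiveness scan needs a covariate")
        if covariate.range() <= 0:
            raise ValueError(
                f"covariate {covariate.name!r} is constant (range 0): a "
                "responsiveness effect per covariate unit is undefined"
            )
        for line in spec.lines:
            if line not in covariate.wide.index:
                raise ValueError(f"covariate {covariate.name!r} missing line {line!r}")


def scan_genome_multi(
    spec: ModelSpec,
    M: IntervalMarkerMatrix,
    runs: list,
    baseline: FitResult | None = None,
    config: ScanConfig | None = None,
) -> tuple[list[ScanResult], np.ndarray | None]:
    """Several scan runs over one set of shared null models.

    The chromosome-null model (variance parameters, projections) does not
    depend on the scan regressor, so the performance run and every
    responsiveness covariate run share each chromosome's REML fit. ``runs``
    is a list of (kind, covariate-or-None). Returns the ScanResults in run
    order plus the last null-model parameter vector (a warm start for final
    models).
    """
    config = config or ScanConfig()
    for kind, covariate in runs:
        _check_run(spec, kind, covariate)
    if list(M.lines) != list(spec.lines):
        raise ValueError("interval markers and design disagree on lines")

    A0 = _dh_incidence(spec)
    regressors = []
    for kind, covariate in runs:
        if kind == "responsiveness":
            regressors.append(A0 * _plot_covariate(spec, covariate)[:, None])
        else:
            regressors.append(A0)

    chroms = list(dict.fromkeys(M.info["chrom"]))
    global_theta = None
    if config.vc_mode == "global":
        G_all = compute_grm(M).matrix
        gxe = _scan_gxe(spec, G_all, config)
        model = MixedModel(spec, gxe, config.reml)
        fit = model.fit(start=_start_from(model, baseline, None))
        global_theta = fit.theta

    per_run_rows: list[list] = [[] for _ in runs]
    prev_theta = global_theta
    for chrom in chroms:
        if len(chroms) > 1:
            G = compute_grm(M, exclude_chrom=chrom).matrix
        else:
            G = compute_grm(M).matrix
        gxe = _scan_gxe(spec, G, config)
        model = MixedModel(spec, gxe, config.reml)
        if config.vc_mode == "global":
            model.state = model._evaluate(model.clamp(global_theta))
        else:
            fit = model.fit(start=_start_from(model, baseline, prev_theta))
            prev_theta = fit.theta
        st = model.state
        info = M.info
        for run_i, ((kind, covariate), A) in enumerate(zip(runs, regressors)):
            PA = model.p_apply(A)
            S = A.T @ PA
            v = A.T @ st.Py
            for name in M.chrom_markers(chrom):
                m = M.scores[name].to_numpy(float)
                if np.ptp(m) == 0.0:
                    per_run_rows[run_i].append(
                        (name, chrom, info.at[name, "pos_cM"],
                         np.nan, np.nan, np.nan, np.nan, True))
                    continue
                if config.vc_mode == "per_marker":
                    eff, se, wald, pval, bad = _per_marker_fit(
                        spec, gxe, config, A @ m, prev_theta)
                else:
                    eff, se, wald, pval, bad = _marker_stats(m, v, S)
                per_run_rows[run_i].append(
                    (name, chrom, info.at[name, "pos_cM"], eff, se, wald,
                     pval, bad))
    results = []
    for (kind, covariate), rows in zip(runs, per_run_rows):
        table = pd.DataFrame(
            rows,
            columns=["marker", "chrom", "pos_cM", "effect", "se", "wald",
                     "pvalue", "untestable"],
        )
        table.insert(3, "kind", kind)
        table.insert(4, "covariate", covariate.name if covariate else None)
        results.append(ScanResult(table, kind, covariate.name if covariate else None))
    return results, prev_theta


def scan_genome(
    spec: ModelSpec,
    M: IntervalMarkerMatrix,
    baseline: FitResult | None = None,
    kind: str = "performance",
    covariate: ClimaticCovariate | None = None,
    config: ScanConfig | None = None,
) -> ScanResult:
    """One scan run (performance, or responsiveness for one covariate).

    Returns per-marker effects, standard errors, Wald statistics and
    chi-square(1) p-values. Monomorphic markers are flagged untestable
    rather than raising.
    """
    results, _ = scan_genome_multi(spec, M, [(kind, covariate)], baseline, config)
    return results[0]


def _per_marker_fit(spec, gxe, config, x, start):
    Xaug = np.column_stack([spec.X, x])
    aug = replace(spec, X=Xaug, fixed_names=spec.fixed_names + ["marker"])
    model = MixedModel(aug, GxECov([(n, d, K) for n, d, K in gxe.terms],
                                   spec.n_lines), config.reml)
    fit = model.fit(start=start)
    eff = float(fit.beta.iloc[-1])
    se = float(fit.beta_se.iloc[-1])
    wald = (eff / se) ** 2
    return eff, se, wald, float(stats.chi2.sf(wald, df=1)), False


def prune_30cM(scan: ScanResult, threshold: ThresholdSpec,
               window_cM: float = 30.0) -> pd.DataFrame:
    """Greedy pruning of significant markers within a cM window.

    Markers above the Wald threshold are visited most-significant first
    (ties: lower cM position wins); each kept marker suppresses all
    same-chromosome markers within ``window_cM``. Idempotent and
    order-independent given the tie rule.
    """
    tbl = scan.table
    sig = tbl[(~tbl["untestable"]) & (tbl["wald"] >= threshold.wald_threshold)]
    sig = sig.sort_values(["wald", "pos_cM", "marker"],
                          ascending=[False, True, True], kind="stable")
    kept: list = []
    for row in sig.itertuples(index=False):
        clash = any(
            k.chrom == row.chrom and abs(k.pos_cM - row.pos_cM) <= window_cM
            for k in kept
        )
        if not clash:
            kept.append(row)
    out = pd.DataFrame(kept, columns=sig.columns)
    return out.sort_values(["chrom", "pos_cM"]).reset_index(drop=True)


def fit_final_model(
    spec: ModelSpec,
    M: IntervalMarkerMatrix,
    selected: pd.DataFrame,
    kind: str = "performance",
    covariate: ClimaticCovariate | None = None,
    config: ScanConfig | None = None,
    baseline: FitResult | None = None,
    trait: str = "yield",
    population: str = "POP",
    parents: tuple = ("A", "B"),
    start_theta: np.ndarray | None = None,
) -> list[QTLRecord]:
    """Joint multi-QTL model over the pruned marker set.

    All selected marker effects enter as fixed effects together with the
    additive genomic term on G_{-s} (interval markers within the exclusion
    window of any selected marker removed) and the residual polygenic term.
    Effects, Wald p-values and LOD scores come from the joint fit;
    responsiveness effects also get their covariate-range-normalised size.
    """
    config = config or ScanConfig()
    if selected.empty:
        return []
    sel = selected.reset_index(drop=True)
    windows = [
        (row.chrom, row.pos_cM - config.grm_exclusion_cM,
         row.pos_cM + config.grm_exclusion_cM)
        for row in sel.itertuples(index=False)
    ]
    try:
        G = compute_grm(M, exclude_windows=windows).matrix
    except ValueError:
        # exclusion windows cover the whole map: drop the genomic term and
        # let the polygenic G x E term carry the background alone
        warnings.warn("selected-marker windows exclude every interval "
                      "marker; final model fitted without the genomic term")
        G = None
    A = _dh_incidence(spec)
    if kind == "responsiveness":
        A = A * _plot_covariate(spec, covariate)[:, None]
    xs, names = [], []
    for row in sel.itertuples(index=False):
        xs.append(A @ M.scores[row.marker].to_numpy(float))
        names.append(row.marker)
    # drop aliased (collinear) marker regressors, weaker scan Wald first
    keep = list(range(len(xs)))
    def _rank_ok(idx):
        Xa = np.column_stack([spec.X] + [xs[i] for i in idx])
        return np.linalg.matrix_rank(Xa) == Xa.shape[1]
    for i in np.argsort(sel["wald"].to_numpy()):  # weakest first
        if _rank_ok(keep) or len(keep) <= 1:
            break
        warnings.warn(
            f"marker {names[i]} aliased with a stronger selected marker; "
            "dropped from the final model"
        )
        keep = [j for j in keep if j != i]
    if not _rank_ok(keep):
        raise ValueError("could not resolve collinear selected markers")
    sel = sel.iloc[keep].reset_index(drop=True)
    xs = [xs[i] for i in keep]
    names = [names[i] for i in keep]

    Xaug = np.column_stack([spec.X] + xs)
    aug_spec = replace(spec, X=Xaug, fixed_names=spec.fixed_names + names)
    gxe = _scan_gxe(spec, G, config)
    model = MixedModel(aug_spec, gxe, config.reml)
    fit = model.fit(start=_start_from(model, baseline, start_theta))

    records = []
    chrom_counts: dict = {}
    n_fixed = len(spec.fixed_names)
    for i, row in enumerate(sel.itertuples(index=False)):
        eff = float(fit.beta.iloc[n_fixed + i])
        se = float(fit.beta_se.iloc[n_fixed + i])
        wald = (eff / se) ** 2
        pval = float(stats.chi2.sf(wald, df=1))
        chrom_counts[row.chrom] = chrom_counts.get(row.chrom, 0) + 1
        suffix = f"-{chrom_counts[row.chrom]}" if \
            (sel["chrom"] == row.chrom).sum() > 1 else ""
        rec = QTLRecord(
            name=f"Q{trait}.{population}.{row.chrom}{suffix}",
            trait=trait,
            population=population,
            qtl_type=kind,
            covariate=covariate.name if kind == "responsiveness" else None,
            chrom=row.chrom,
            pos_cM=float(row.pos_cM),
            effect=eff,
            se=se,
            wald=wald,
            pvalue=pval,
            lod=lod_from_wald(wald),
            positive_allele_parent=parents[0] if eff > 0 else parents[1],
            marker=row.marker,
        )
        if kind == "responsiveness":
            rec = normalise_effect(rec, covariate.range())
        records.append(rec)
    return records


def normalise_effect(record: QTLRecord, covariate_range: float) -> QTLRecord:
    """Scale a responsiveness effect by the covariate's numerical range."""
    if record.qtl_type != "responsiveness":
        raise ValueError("normalisation applies to responsiveness records only")
    return replace(record, normalised_effect=record.effect * covariate_range)


def qtl_analysis(
    spec: ModelSpec,
    M: IntervalMarkerMatrix,
    baseline: FitResult | None = None,
    kind: str = "performance",
    covariate: ClimaticCovariate | None = None,
    config: ScanConfig | None = None,
    trait: str = "yield",
    population: str = "POP",
    parents: tuple = ("A", "B"),
):
    """Scan -> threshold -> prune -> final model, for one run.

    Returns (ScanResult, ThresholdSpec, selected table, QTLRecord list).
    """
    config = config or ScanConfig()
    results, null_theta = scan_genome_multi(
        spec, M, [(kind, covariate)], baseline, config)
    scan = results[0]
    threshold = li_ji_threshold(M, config.alpha)
    selected = prune_30cM(scan, threshold, config.prune_window_cM)
    records = fit_final_model(
        spec, M, selected, kind, covariate, config, baseline,
        trait=trait, population=population, parents=parents,
        start_theta=null_theta,
    )
    return scan, threshold, selected, records
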