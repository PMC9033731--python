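"""Genome scan: thresholds, pruning, effect recovery, calibration checks."""

import numpy as np
import pandas as pd
import pytest

from heatqtl import markers as mk
from heatqtl import scan as sc
from heatqtl import validation
from heatqtl.phenology import ClimaticCovariate
from heatqtl.types import GenotypeMatrix, LinkageMap


class TestLod:
    def test_definition_examples(self):
        assert sc.lod_from_wald(0.0) == 0.0
        assert sc.lod_from_wald(2 * np.log(10.0)) == pytest.approx(1.0)

    def test_monotone(self):
        w = np.linspace(0, 30, 50)
        lods = [sc.lod_from_wald(x) for x in w]
        assert all(b > a for a, b in zip(lods, lods[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sc.lod_from_wald(-1.0)


def _interval_from_scores(scores, positions=None, chrom="1"):
    n, p = scores.shape
    names = [f"m{j}" for j in range(p)]
    pos = positions if positions is not None else np.arange(p, dtype=float)
    info = pd.DataFrame({
        "chrom": [chrom] * p, "pos_cM": pos, "left": names, "right": names,
        "kind": ["marker"] * p,
    }, index=pd.Index(names, name="interval_marker"))
    frame = pd.DataFrame(scores, index=[f"L{i}" for i in range(n)],
                         columns=names)
    return mk.IntervalMarkerMatrix(frame, info)


class TestLiJi:
    def test_orthogonal_markers_give_full_count(self):
        # columns of a +-1 Hadamard-type design are exactly orthogonal
        H = np.array([[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1],
                      [1, -1, -1, 1]], float)
        M = _interval_from_scores(np.vstack([H, -H]))
        thr = sc.li_ji_threshold(M, alpha=0.05)
        assert thr.m_eff == pytest.approx(4.0)

    def test_duplicated_markers_halve_the_count(self):
        # duplicating each of p orthogonal markers pairs the eigenvalues
        # into {2, 0}, so the effective count is p (half of 2p)
        H = np.array([[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1],
                      [1, -1, -1, 1]], float)
        base = np.vstack([H, -H])
        dup = np.repeat(base, 2, axis=1)
        thr = sc.li_ji_threshold(_interval_from_scores(dup))
        assert thr.m_eff == pytest.approx(dup.shape[1] / 2)

    def test_matches_dense_eigendecomposition_oracle(self):
        data = validation.calibration_dataset(71)
        M = data["M"]
        thr = sc.li_ji_threshold(M, alpha=0.05)
        m_eff = 0.0
        for chrom in dict.fromkeys(M.info["chrom"]):
            X = M.scores[M.chrom_markers(chrom)].to_numpy(float)
            lam = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))
            lam = np.clip(lam, 0, None)
            m_eff += float(np.sum((lam >= 1) + (lam - np.floor(lam))))
        assert thr.m_eff == pytest.approx(m_eff, rel=1e-10)
        # threshold sits between Sidak on chromosomes and Sidak on markers
        from scipy import stats
        lo = stats.chi2.isf(1 - 0.95 ** (1 / M.n_markers), 1)
        hi = stats.chi2.isf(1 - 0.95 ** (1 / 3), 1)
        assert hi <= thr.wald_threshold <= lo

    def test_zero_variance_column_warns(self):
        rng = np.random.default_rng(72)
        X = rng.choice([-1.0, 1.0], size=(30, 5))
        X[:, 2] = 1.0
        M = _interval_from_scores(X)
        with pytest.warns(UserWarning, match="zero-variance"):
            sc.li_ji_threshold(M)


def _scan_table(rows):
    tbl = pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM", "wald"])
    tbl["kind"] = "performance"
    tbl["covariate"] = None
    tbl["effect"] = 1.0
    tbl["se"] = 1.0
    tbl["pvalue"] = 0.01
    tbl["untestable"] = False
    return sc.ScanResult(tbl, "performance")


THR = sc.ThresholdSpec(0.05, 10.0, 0.005, 8.0, {})


class TestPrune:
    def test_close_pair_keeps_stronger(self):
        res = _scan_table([("a", "1", 10.0, 20.0), ("b", "1", 20.0, 30.0)])
        kept = sc.prune_30cM(res, THR)
        assert list(kept["marker"]) == ["b"]

    def test_distant_pair_keeps_both(self):
        res = _scan_table([("a", "1", 10.0, 20.0), ("b", "1", 50.0, 30.0)])
        kept = sc.prune_30cM(res, THR)
        assert sorted(kept["marker"]) == ["a", "b"]

    def test_tie_keeps_lower_position(self):
        res = _scan_table([("a", "1", 20.0, 15.0), ("b", "1", 10.0, 15.0)])
        kept = sc.prune_30cM(res, THR)
        assert list(kept["marker"]) == ["b"]

    def test_different_chromosomes_do_not_interact(self):
        res = _scan_table([("a", "1", 10.0, 20.0), ("b", "2", 12.0, 12.0)])
        kept = sc.prune_30cM(res, THR)
        assert sorted(kept["marker"]) == ["a", "b"]

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(73)
        rows = [(f"m{j}", "1", float(rng.uniform(0, 200)),
                 float(rng.uniform(5, 50))) for j in range(25)]
        res = _scan_table(rows)
        kept1 = sc.prune_30cM(res, THR)
        res_rev = _scan_table(rows[::-1])
        kept2 = sc.prune_30cM(res_rev, THR)
        assert list(kept1["marker"]) == list(kept2["marker"])
        res_kept = _scan_table(
            [(r.marker, r.chrom, r.pos_cM, r.wald)
             for r in kept1.itertuples(index=False)])
        kept3 = sc.prune_30cM(res_kept, THR)
        assert list(kept3["marker"]) == list(kept1["marker"])

    def test_empty_selection_allowed(self):
        res = _scan_table([("a", "1", 10.0, 2.0)])
        assert sc.prune_30cM(res, THR).empty


class TestNormalise:
    @staticmethod
    def _record(qtl_type="responsiveness", effect=0.1):
        return sc.QTLRecord(
            name="Qy.P.1", trait="yield", population="P", qtl_type=qtl_type,
            covariate="anthesis_avg_max" if qtl_type == "responsiveness" else None,
            chrom="1", pos_cM=10.0, effect=effect, se=0.02, wald=25.0,
            pvalue=1e-6, lod=sc.lod_from_wald(25.0))

    def test_multiplies_by_range(self):
        rec = sc.normalise_effect(self._record(effect=0.1), 3.5)
        assert rec.normalised_effect == pytest.approx(0.35)

    def test_zero_range_gives_zero(self):
        rec = sc.normalise_effect(self._record(effect=0.1), 0.0)
        assert rec.normalised_effect == 0.0

    def test_sign_preserved(self):
        rec = sc.normalise_effect(self._record(effect=-0.2), 4.0)
        assert rec.normalised_effect < 0

    def test_performance_record_refused(self):
        with pytest.raises(ValueError, match="responsiveness"):
            sc.normalise_effect(self._record(qtl_type="performance"), 3.5)

    def test_record_field_constraints(self):
        with pytest.raises(ValueError):
            sc.QTLRecord(name="x", trait="y", population="p",
                         qtl_type="responsiveness", covariate=None,
                         chrom="1", pos_cM=1.0, effect=0.1, se=0.1,
                         wald=1.0, pvalue=0.3, lod=0.2)


@pytest.fixture(scope="module")
def planted():
    """Small trial with one performance and one responsiveness QTL."""
    return validation.make_dataset(
        77, 130, {2015: ["E1", "E2", "E3"]}, n_chromosomes=2,
        markers_per_chromosome=25, chromosome_length=110.0,
        perf_marker="c1m12", resp_marker="c2m12")


class TestScanRuns:
    def test_monomorphic_marker_flagged_untestable(self, planted):
        data = planted
        M = data["M"]
        scores = M.scores.copy()
        scores.iloc[:, 3] = 1.0
        info = M.info
        M2 = mk.IntervalMarkerMatrix(scores, info)
        cfg = sc.ScanConfig(vc_mode="global")
        res = sc.scan_genome(data["spec"], M2, None, "performance", config=cfg)
        flagged = res.table.set_index("marker")["untestable"]
        assert flagged.iloc[3]
        assert not flagged.drop(flagged.index[3]).all()

    def test_constant_covariate_refused(self, planted):
        cov = ClimaticCovariate("flat", planted["cov"].wide * 0.0 + 1.0)
        with pytest.raises(ValueError, match="constant"):
            sc.scan_genome(planted["spec"], planted["M"], None,
                           "responsiveness", cov)

    def test_planted_qtl_detected_at_their_loci(self, planted):
        data = planted
        cfg = sc.ScanConfig(vc_mode="global")
        runs = [("performance", None), ("responsiveness", data["cov"])]
        results, _ = sc.scan_genome_multi(data["spec"], data["M"], runs,
                                          None, cfg)
        thr = sc.li_ji_threshold(data["M"])
        for res, key in zip(results, ["performance", "responsiveness"]):
            chrom, pos = data["truth"][key]
            sel = sc.prune_30cM(res, thr)
            hits = sel[(sel["chrom"] == chrom)
                       & (abs(sel["pos_cM"] - pos) <= 15.0)]
            assert not hits.empty
            assert (hits["effect"] > 0).all()

    def test_responsiveness_rescaling_equivariance(self, planted):
        # c -> 2c halves the per-unit effect; the normalised effect is invariant
        data = planted
        cfg = sc.ScanConfig(vc_mode="global")
        cov2 = ClimaticCovariate("scaled", 2.0 * data["cov"].wide)
        r1 = sc.scan_genome(data["spec"], data["M"], None, "responsiveness",
                            data["cov"], cfg)
        r2 = sc.scan_genome(data["spec"], data["M"], None, "responsiveness",
                            cov2, cfg)
        chrom, pos = data["truth"]["responsiveness"]
        t1 = r1.table.set_index("marker")
        t2 = r2.table.set_index("marker")
        near = t1[(t1["chrom"] == chrom) & (abs(t1["pos_cM"] - pos) < 8)]
        m = near["wald"].idxmax()
        assert t2.at[m, "effect"] == pytest.approx(t1.at[m, "effect"] / 2,
                                                   rel=1e-6)
        assert t2.at[m, "effect"] * cov2.range() == pytest.approx(
            t1.at[m, "effect"] * data["cov"].range(), rel=1e-6)

    def test_permuted_covariate_destroys_within_env_signal(self, planted):
        data = planted
        cfg = sc.ScanConfig(vc_mode="global")
        rng = np.random.default_rng(78)
        wide = data["cov"].wide.copy()
        perm = rng.permutation(len(wide))
        wide_p = pd.DataFrame(wide.to_numpy()[perm], index=wide.index,
                              columns=wide.columns)
        cov_p = ClimaticCovariate("perm", wide_p)
        res = sc.scan_genome(data["spec"], data["M"], None, "responsiveness",
                             cov_p, cfg)
        chrom, pos = data["truth"]["responsiveness"]
        t = res.table
        near = t[(t["chrom"] == chrom) & (abs(t["pos_cM"] - pos) < 8)]
        orig = sc.scan_genome(data["spec"], data["M"], None, "responsiveness",
                              data["cov"], cfg).table
        near_o = orig[(orig["chrom"] == chrom)
                      & (abs(orig["pos_cM"] - pos) < 8)]
        # permuting line labels keeps the environment-level signal but kills
        # the line-level component, weakening the statistic
        assert near["wald"].max() <= near_o["wald"].max()

    def test_final_model_single_qtl_consistent_with_scan(self, planted):
        data = planted
        cfg = sc.ScanConfig(vc_mode="global")
        scan_res, thr, sel, recs = sc.qtl_analysis(
            data["spec"], data["M"], None, "performance", config=cfg,
            trait="yield", population="SYN")
        chrom, pos = data["truth"]["performance"]
        near = [r for r in recs if r.chrom == chrom
                and abs(r.pos_cM - pos) <= 15]
        assert near
        rec = near[0]
        t = scan_res.table.set_index("marker")
        assert rec.effect == pytest.approx(t.at[rec.marker, "effect"],
                                           rel=0.35)
        assert rec.name.startswith("Qyield.SYN.")
        assert rec.lod == pytest.approx(sc.lod_from_wald(rec.wald))

    def test_per_marker_refit_agrees_with_held_variance_mode(self):
        # without a segregating QTL the per-marker REML refit and the
        # held-per-chromosome variances give near-identical statistics
        # (with a strong QTL they differ legitimately: the refit
        # reallocates the QTL's variance out of the polygenic term)
        data = validation.make_dataset(
            82, 60, {2015: ["E1", "E2"]}, n_chromosomes=1,
            markers_per_chromosome=8, chromosome_length=60.0)
        fast = sc.scan_genome(data["spec"], data["M"], None, "performance",
                              config=sc.ScanConfig(vc_mode="chromosome"))
        slow = sc.scan_genome(data["spec"], data["M"], None, "performance",
                              config=sc.ScanConfig(vc_mode="per_marker"))
        a = fast.table.set_index("marker")
        b = slow.table.set_index("marker")
        assert np.allclose(a["effect"], b["effect"], rtol=0.1)
        assert np.corrcoef(a["wald"], b["wald"])[0, 1] > 0.99
        assert a["wald"].idxmax() == b["wald"].idxmax()

    def test_two_unlinked_qtl_recovered_jointly(self):
        data = validation.make_dataset(
            79, 150, {2015: ["E1", "E2", "E3"]}, n_chromosomes=2,
            markers_per_chromosome=25, chromosome_length=110.0,
            perf_marker="c1m12", perf_sd=0.5)
        # plant a second performance QTL on the other chromosome
        from heatqtl import simdata
        from heatqtl.melmm import build_design
        from heatqtl.types import QTLEffect, QTLSpec
        lm, geno = data["map"], data["geno"]
        a = 0.5 * data["sd_p"]
        effects = [QTLEffect("c1m12", "performance", a),
                   QTLEffect("c2m12", "performance", a)]
        obs = simdata.simulate_phenotypes(
            data["design"], geno, QTLSpec(effects), {},
            {e: 3.0 for e in ["E1", "E2", "E3"]}, data["fa"],
            data["spatial"], seed=80)
        spec = build_design(obs, data["design"], dh_lines=geno.lines)
        cfg = sc.ScanConfig(vc_mode="global")
        _, _, sel, recs = sc.qtl_analysis(spec, data["M"], None,
                                          "performance", config=cfg)
        for marker in ["c1m12", "c2m12"]:
            chrom = lm.chrom_of()[marker]
            pos = float(lm.pos_of()[marker])
            near = [r for r in recs if r.chrom == chrom
                    and abs(r.pos_cM - pos) <= 15]
            assert near, marker
            # joint estimate within simulation tolerance of the truth
            assert near[0].effect == pytest.approx(a, abs=3.5 * near[0].se)
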