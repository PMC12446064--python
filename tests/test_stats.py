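import numpy as np
import pandas as pd
import pytest
import scipy.stats

from gepcat.stats import (
    aim_association,
    bh_adjust,
    disease_association,
    fisher_combine,
    make_pseudobulk,
    marker_enrichment,
    proliferation_association,
    proliferation_meta,
    stepwise_asa_selection,
)


class TestBH:
    def test_q_geq_p_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_equal_ps_unchanged(self):
        q = bh_adjust([0.2] * 10)
        np.testing.assert_allclose(q, 0.2)


def _aim_pseudobulk(rng, n_donors=5, effect=0.0, sigma=0.005, n_programs=3):
    rows = []
    for d in range(n_donors):
        for stim, aim in [(0, 0), (1, 0), (1, 1)]:
            row = {"donor": d, "stim": stim, "aim_pos": aim}
            for p in range(n_programs):
                base = 0.1 + (effect * aim if p == 0 else 0.0)
                row[f"P{p}"] = base + rng.normal(0, sigma)
            rows.append(row)
    return pd.DataFrame(rows)


class TestAimAssociation:
    def test_recovers_planted_aim_effect(self):
        rng = np.random.default_rng(1)
        pb = _aim_pseudobulk(rng, effect=0.05)
        res = aim_association(pb, ["P0", "P1", "P2"])
        row = res[(res["program"] == "P0") & (res["term"] == "aim_pos")].iloc[0]
        assert 0.03 < row["coef"] < 0.07
        assert row["q"] < 0.05
        assert row["classification"] == "AIM-associated"

    def test_constant_usage_is_null(self):
        pb = _aim_pseudobulk(np.random.default_rng(2), sigma=0.0)
        pb[["P0", "P1", "P2"]] = 0.2
        res = aim_association(pb, ["P0", "P1", "P2"])
        assert np.allclose(res["coef"], 0.0, atol=1e-12)

    def test_collinear_design_names_column(self):
        pb = _aim_pseudobulk(np.random.default_rng(3))
        pb["aim_pos"] = pb["stim"]
        with pytest.raises(ValueError, match="collinear"):
            aim_association(pb, ["P0"])


class TestProliferation:
    def _cells(self, rng, n_samples=20, shift=0.0, sigma=0.01):
        frames, cc, samples = [], [], []
        for s in range(n_samples):
            n_high, n_low = 30, 200
            hi = 0.15 + shift + rng.normal(0, sigma, n_high)
            lo = 0.15 + rng.normal(0, sigma, n_low)
            frames.append(pd.DataFrame({"P0": np.r_[hi, lo]}))
            cc.extend([0.5] * n_high + [0.0] * n_low)
            samples.extend([f"s{s}"] * (n_high + n_low))
        usage = pd.concat(frames, ignore_index=True)
        usage.index = [f"c{i}" for i in range(len(usage))]
        return usage, pd.Series(cc, index=usage.index), pd.Series(samples, index=usage.index)

    def test_null_program_not_significant(self):
        # high and low cells share one usage distribution
        usage, cc, samples = self._cells(np.random.default_rng(4), shift=0.0)
        res = proliferation_association(usage, cc, samples)
        assert np.isnan(res["p"].iloc[0]) or res["p"].iloc[0] > 0.1

    def test_planted_shift_detected(self):
        usage, cc, samples = self._cells(np.random.default_rng(5), shift=0.02)
        res = proliferation_association(usage, cc, samples)
        assert res["p"].iloc[0] < 0.01

    def test_underpowered_sample_excluded(self):
        usage, cc, samples = self._cells(np.random.default_rng(6), shift=0.02)
        # drop high cells of sample s0 below the minimum of 10
        drop = usage.index[(samples == "s0") & (cc > 0.1)][:25]
        keep = ~usage.index.isin(drop)
        res = proliferation_association(usage[keep], cc[keep], samples[keep])
        assert res["n_samples"].iloc[0] == 19

    def test_meta_combines_across_datasets(self):
        tables = {
            "d1": pd.DataFrame({"program": ["P0"], "p": [0.01]}),
            "d2": pd.DataFrame({"program": ["P0"], "p": [0.02]}),
        }
        meta = proliferation_meta(tables)
        stat, p = fisher_combine([0.01, 0.02])
        assert meta["fisher_p"].iloc[0] == pytest.approx(p)


class TestDiseaseAssociation:
    def test_planted_effect_specific_under_confounding(self):
        rng = np.random.default_rng(7)
        n = 60
        covariate = np.repeat(["siteA", "siteB"], n // 2)
        condition = rng.permutation(np.repeat([0, 1], n // 2))
        pb = pd.DataFrame({
            "condition": condition,
            "site": covariate,
            "n_cells": 100,
            "P_disease": 0.1 + 0.03 * condition + rng.normal(0, 0.01, n),
            "P_site": 0.1 + 0.03 * (covariate == "siteB") + rng.normal(0, 0.01, n),
        })
        res = disease_association(pb, ["P_disease", "P_site"], "condition", ["site"])
        qs = res.set_index("program")["q"]
        assert qs["P_disease"] < 0.05 and qs["P_site"] > 0.05

    def test_duplicate_donor_keeps_larger_sample(self):
        pb = pd.DataFrame({
            "donor": ["d1", "d1", "d2", "d3"],
            "condition": [1, 1, 0, 0],
            "n_cells": [10, 500, 100, 100],
            "P0": [0.4, 0.2, 0.1, 0.1],
        })
        res = disease_association(pb, ["P0"], "condition", donor_col="donor")
        # the 10-cell duplicate is dropped: effect is 0.2 - 0.1
        assert res["coef"].iloc[0] == pytest.approx(0.1)

    def test_confounded_design_errors(self):
        pb = pd.DataFrame({
            "condition": [0, 0, 1, 1],
            "site": ["a", "a", "b", "b"],
            "n_cells": 10,
            "P0": [0.1, 0.1, 0.2, 0.2],
        })
        with pytest.raises(ValueError, match="collinear"):
            disease_association(pb, ["P0"], "condition", ["site"])


class TestStepwise:
    def _datasets(self, rng, n=3000, predictive=("A", "B"), noise=("C", "D", "E")):
        targets, usages = {}, {}
        for ds in ("d1", "d2"):
            y = rng.random(n) < 0.3
            cols = {}
            for c in predictive:
                cols[c] = 0.05 + 0.04 * y + rng.normal(0, 0.02, n).clip(-0.04)
            for c in noise:
                cols[c] = 0.05 + rng.normal(0, 0.02, n).clip(-0.04)
            usages[ds] = pd.DataFrame(cols)
            targets[ds] = pd.Series(y.astype(int))
        return targets, usages

    def test_perfect_predictor_selected_first(self):
        rng = np.random.default_rng(8)
        n = 500
        y = pd.Series((rng.random(n) < 0.4).astype(int))
        usage = pd.DataFrame({
            "oracle": y.astype(float),
            "noise": rng.random(n),
        })
        sel, traj = stepwise_asa_selection(["noise", "oracle"],
                                           {"d": y}, {"d": usage})
        assert sel[0] == "oracle"
        assert traj["mean_auc"].iloc[0] == pytest.approx(1.0)

    def test_recovers_planted_components(self):
        rng = np.random.default_rng(9)
        targets, usages = self._datasets(rng)
        sel, _ = stepwise_asa_selection(list("ABCDE"), targets, usages)
        assert {"A", "B"} <= set(sel)

    def test_pure_noise_mean_auc_near_half(self):
        rng = np.random.default_rng(10)
        targets, usages = self._datasets(rng, n=20_000, predictive=(),
                                         noise=tuple("CDEFG"))
        sel, traj = stepwise_asa_selection(list("CDEFG"), targets, usages)
        # under the add-if-mean-improves policy a few noise components can
        # slip in, but the score never leaves chance level
        if len(traj):
            assert np.abs(traj["mean_auc"] - 0.5).max() < 0.02

    def test_single_class_dataset_excluded(self):
        rng = np.random.default_rng(11)
        targets, usages = self._datasets(rng, n=400)
        targets["d2"] = pd.Series(np.zeros(400, dtype=int))
        with pytest.warns(UserWarning, match="one class"):
            sel, _ = stepwise_asa_selection(list("ABCDE"), targets, usages)
        assert "A" in sel and "B" in sel


class TestMarkerEnrichment:
    def test_odds_ratio_arithmetic(self):
        # build a z-score row realizing the 2x2 table (10, 90, 40, 860)
        genes = [f"g{i}" for i in range(1000)]
        z = pd.Series(0.0, index=genes)
        z.iloc[:100] = 1.0  # 100 marker genes
        gene_set = genes[:10] + genes[100:140]  # 10 in markers, 40 out
        zs = pd.DataFrame([z], index=["P0"])
        res = marker_enrichment(zs, {"set": gene_set}, z_threshold=0.5)
        assert res["odds_ratio"].iloc[0] == pytest.approx((10 * 860) / (90 * 40))
        fisher_p = scipy.stats.fisher_exact([[10, 90], [40, 860]])[1]
        assert res["p"].iloc[0] == pytest.approx(fisher_p)

    def test_perfect_overlap_infinite_or(self):
        genes = [f"g{i}" for i in range(200)]
        z = pd.Series(0.0, index=genes)
        z.iloc[:20] = 1.0
        res = marker_enrichment(pd.DataFrame([z], index=["P0"]),
                                {"set": genes[:20]}, z_threshold=0.5)
        assert np.isinf(res["odds_ratio"].iloc[0])
        assert res["p"].iloc[0] < 1e-20

    def test_empty_intersection_errors(self):
        zs = pd.DataFrame([[0.1, 0.2]], index=["P0"], columns=["g0", "g1"])
        with pytest.raises(ValueError, match="intersect"):
            marker_enrichment(zs, {"set": ["absent"]})


class TestFisherCombine:
    def test_statistic_definition(self):
        ps = [0.1, 0.01, 0.5]
        stat, p = fisher_combine(ps)
        assert stat == pytest.approx(-2 * np.sum(np.log(ps)))
        assert p == pytest.approx(scipy.stats.chi2.sf(stat, 2 * len(ps)))

    def test_uniform_ps_match_chisq(self):
        rng = np.random.default_rng(12)
        k = 4
        stats = [fisher_combine(rng.uniform(size=k))[0] for _ in range(2000)]
        ks = scipy.stats.kstest(stats, scipy.stats.chi2(2 * k).cdf)
        assert ks.pvalue > 0.01


class TestPseudobulk:
    def test_means_and_counts(self):
        usage = pd.DataFrame({"P0": [0.1, 0.3, 0.5, 0.7]},
                             index=["c0", "c1", "c2", "c3"])
        meta = pd.DataFrame({"sample": ["s1", "s1", "s2", "s2"]},
                            index=usage.index)
        pb = make_pseudobulk(usage, meta, ["sample"])
        assert pb.loc[pb["sample"] == "s1", "P0"].iloc[0] == pytest.approx(0.2)
        assert (pb["n_cells"] == 2).all()
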