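"""NB differential expression: size factors, QC, calibration, BH, MPV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyexpr.containers import CountMatrix
from polyexpr.de import (
    NBExpressionModel,
    bh_adjust,
    mpv_test,
    nb_test,
    qc_filter,
    sample_qc,
    size_factors,
)

from conftest import nb_matrix


def cm_from_arrays(cols: dict, groups: list) -> CountMatrix:
    counts = pd.DataFrame(cols)
    counts.index = [f"g{i}" for i in range(len(counts))]
    samples = pd.DataFrame({"group": groups}, index=list(cols))
    return CountMatrix(counts, samples)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        cm = cm_from_arrays({"s1": [10, 20, 30], "s2": [10, 20, 30]}, ["a", "a"])
        sf = size_factors(cm)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_closed_form(self):
        cm = cm_from_arrays({"s1": [10, 20, 30], "s2": [20, 40, 60]}, ["a", "a"])
        sf = size_factors(cm)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_geometric_mean_one(self, rng):
        cm = nb_matrix(rng, rng.lognormal(4, 1, 300), 0.05, ["a"] * 3 + ["b"] * 3)
        sf = size_factors(cm)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_fallback_when_no_common_locus(self):
        cm = cm_from_arrays({"s1": [5, 0], "s2": [0, 5]}, ["a", "a"])
        sf = size_factors(cm)
        assert sf.attrs["fallback_total_count"]
        assert np.allclose(sf, 1.0)


class TestQCFilter:
    def test_zero_total_removed(self):
        cm = cm_from_arrays({"s1": [0, 10, 10], "s2": [0, 12, 9]}, ["a", "a"])
        filtered, log = qc_filter(cm, min_mean_norm=0.0)
        assert "g0" not in filtered.loci
        assert ("g0", "zero_total_count") in list(map(tuple, log.to_numpy()))

    def test_uniform_counts_survive(self):
        cm = cm_from_arrays({"s1": [10] * 5, "s2": [10] * 5, "s3": [10] * 5}, ["a"] * 3)
        filtered, log = qc_filter(cm)
        assert filtered.n_loci == 5 and len(log) == 0

    def test_extreme_outlier_flagged(self):
        cols = {f"s{j}": [10, 10] for j in range(3)}
        cols["s0"] = [10, 1500]  # one replicate at >100x the others
        cm = cm_from_arrays(cols, ["a", "a", "a"])
        filtered, log = qc_filter(cm, min_mean_norm=0.0)
        reasons = dict(map(tuple, log.to_numpy()))
        assert reasons.get("g1") == "extreme_count_outlier"

    def test_low_mean_removed(self):
        cm = cm_from_arrays({"s1": [1, 100], "s2": [0, 100], "s3": [0, 100]}, ["a"] * 3)
        filtered, log = qc_filter(cm, min_mean_norm=1.0)
        assert list(filtered.loci) == ["g1"]


class TestSampleQC:
    def test_clean_replicates_unflagged(self, rng):
        mu = rng.lognormal(4, 1, 200)
        shift = np.exp2(rng.normal(0, 1.5, 200))  # per-locus composition change
        cols = {f"s{j}": rng.poisson(mu) for j in range(2)}
        cols.update({f"s{j}": rng.poisson(mu * shift) for j in range(2, 4)})
        cm = cm_from_arrays(cols, ["a", "a", "b", "b"])
        qc = sample_qc(cm)
        assert not qc.flags.any()

    def test_corrupted_sample_flagged(self, rng):
        mu = rng.lognormal(4, 1, 500)
        shift = np.exp2(rng.normal(0, 1.5, 500))
        cols = {f"s{j}": rng.poisson(rng.gamma(50, mu / 50)) for j in range(3)}
        cols.update(
            {f"s{j}": rng.poisson(rng.gamma(50, mu * shift / 50)) for j in range(3, 6)}
        )
        cm = cm_from_arrays(cols, ["a"] * 3 + ["b"] * 3)
        # corrupt one replicate of group a with heavy multiplicative noise
        noisy = cm.counts.copy()
        noise = rng.lognormal(0, 2.5, 500)
        noisy["s0"] = np.maximum((noisy["s0"] * noise).astype(int), 0)
        cm2 = CountMatrix(noisy, cm.samples)
        qc = sample_qc(cm2)
        assert qc.flags["s0"]
        assert qc.flags.sum() == 1

    def test_two_clean_groups_separate_on_pc1(self, rng):
        mu = rng.lognormal(4, 1, 400)
        shift = np.exp2(rng.normal(0, 1.5, 400))
        cols = {}
        for j in range(3):
            cols[f"s{j}"] = rng.poisson(mu)
        for j in range(3, 6):
            cols[f"s{j}"] = rng.poisson(mu * shift)
        cm = cm_from_arrays(cols, ["a"] * 3 + ["b"] * 3)
        qc = sample_qc(cm)
        assert not qc.flags.any()
        pc1 = qc.pca["PC1"]
        assert (pc1[:3] < 0).all() != (pc1[3:] < 0).all()  # groups on opposite sides

    def test_requires_three_samples(self):
        cm = cm_from_arrays({"s1": [1, 2], "s2": [1, 2]}, ["a", "a"])
        with pytest.raises(ValueError):
            sample_qc(cm)


class TestBH:
    def test_hand_computed(self):
        # m=4: 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 -> monotone min = 0.04 each
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([1.0, 1.0]), 1.0)

    def test_order_invariance(self, rng):
        p = rng.uniform(0, 1, 50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNBTest:
    def test_null_calibration(self, rng):
        """Type-I error near nominal and near-uniform p under the null."""
        mu = rng.lognormal(np.log(100), 1.0, 5000)
        cm = nb_matrix(rng, mu, 0.05, ["g1"] * 3 + ["g2"] * 3)
        res = nb_test(cm, "g1", "g2")
        p = res.frame["p_value"].to_numpy()
        assert 0.035 <= (p < 0.05).mean() <= 0.065
        assert stats.kstest(p, "uniform").statistic <= 0.03

    def test_equal_counts_zero_lfc(self):
        cm = cm_from_arrays(
            {"s1": [50, 100], "s2": [50, 100], "s3": [50, 100], "s4": [50, 100]},
            ["g1", "g1", "g2", "g2"],
        )
        res = nb_test(cm, "g1", "g2")
        assert np.allclose(res.frame["log2_fc"], 0.0)
        assert np.allclose(res.frame["stat"], 0.0)

    def test_power_at_4fold(self, rng):
        """|log2 FC| = 2 at depth >= 100, 3v3: >= 80% called DE at FDR 0.05."""
        n = 1000
        mu = rng.lognormal(np.log(300), 0.5, n)
        de = np.zeros(n, dtype=bool)
        de[:200] = True
        mu2 = np.where(de, mu * 4.0, mu)
        cols = {}
        for j in range(3):
            cols[f"a{j}"] = rng.poisson(rng.gamma(20, mu / 20))
        for j in range(3):
            cols[f"b{j}"] = rng.poisson(rng.gamma(20, mu2 / 20))
        cm = cm_from_arrays(cols, ["g1"] * 3 + ["g2"] * 3)
        res = nb_test(cm, "g1", "g2")
        called = res.frame.loc[de, "direction"] == "up_in_second"
        assert called.mean() >= 0.8

    def test_sample_scaling_leaves_statistics_stable(self, rng):
        """Scaling one sample's counts moves its size factor, not the calls."""
        mu = rng.lognormal(np.log(500), 0.8, 800)
        cm = nb_matrix(rng, mu, 0.02, ["g1"] * 3 + ["g2"] * 3)
        res1 = nb_test(cm, "g1", "g2")
        scaled = cm.counts.copy()
        scaled["s0"] = scaled["s0"] * 3
        cm2 = CountMatrix(scaled, cm.samples)
        sf1, sf2 = size_factors(cm), size_factors(cm2)
        assert sf2["s0"] / sf1["s0"] == pytest.approx(3.0 ** (5 / 6), rel=0.01)
        res2 = nb_test(cm2, "g1", "g2")
        # statistics approximately invariant at high depth
        assert np.corrcoef(res1.frame["stat"], res2.frame["stat"])[0, 1] > 0.98

    def test_group_with_one_sample_rejected(self):
        cm = cm_from_arrays({"s1": [5], "s2": [5], "s3": [5]}, ["g1", "g2", "g2"])
        with pytest.raises(ValueError):
            nb_test(cm, "g1", "g2")


class TestMPV:
    def _trio(self, rng, mu_m_factor, n=2000, depth=200.0, frac_dev=1.0):
        """mu_m deviates from MPV by mu_m_factor on a frac_dev subset of loci."""
        mu = rng.lognormal(np.log(depth), 0.7, n)
        mu_a, mu_b = mu * 1.5, mu * 0.5
        dev = np.zeros(n, dtype=bool)
        dev[: int(frac_dev * n)] = True
        mu_m = (mu_a + mu_b) / 2 * np.where(dev, mu_m_factor, 1.0)
        self._dev = dev
        cols = {}
        for j, (g, m) in enumerate([("A", mu_a)] * 3 + [("B", mu_b)] * 3 + [("M", mu_m)] * 3):
            cols[f"s{j}_{g}"] = rng.poisson(rng.gamma(50, m / 50))
        groups = ["A"] * 3 + ["B"] * 3 + ["M"] * 3
        return cm_from_arrays(cols, groups)

    def test_null_type_one_near_nominal(self, rng):
        cm = self._trio(rng, mu_m_factor=1.0, n=4000)
        res = mpv_test(cm, "M", "A", "B")
        p = res.frame["p_value"].to_numpy()
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_equal_means_statistic_zero(self):
        cols = {f"s{j}": [100, 40] for j in range(9)}
        cm = cm_from_arrays(cols, ["A"] * 3 + ["B"] * 3 + ["M"] * 3)
        res = mpv_test(cm, "M", "A", "B")
        assert np.allclose(res.frame["stat"], 0.0)

    def test_twofold_deviation_rejected_at_depth(self, rng):
        cm = self._trio(rng, mu_m_factor=2.0, n=1000, depth=500.0, frac_dev=0.2)
        res = mpv_test(cm, "M", "A", "B")
        called = res.frame.loc[self._dev, "direction"] == "up_in_first"
        assert called.mean() > 0.9


def test_crosscheck_against_independent_nb_glm(rng):
    """Fold changes and calls agree with an independent NB GLM (pydeseq2)."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    mu = rng.lognormal(np.log(200), 1.0, 300)
    lfc = np.where(rng.random(300) < 0.3, rng.choice([-2.0, 2.0], 300), 0.0)
    cols = {}
    for j in range(3):
        cols[f"a{j}"] = rng.poisson(rng.gamma(20, mu / 20))
    for j in range(3):
        cols[f"b{j}"] = rng.poisson(rng.gamma(20, mu * np.exp2(lfc) / 20))
    cm = cm_from_arrays(cols, ["g1"] * 3 + ["g2"] * 3)
    ours = nb_test(cm, "g2", "g1")

    meta = pd.DataFrame({"condition": ["g1"] * 3 + ["g2"] * 3},
                        index=cm.counts.columns)
    dds = DeseqDataSet(counts=cm.counts.T, metadata=meta,
                       design="~condition", quiet=True)
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["condition", "g2", "g1"], quiet=True)
    ds.summary()
    theirs = ds.results_df.reindex(ours.frame.index)
    r = np.corrcoef(ours.frame["log2_fc"], theirs["log2FoldChange"])[0, 1]
    assert r > 0.95
    true_de = lfc != 0
    assert (ours.frame["direction"][true_de] != "no_de").mean() > 0.8
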