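"""Negative-binomial differential testing: size factors, dispersion, Wald."""

import numpy as np
import pandas as pd
import pytest

from epipattern.counts import (
    NegativeBinomialDE,
    call_dhml,
    nb_dispersion,
    nb_wald_test,
    size_factors,
)


def nb_counts(rng, n_features, mean, dispersion, n_samples):
    r = 1.0 / dispersion
    mu = np.full((n_features, n_samples), float(mean))
    return rng.negative_binomial(r, r / (r + mu)).astype(int)


def count_frame(arr, sample_ids):
    return pd.DataFrame(
        arr, columns=sample_ids,
        index=pd.Index([f"f{i}" for i in range(arr.shape[0])],
                       name="feature_id"),
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[10], [20], [5]], (1, 3))
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_library_hand_example(self):
        counts = np.array([[10, 20], [4, 8], [30, 60], [7, 14]])
        expect = [1 / np.sqrt(2), np.sqrt(2)]
        assert np.allclose(size_factors(counts), expect)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.poisson(20, size=(100, 6)) + 1
        sf = size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_feature_order_is_irrelevant(self, rng):
        counts = rng.poisson(20, size=(100, 4)) + 1
        perm = rng.permutation(100)
        assert np.allclose(size_factors(counts), size_factors(counts[perm]))

    def test_all_zero_sample_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            size_factors(np.array([[1, 0], [2, 0]]))

    def test_fallback_without_everywhere_positive_features(self):
        # no feature positive in every sample: total-count fallback
        counts = np.array([[10, 0], [0, 40]])
        sf = size_factors(counts)
        assert np.allclose(sf, [0.5, 2.0])


class TestDispersion:
    def test_poisson_counts_shrink_to_tiny_dispersion(self, rng):
        counts = rng.poisson(50, size=(300, 8))
        sf = np.ones(8)
        d = nb_dispersion(counts, sf, ["A"] * 4 + ["B"] * 4)
        assert np.median(d) < 0.02

    def test_mean_recovery_at_study_conditions(self, rng):
        counts = nb_counts(rng, 500, mean=30, dispersion=0.1, n_samples=8)
        d = nb_dispersion(counts, np.ones(8), ["A"] * 4 + ["B"] * 4)
        assert 0.05 <= d.mean() <= 0.2

    def test_identical_raw_estimates_survive_shrinkage(self, rng):
        # when every raw estimate coincides, the trend fits that value and
        # shrinkage returns (approximately) the common estimate
        base = nb_counts(rng, 1, mean=40, dispersion=0.2, n_samples=8)
        counts = np.tile(base, (50, 1))
        d = nb_dispersion(counts, np.ones(8), ["A"] * 4 + ["B"] * 4)
        assert np.allclose(d, d[0])
        q = counts[0].astype(float)
        resid2 = sum(((q[g] - q[g].mean()) ** 2).sum()
                     for g in (slice(0, 4), slice(4, 8)))
        raw = (resid2 - 0.75 * (q[:4].mean() + q[4:].mean()) * 4) / (
            3 * (q[:4].mean() ** 2 + q[4:].mean() ** 2))
        assert d[0] == pytest.approx(raw, rel=1e-2)

    def test_singleton_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            nb_dispersion(np.ones((5, 3)), np.ones(3), ["A", "A", "B"])


class TestModel:
    def test_equal_groups_are_null(self):
        counts = count_frame(np.tile([[8, 12, 8, 12]], (20, 1)),
                             ["a1", "a2", "b1", "b2"])
        res = nb_wald_test(counts, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(res["log2fc"], 0.0)
        assert not res["significant"].any()
        assert (res["padj"] >= res["p"] - 1e-12).all()

    def test_sub_threshold_fold_change_is_not_called(self, rng):
        # ten features with a certain ~1.4-fold change among null features:
        # their padj is tiny but |log2fc| ~ 0.5 < 1, so no call is made
        null = rng.poisson(20_000, size=(40, 6))
        a = rng.poisson(20_000, size=(10, 3))
        b = rng.poisson(28_000, size=(10, 3))
        counts = count_frame(np.vstack([null, np.hstack([a, b])]),
                             ["a1", "a2", "a3", "b1", "b2", "b3"])
        res = nb_wald_test(counts, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        shifted = res.iloc[40:]
        assert (shifted["padj"] < 0.01).all()
        assert (shifted["log2fc"].abs() < 1.0).all()
        assert not res["significant"].any()

    def test_all_zero_features_are_excluded(self):
        arr = np.array([[5, 5, 9, 9], [0, 0, 0, 0]])
        counts = count_frame(arr, ["a1", "a2", "b1", "b2"])
        res = nb_wald_test(counts, ["a1", "a2"], ["b1", "b2"])
        assert list(res["feature_id"]) == ["f0"]

    def test_non_integer_counts_rejected(self):
        counts = count_frame(np.full((3, 4), 2.5), ["a1", "a2", "b1", "b2"])
        with pytest.raises(ValueError, match="integer"):
            nb_wald_test(counts, ["a1", "a2"], ["b1", "b2"])

    def test_log2fc_sign_and_antisymmetry(self):
        # a handful of raised features among a null majority (size factors
        # are anchored by the null features)
        arr = np.vstack([np.tile([[10, 10, 10, 10]], (30, 1)),
                         np.tile([[5, 5, 40, 40]], (5, 1))])
        counts = count_frame(arr, ["a1", "a2", "b1", "b2"])
        res = nb_wald_test(counts, ["a1", "a2"], ["b1", "b2"])
        assert (res["log2fc"].iloc[30:] > 0).all()
        flip = nb_wald_test(counts, ["b1", "b2"], ["a1", "a2"])
        assert np.allclose(flip["wald_z"], -res["wald_z"])

    def test_normalisation_invariance(self, rng):
        # rescaling libraries by factors with geometric mean 1 must leave
        # per-feature results untouched (counts kept integral: even base
        # counts scaled by 2 and 1/2)
        base = 2 * nb_counts(rng, 80, mean=25, dispersion=0.1, n_samples=4)
        scale = np.array([2.0, 0.5, 0.5, 2.0])
        scaled = (base * scale[None, :]).astype(int)
        ids = ["a1", "a2", "b1", "b2"]
        r1 = nb_wald_test(count_frame(base, ids), ["a1", "a2"], ["b1", "b2"])
        r2 = nb_wald_test(count_frame(scaled, ids), ["a1", "a2"], ["b1", "b2"])
        # normalised means are restored exactly, so effect estimates match;
        # p-values may differ slightly because per-sample shot noise
        # legitimately depends on library size
        assert np.allclose(r1["log2fc"], r2["log2fc"])
        assert np.allclose(r1["base_mean"], r2["base_mean"])
        from scipy import stats

        assert stats.spearmanr(r1["p"], r2["p"]).statistic > 0.999

    def test_size_factors_exposed_on_results(self, rng):
        arr = nb_counts(rng, 50, 20, 0.1, 4)
        ids = ["a1", "a2", "b1", "b2"]
        fit = NegativeBinomialDE.from_table(count_frame(arr, ids),
                                            ["a1", "a2"], ["b1", "b2"]).fit()
        assert list(fit.size_factors.index) == ids
        assert "significant" in fit.summary()


class TestDHML:
    def test_strands_are_independent_features(self, rng):
        # one strand differential, the other null, at the same position
        null = np.tile([[20, 20, 20, 20]], (30, 1))
        plus = null.copy()
        minus = null.copy()
        minus[0] = [20, 20, 90, 95]
        ids = [f"chr1:{i}:+" for i in range(30)] + [
            f"chr1:{i}:-" for i in range(30)]
        table = pd.DataFrame(np.vstack([plus, minus]), columns=
                             ["a1", "a2", "b1", "b2"],
                             index=pd.Index(ids, name="feature_id"))
        res = call_dhml(table, ["a1", "a2"], ["b1", "b2"])
        sig = set(res.loc[res["significant"], "feature_id"])
        assert sig == {"chr1:0:-"}

    def test_strand_swap_symmetry(self, rng):
        arr = nb_counts(rng, 40, 25, 0.1, 4)
        ids_plus = [f"chr1:{i}:+" for i in range(40)]
        ids_minus = [f"chr1:{i}:-" for i in range(40)]
        t1 = pd.DataFrame(arr, columns=["a1", "a2", "b1", "b2"],
                          index=pd.Index(ids_plus, name="feature_id"))
        t2 = t1.set_axis(pd.Index(ids_minus, name="feature_id"), axis=0)
        r1 = call_dhml(t1, ["a1", "a2"], ["b1", "b2"])
        r2 = call_dhml(t2, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(r1["p"], r2["p"])
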