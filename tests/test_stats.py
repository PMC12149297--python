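import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from eegrc.stats import (bh_adjust, channelwise_t_map, cohens_d,
                         mann_whitney_u, normality_diagnostic, one_way_anova,
                         pillai_manova, pooled_t, regional_summary, tukey_hsd)
from eegrc.io import standard_montage


class TestRegionalSummary:
    def test_uniform_values(self):
        m = standard_montage()
        rs = regional_summary({c: 3.14 for c in m.all19}, m)
        assert rs.global_mean == rs.rostral_mean == rs.caudal_mean == 3.14
        assert rs.asymmetry == 0.0

    def test_caudal_dominance_negative_asymmetry(self):
        m = standard_montage()
        vals = {c: 1.6 if c in m.rostral else 1.7 if c in m.caudal else 1.65
                for c in m.all19}
        rs = regional_summary(vals, m)
        assert rs.asymmetry == pytest.approx(-0.1)
        assert rs.global_mean == pytest.approx(
            (7 * 1.6 + 7 * 1.7 + 5 * 1.65) / 19)

    def test_missing_channel_named(self):
        m = standard_montage()
        vals = {c: 1.0 for c in m.all19 if c != "Pz"}
        with pytest.raises(ValueError, match="Pz"):
            regional_summary(vals, m)


class TestCohensD:
    def test_hand_example_pooled_sd_one(self):
        assert cohens_d([2, 3, 4], [0, 1, 2]) == pytest.approx(2.0)

    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_relation_to_pooled_t(self, rng):
        a, b = rng.normal(size=14), rng.normal(0.5, 1.2, size=9)
        t, _, _ = pooled_t(a, b)
        d = cohens_d(a, b)
        n1, n2 = len(a), len(b)
        assert t == pytest.approx(d * np.sqrt(n1 * n2 / (n1 + n2)))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 1, size=11)
        res = one_way_anova({"a": a, "b": b})
        t, _, p = pooled_t(a, b)
        assert res.statistic == pytest.approx(t ** 2)
        assert res.p_value == pytest.approx(p)

    def test_identical_groups_zero_f(self):
        res = one_way_anova({g: [1, 2, 3] for g in "abc"})
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_matches_sums_of_squares_oracle(self, rng):
        groups = {g: rng.normal(m, 1.0, size=10)
                  for g, m in zip("abc", (0.0, 1.0, 2.0))}
        res = one_way_anova(groups)
        # independent oracle: scipy f_oneway + direct SS decomposition
        f_ref, p_ref = ss.f_oneway(*groups.values())
        assert res.statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)
        allv = np.concatenate(list(groups.values()))
        ssb = sum(len(v) * (np.mean(v) - allv.mean()) ** 2
                  for v in groups.values())
        sst = np.sum((allv - allv.mean()) ** 2)
        assert res.effect_size == pytest.approx(ssb / sst)
        assert res.df == (2, 27)

    def test_r_squared_bounds(self, rng):
        res = one_way_anova({"a": rng.normal(size=5),
                             "b": rng.normal(size=5)})
        assert 0.0 <= res.effect_size <= 1.0


class TestTukey:
    def test_two_groups_reduce_to_pooled_t(self, rng):
        a, b = rng.normal(size=9), rng.normal(0.8, 1, size=9)
        (res,) = tukey_hsd({"a": a, "b": b})
        assert res.p_value == pytest.approx(pooled_t(a, b)[2], abs=1e-9)

    def test_identical_groups_nonsignificant(self):
        res = tukey_hsd({g: [1.0, 2.0, 3.0, 4.0] for g in "abc"})
        assert all(r.p_value > 0.99 for r in res)

    def test_separated_groups_tiny_p(self, rng):
        groups = {g: rng.normal(m, 1.0, size=10)
                  for g, m in zip("abc", (0.0, 10.0, 20.0))}
        assert all(r.p_value < 1e-6 for r in tukey_hsd(groups))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {g: rng.normal(m, 1.0, size=8)
                  for g, m in zip("abc", (0.0, 0.7, 1.1))}
        ours = {tuple(sorted(r.comparison)): r.p_value
                for r in tukey_hsd(groups)}
        vals = np.concatenate(list(groups.values()))
        labs = np.repeat(list(groups), [len(v) for v in groups.values()])
        ref = pairwise_tukeyhsd(vals, labs)
        for row, p in zip(ref.summary().data[1:], ref.pvalues):
            key = tuple(sorted((row[0], row[1])))
            assert ours[key] == pytest.approx(p, abs=1e-4)

    def test_reports_pairwise_df_and_d(self, rng):
        groups = {"a": rng.normal(size=10), "b": rng.normal(size=7),
                  "c": rng.normal(size=5)}
        for r in tukey_hsd(groups):
            n1 = len(groups[r.comparison[0]])
            n2 = len(groups[r.comparison[1]])
            assert r.df == (n1 + n2 - 2,)
            assert r.effect_name == "cohens_d"


class TestPillaiManova:
    @staticmethod
    def _sim(rng, shift):
        return {g: rng.normal(m, 1.0, size=(12, 4))
                for g, m in zip("abc", (0.0, shift, 2 * shift))}

    def test_identical_means_trace_near_zero(self, rng):
        groups = {g: rng.normal(0.0, 1.0, size=(15, 3)) for g in "ab"}
        res = pillai_manova(groups)
        assert res.statistic < 0.4
        assert res.p_value > 0.01

    def test_matches_eigendecomposition_oracle(self, rng):
        groups = self._sim(rng, 0.8)
        res = pillai_manova(groups)
        # brute force: eigenvalues of W^-1 B
        grand = np.vstack(list(groups.values())).mean(axis=0)
        p = 4
        B = np.zeros((p, p)); W = np.zeros((p, p))
        for m in groups.values():
            d = m.mean(axis=0) - grand
            B += len(m) * np.outer(d, d)
            c = m - m.mean(axis=0)
            W += c.T @ c
        lam = np.linalg.eigvals(np.linalg.inv(W) @ B).real
        assert res.statistic == pytest.approx(np.sum(lam / (1 + lam)),
                                              abs=1e-10)

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        groups = self._sim(rng, 0.6)
        res = pillai_manova(groups)
        endog = np.vstack(list(groups.values()))
        labs = np.repeat(list(groups), [len(v) for v in groups.values()])
        df = pd.DataFrame(endog, columns=["v1", "v2", "v3", "v4"])
        df["g"] = labs
        mv = MANOVA.from_formula("v1 + v2 + v3 + v4 ~ g", data=df)
        tab = mv.mv_test().results["g"]["stat"]
        assert res.statistic == pytest.approx(
            tab.loc["Pillai's trace", "Value"], abs=1e-8)
        assert res.p_value == pytest.approx(
            tab.loc["Pillai's trace", "Pr > F"], abs=1e-8)
        assert res.df == (tab.loc["Pillai's trace", "Num DF"],
                          tab.loc["Pillai's trace", "Den DF"])

    def test_univariate_input_rejected(self, rng):
        with pytest.raises(ValueError):
            pillai_manova({"a": rng.normal(size=(5, 1)),
                           "b": rng.normal(size=(5, 1))})

    def test_singular_within_covariance_rejected(self):
        a = np.ones((6, 3))
        a[:, 1] = np.arange(6)
        a[:, 2] = 2 * a[:, 1]  # collinear
        with pytest.raises(np.linalg.LinAlgError):
            pillai_manova({"a": a, "b": a + 1.0})


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0

    def test_tied_identical_groups(self):
        # average-rank U for {1,2,3} vs {1,2,3}
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5

    def test_swap_invariance_under_min_convention(self, rng):
        a, b = rng.normal(size=9), rng.normal(0.5, 1.0, size=7)
        assert mann_whitney_u(a, b).statistic == \
            mann_whitney_u(b, a).statistic

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFdr:
    def test_hand_applied_step_up(self):
        adj = bh_adjust([0.001, 0.02, 0.03, 0.4])
        assert np.allclose(adj, [0.004, 0.04, 0.04, 0.4])

    def test_monotone_and_never_smaller(self, rng):
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestChannelTMap:
    @staticmethod
    def _frame(rng, n_per_group, effect_channel=None, delta=0.0):
        chans = list(standard_montage().all19)
        subs = [f"s{i}" for i in range(2 * n_per_group)]
        labels = pd.Series(["x"] * n_per_group + ["y"] * n_per_group,
                           index=subs)
        data = rng.standard_normal((2 * n_per_group, 19))
        if effect_channel is not None:
            data[:n_per_group, chans.index(effect_channel)] += delta
        return pd.DataFrame(data, index=subs, columns=chans), labels

    def test_planted_effect_detected(self, rng):
        mat, labels = self._frame(rng, 30, "Pz", 3.0)
        tm = channelwise_t_map(mat, labels, ("x", "y"))
        assert tm.significant[tm.channels.index("Pz")]

    def test_null_family_discovery_rate_controlled(self, rng):
        hits = 0
        runs = 300
        for _ in range(runs):
            mat, labels = self._frame(rng, 8)
            tm = channelwise_t_map(mat, labels, ("x", "y"))
            hits += tm.significant.any()
        # BH controls FDR at 0.05; under the global null that bounds the
        # probability of any discovery
        assert hits / runs <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / runs)

    def test_mask_matches_alpha_threshold(self, rng):
        mat, labels = self._frame(rng, 12, "O1", 2.0)
        tm = channelwise_t_map(mat, labels, ("x", "y"), alpha_level=0.01)
        assert np.array_equal(tm.significant, tm.p_fdr < 0.01)

    def test_needs_two_subjects_per_group(self, rng):
        mat, labels = self._frame(rng, 1)
        with pytest.raises(ValueError):
            channelwise_t_map(mat, labels, ("x", "y"))


def test_normality_diagnostic_is_reported_not_enforced(rng):
    res = normality_diagnostic(rng.normal(size=50))
    assert res.test == "dagostino_pearson"
    assert 0.0 <= res.p_value <= 1.0
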