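"""The MoR factors B, S, O, their composition, and the information chain."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mor import (
    FeatureMatrix,
    biological_difference,
    build_chain,
    dispersion,
    overlap_dependent,
    overlap_independent,
    rank_transform,
    read_scores,
    score_features,
    u_transform,
    write_scores,
)


def u_grid(n):
    return u_transform(np.arange(1.0, n + 1), n)


class TestBiologicalDifference:
    def test_complete_separation_small(self):
        u = u_grid(4)
        assert biological_difference(u[2:], u[:2]) == pytest.approx(0.5)

    def test_identical_groups_zero(self):
        u = np.array([0.2, 0.5, 0.8])
        assert biological_difference(u, u) == pytest.approx(0.0)

    def test_complete_separation_n10(self):
        u = u_grid(20)
        assert biological_difference(u[10:], u[:10]) == pytest.approx(0.5)

    def test_bound_and_attainment_brute_force(self):
        """|B| <= 0.5 over all two-group splits (N <= 8); = 0.5 only at separation."""
        for n1 in range(1, 5):
            for n2 in range(1, 5):
                u = u_grid(n1 + n2)
                for idx in itertools.combinations(range(n1 + n2), n1):
                    g1 = np.array(idx)
                    g2 = np.setdiff1d(np.arange(n1 + n2), g1)
                    b = biological_difference(u[g1], u[g2])
                    assert abs(b) <= 0.5 + 1e-12
                    separated = set(idx) in ({*range(n1)}, {*range(n2, n1 + n2)})
                    assert (abs(abs(b) - 0.5) < 1e-12) == separated

    def test_distinct_b_values_count(self):
        """Untied data admit exactly n1*n2 + 1 distinct B values over all splits."""
        for n1, n2 in [(2, 2), (3, 2), (3, 3), (4, 3), (5, 5)]:
            u = u_grid(n1 + n2)
            vals = set()
            for idx in itertools.combinations(range(n1 + n2), n1):
                g1 = np.array(idx)
                g2 = np.setdiff1d(np.arange(n1 + n2), g1)
                vals.add(round(biological_difference(u[g1], u[g2]), 10))
            assert len(vals) == n1 * n2 + 1


class TestDispersion:
    def test_complete_separation_n10_closed_form(self):
        u = u_grid(20)
        # each group is an arithmetic grid of step 0.05
        assert dispersion(u[10:], u[:10]) == pytest.approx(0.05 * np.sqrt(99 / 12), abs=1e-9)

    def test_paired_identical_zero(self):
        u = np.array([0.1, 0.4, 0.7])
        assert dispersion(u, u, design="dependent") == pytest.approx(0.0)

    def test_pooled_of_equal_variances(self, rng):
        u1 = rng.random(30)
        u2 = u1 + 0.01  # same spread, shifted
        v = np.var(u1, ddof=0)
        assert dispersion(u1, u2) == pytest.approx(np.sqrt(v), rel=1e-9)


class TestOverlapIndependent:
    def test_complete_separation_n10(self):
        u = u_grid(20)
        o = overlap_independent(u[10:], u[:10])
        assert o == pytest.approx(1 / np.sqrt(0.25 * 0.2), abs=1e-9)  # 4.4721

    def test_equal_proportions_zero(self):
        u = u_grid(10)
        # both groups hold two values below and two above the pooled median
        assert overlap_independent(u[[0, 1, 8, 9]], u[[2, 3, 6, 7]]) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("gamma", [0.25, 0.5, 0.75, 0.9])
    def test_pooled_proportion_identity(self, rng, gamma):
        """On untied data the pooled exceedance fraction is 1 - gamma (+- 1/N)."""
        for _ in range(20):
            n1, n2 = rng.integers(4, 30, size=2)
            x = rng.standard_normal(n1 + n2)
            u = u_transform(rank_transform(x))
            u1, u2 = u[:n1], u[n1:]
            q = np.quantile(u, gamma)
            pbar = (np.sum(u1 > q) + np.sum(u2 > q)) / (n1 + n2)
            assert abs(pbar - (1 - gamma)) <= 1 / (n1 + n2) + 1e-12

    def test_degenerate_pbar_gives_zero(self):
        # nothing strictly above the threshold: pbar = 0, no information
        u1 = np.array([0.5, 0.5])
        u2 = np.array([0.5, 0.5])
        assert overlap_independent(u1, u2) == 0.0


class TestOverlapDependent:
    def test_all_positive_differences(self):
        u1 = np.linspace(0.6, 0.9, 10)
        u2 = np.linspace(0.1, 0.4, 10)
        assert overlap_dependent(u1, u2) == pytest.approx(1 / np.sqrt(0.05), abs=1e-9)

    def test_balanced_signs_zero(self):
        u1 = np.array([1.0] * 5 + [0.0] * 5)
        u2 = np.array([0.0] * 5 + [1.0] * 5)
        assert overlap_dependent(u1, u2) == pytest.approx(0.0)

    def test_all_ties_zero(self):
        u = np.full(6, 0.5)
        assert overlap_dependent(u, u) == 0.0


class TestMeasureOfRelevance:
    def test_worked_oracle_complete_separation(self, separated_matrix):
        """n1 = n2 = 10 complete separation: MoR = 4.4721 * 0.5 / 0.14361 = 15.571."""
        row = score_features(separated_matrix).iloc[0]
        assert row["B"] == pytest.approx(0.5)
        assert row["S"] == pytest.approx(0.14361, abs=1e-5)
        assert row["O"] == pytest.approx(4.47214, abs=1e-5)
        assert row["mor"] == pytest.approx(15.571, abs=2e-3)

    def test_identical_distributions_zero(self):
        vals = np.tile(np.array([[1.0], [2.0], [3.0]]), (2, 1))
        fm = FeatureMatrix(values=vals, group=np.array(["a"] * 3 + ["b"] * 3))
        assert score_features(fm)["mor"].iloc[0] == pytest.approx(0.0)

    def test_overlap_invariant_between_modes(self, rng):
        x = rng.standard_normal((20, 4))
        x[:10] += 1.0
        fm = FeatureMatrix(values=x, group=np.array(["a"] * 10 + ["b"] * 10))
        fm_mono = FeatureMatrix(
            values=np.exp(x), group=fm.group, feature_names=fm.feature_names
        )
        o_rank = score_features(fm, mode="rank")["O"]
        o_raw = score_features(fm_mono, mode="raw")["O"]
        pd.testing.assert_series_equal(o_rank, o_raw, check_names=False)

    def test_rank_mode_monotone_invariance(self, rng):
        x = rng.standard_normal((16, 3))
        fm = FeatureMatrix(values=x, group=np.array(["a"] * 8 + ["b"] * 8))
        fm2 = FeatureMatrix(values=np.tanh(x) * 9 + 1, group=fm.group,
                            feature_names=fm.feature_names)
        pd.testing.assert_frame_equal(
            score_features(fm)[["B", "S", "O", "mor"]],
            score_features(fm2)[["B", "S", "O", "mor"]],
            atol=1e-10,
        )

    def test_group_swap_negates_b_o_mor(self, rng):
        x = rng.standard_normal((14, 5))
        g = np.array(["a"] * 7 + ["b"] * 7)
        fm = FeatureMatrix(values=x, group=g, levels=("a", "b"))
        swapped = FeatureMatrix(values=x, group=g, levels=("b", "a"))
        s1, s2 = score_features(fm), score_features(swapped)
        for col in ("B", "O", "mor"):
            np.testing.assert_allclose(s1[col], -s2[col], atol=1e-10)
        np.testing.assert_allclose(s1["S"], s2["S"], atol=1e-12)

    def test_degenerate_constant_feature_flagged_zero(self):
        vals = np.column_stack([np.ones(8), np.arange(8.0)])
        fm = FeatureMatrix(values=vals, group=np.array(["a"] * 4 + ["b"] * 4))
        s = score_features(fm)
        assert s["degenerate"].iloc[0]
        assert s["mor"].iloc[0] == 0.0
        assert not s["degenerate"].iloc[1]

    def test_raw_mode_zero_spread_sentinel(self):
        # zero within-group spread but distinct means: off-scale sentinel, flagged
        vals = np.array([[2.0], [2.0], [2.0], [1.0], [1.0], [1.0]])
        fm = FeatureMatrix(values=vals, group=np.array(["a"] * 3 + ["b"] * 3))
        s = score_features(fm, mode="raw")
        assert s["degenerate"].iloc[0]
        assert s["mor"].iloc[0] == pytest.approx(1e6)

    def test_nominal_features_excluded_with_warning(self):
        vals = np.column_stack([np.arange(6.0), np.arange(6.0)])
        fm = FeatureMatrix(
            values=vals,
            group=np.array(["a"] * 3 + ["b"] * 3),
            feature_names=["cat", "ok"],
            feature_kind=["nominal", "metric"],
        )
        with pytest.warns(UserWarning, match="nominal"):
            s = score_features(fm)
        assert list(s.index) == ["ok"]

    def test_missing_values_per_feature_counts(self, rng):
        x = rng.standard_normal((12, 2))
        x[:3, 0] = np.nan
        fm = FeatureMatrix(values=x, group=np.array(["a"] * 6 + ["b"] * 6))
        s = score_features(fm)
        assert s["n1"].tolist() == [3, 6]
        assert np.isfinite(s["mor"]).all()

    def test_paired_design_uses_pairing(self, paired_matrix):
        s = score_features(paired_matrix)
        assert abs(s["mor"].iloc[0]) > abs(s["mor"].iloc[1])
        # all 8 differences positive for the shifted feature
        assert s["O"].iloc[0] == pytest.approx(1 / np.sqrt(0.25 * 2 / 8), abs=1e-9)

    def test_null_overlap_factor_is_near_standard_normal(self, rng):
        """Under identical continuous distributions O has sd within 15% of 1."""
        reps, n = 10_000, 50
        x = rng.standard_normal((2 * n, reps))
        fm = FeatureMatrix(values=x, group=np.array(["a"] * n + ["b"] * n))
        o = score_features(fm)["O"].to_numpy()
        assert abs(o.std() - 1.0) < 0.15


class TestInformationChain:
    def test_sorted_by_absolute_value(self):
        s = pd.DataFrame({"mor": [0.2, -5.0, 1.0]}, index=["a", "b", "c"])
        chain = build_chain(s)
        assert list(chain.index) == ["b", "c", "a"]
        assert chain["chain_rank"].tolist() == [1, 2, 3]

    def test_ties_keep_input_order(self):
        s = pd.DataFrame({"mor": [1.0, -1.0, 1.0]}, index=["a", "b", "c"])
        assert list(build_chain(s).index) == ["a", "b", "c"]

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40))
    @settings(deadline=None)
    def test_chain_is_non_increasing_permutation(self, mors):
        s = pd.DataFrame({"mor": mors}, index=[f"f{i}" for i in range(len(mors))])
        chain = build_chain(s)
        assert sorted(chain.index) == sorted(s.index)
        a = np.abs(chain["mor"].to_numpy())
        assert np.all(a[:-1] >= a[1:] - 1e-12)


def test_scores_roundtrip_tsv(tmp_path, separated_matrix):
    s = score_features(separated_matrix)
    chain = build_chain(s)
    path = tmp_path / "scores.tsv"
    write_scores(chain, path)
    back = read_scores(path)
    assert list(back.columns) == list(chain.columns)
    np.testing.assert_allclose(back["mor"], chain["mor"], rtol=1e-5)
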