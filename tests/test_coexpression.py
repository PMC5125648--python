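"""Co-expression core: filter, Pearson matrices, ΣR/ΔΣR, ΔR flags, tests."""

import logging

import numpy as np
import pandas as pd
import pytest

from conftest import symmetric_corr
from oracles import (corr_matrix_bruteforce, paired_t_bruteforce,
                     pearson_bruteforce, sum_r_bruteforce)
from pirna_coreg import coexpression as cx
from pirna_coreg import simulate as sim
from pirna_coreg.matrix import ExpressionMatrix


def make_matrix(values: dict, groups=None, unit="RPKM", controls=frozenset()):
    df = pd.DataFrame(values, dtype=float).T  # rows = features
    if groups is None:
        groups = pd.Series({c: ("A" if i < len(df.columns) // 2 else "B")
                            for i, c in enumerate(df.columns)})
    return ExpressionMatrix(df, unit, groups=groups, controls=controls)


class TestFilterExpressed:
    def test_zero_threshold_retains_everything(self, tiny_rpkm):
        out = cx.filter_expressed(tiny_rpkm, 0.0)
        assert list(out.features) == list(tiny_rpkm.features)

    def test_boundary_means_filter_exactly(self):
        E = make_matrix({"f1": [600, 600], "f2": [500, 500], "f3": [499.9, 499.9]},
                        groups=pd.Series({0: "A", 1: "B"}))
        out = cx.filter_expressed(E, 500.0)
        assert list(out.features) == ["f1", "f2"]

    def test_controls_survive_below_threshold(self):
        E = make_matrix({"f1": [600, 600], "RNU6-6P": [10, 10], "f2": [700, 700]},
                        groups=pd.Series({0: "A", 1: "B"}), controls={"RNU6-6P"})
        out = cx.filter_expressed(E, 500.0)
        assert list(out.features) == ["f1", "RNU6-6P", "f2"]  # order preserved

    def test_empty_result_advises_lower_threshold(self, tiny_rpkm):
        with pytest.raises(ValueError, match="lower the threshold"):
            cx.filter_expressed(tiny_rpkm, 1e12)

    def test_counts_unit_rejected(self, tiny_rpkm):
        tiny_rpkm.unit = "counts"
        with pytest.raises(ValueError, match="RPKM"):
            cx.filter_expressed(tiny_rpkm, 1.0)


class TestCountExpressedInAll:
    def test_all_zero(self):
        E = make_matrix({"f1": [0, 0], "f2": [0, 0]}, groups=pd.Series({0: "A", 1: "B"}))
        assert cx.count_expressed_in_all(E) == 0

    def test_strictly_positive(self, tiny_rpkm):
        assert cx.count_expressed_in_all(tiny_rpkm) == 5

    def test_one_dropout_sample_excludes_feature(self):
        E = make_matrix({"f1": [5, 0], "f2": [1, 2]}, groups=pd.Series({0: "A", 1: "B"}))
        assert cx.count_expressed_in_all(E) == 1


class TestPearsonMatrix:
    def test_self_correlation_is_one(self, tiny_rpkm):
        corr = cx.pearson_matrix(tiny_rpkm, "A")
        assert np.allclose(np.diag(corr.r.to_numpy()), 1.0)

    def test_antisymmetric_pair_gives_minus_one(self):
        E = make_matrix({"f1": [1, 2, 3], "f2": [3, 2, 1]},
                        groups=pd.Series({0: "A", 1: "A", 2: "A"}))
        corr = cx.pearson_matrix(E, "A")
        assert corr.r.loc["f1", "f2"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        """x=(1,2,3), y=(1,2,4): R = 3*sqrt(3)/(2*sqrt(7))."""
        E = make_matrix({"x": [1, 2, 3], "y": [1, 2, 4]},
                        groups=pd.Series({0: "A", 1: "A", 2: "A"}))
        corr = cx.pearson_matrix(E, "A")
        expected = 3 * np.sqrt(3) / (2 * np.sqrt(7))
        assert corr.r.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_bruteforce_formula(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            X = rng.uniform(1, 100, size=(10, 9))
            E = ExpressionMatrix(pd.DataFrame(X, index=[f"f{i}" for i in range(10)],
                                              columns=[f"s{j}" for j in range(9)]),
                                 "RPKM", groups=pd.Series("A", index=[f"s{j}" for j in range(9)]))
            R = cx.pearson_matrix(E, "A").r.to_numpy()
            brute = np.array(corr_matrix_bruteforce(X.tolist()))
            assert np.abs(R - brute).max() < 1e-12

    def test_constant_feature_yields_nan_sentinel(self, caplog):
        E = make_matrix({"f1": [1, 2, 3], "f2": [5, 5, 5], "f3": [2, 1, 4]},
                        groups=pd.Series({0: "A", 1: "A", 2: "A"}))
        with caplog.at_level(logging.WARNING):
            corr = cx.pearson_matrix(E, "A")
        assert np.isnan(corr.r.loc["f1", "f2"])
        assert corr.r.loc["f2", "f2"] == 1.0
        assert any("constant" in r.message for r in caplog.records)
        # downstream: the NaN partner shrinks the partner count
        scores = cx.sum_r(corr)
        assert scores.loc["f1", "n_partners"] == 1

    def test_too_few_samples_rejected(self, tiny_rpkm):
        tiny_rpkm.groups[:] = ["A", "A", "B", "B", "B", "B", "B", "B"]
        with pytest.raises(ValueError, match="need >= 3"):
            cx.pearson_matrix(tiny_rpkm, "A")


class TestSumR:
    def test_two_features_share_their_single_r(self):
        corr = symmetric_corr(np.array([[1.0, 0.6], [0.6, 1.0]]), ["f1", "f2"])
        scores = cx.sum_r(corr)
        assert scores["sum_r"].tolist() == pytest.approx([0.6, 0.6])

    def test_saturated_matrix_gives_partner_count(self):
        n = 38
        R = np.ones((n, n))
        corr = symmetric_corr(R, [f"f{i:02d}" for i in range(n)])
        scores = cx.sum_r(corr)
        assert scores["sum_r"].tolist() == pytest.approx([37.0] * n)
        assert scores["mean_r"].tolist() == pytest.approx([1.0] * n)

    def test_three_feature_direct_summation(self):
        R = np.array([[1.0, 0.2, 0.5], [0.2, 1.0, -0.1], [0.5, -0.1, 1.0]])
        corr = symmetric_corr(R, ["f1", "f2", "f3"])
        scores = cx.sum_r(corr)
        assert scores["sum_r"].tolist() == pytest.approx([0.7, 0.1, 0.4])

    def test_control_excluded_from_partner_sums_but_scored(self):
        R = np.array([[1.0, 0.2, 0.5], [0.2, 1.0, -0.1], [0.5, -0.1, 1.0]])
        corr = symmetric_corr(R, ["f1", "f2", "RNU6-6P"])
        scores = cx.sum_r(corr, exclude={"RNU6-6P"})
        assert scores.loc["f1", "sum_r"] == pytest.approx(0.2)
        assert scores.loc["f1", "n_partners"] == 1
        # the control itself is still reported, over non-control partners
        assert scores.loc["RNU6-6P", "sum_r"] == pytest.approx(0.4)

    def test_agrees_with_bruteforce_summation(self):
        rng = np.random.default_rng(5)
        feats = [f"f{i}" for i in range(8)]
        A = rng.uniform(-1, 1, (8, 8))
        R = (A + A.T) / 2
        np.fill_diagonal(R, 1.0)
        corr = symmetric_corr(R, feats)
        got = cx.sum_r(corr)["sum_r"].tolist()
        assert got == pytest.approx(sum_r_bruteforce(R.tolist()), abs=1e-12)

    def test_too_few_noncontrol_features_rejected(self):
        corr = symmetric_corr(np.eye(2), ["f1", "RNU6-6P"])
        with pytest.raises(ValueError, match="non-control"):
            cx.sum_r(corr, exclude={"RNU6-6P"})


class TestDeltaSumR:
    def _pair(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        feats = [f"f{i}" for i in range(n)]
        def rand_corr():
            A = rng.uniform(-1, 1, (n, n))
            R = (A + A.T) / 2
            np.fill_diagonal(R, 1.0)
            return symmetric_corr(R, feats)
        return rand_corr(), rand_corr()

    def test_identical_groups_give_zero_everywhere(self):
        ca, _ = self._pair()
        scores = cx.delta_sum_r(cx.sum_r(ca), cx.sum_r(ca))
        assert np.allclose(scores["delta_sum_r"], 0.0)

    def test_group_swap_negates_exactly(self):
        ca, cb = self._pair(3)
        fwd = cx.delta_sum_r(cx.sum_r(ca), cx.sum_r(cb))
        rev = cx.delta_sum_r(cx.sum_r(cb), cx.sum_r(ca))
        assert np.array_equal(fwd["delta_sum_r"].to_numpy(),
                              -rev["delta_sum_r"].to_numpy())

    def test_orientation_switch_negates(self):
        ca, cb = self._pair(4)
        fwd = cx.delta_sum_r(cx.sum_r(ca), cx.sum_r(cb))
        alt = cx.delta_sum_r(cx.sum_r(ca), cx.sum_r(cb), orientation="A_minus_B")
        assert np.array_equal(fwd["delta_sum_r"].to_numpy(),
                              -alt["delta_sum_r"].to_numpy())

    def test_ranking_descending_with_id_tiebreak(self):
        sA = pd.DataFrame({"sum_r": [0.0, 0.0, 0.0], "mean_r": [0.0] * 3},
                          index=["b", "a", "c"])
        sB = pd.DataFrame({"sum_r": [1.0, 1.0, 2.0], "mean_r": [0.3] * 3},
                          index=["b", "a", "c"])
        scores = cx.delta_sum_r(sA, sB)
        assert scores.loc["c", "rank"] == 1
        assert scores.loc["a", "rank"] == 2  # tie with b broken by id
        assert scores.loc["b", "rank"] == 3
        assert sorted(scores["rank"]) == [1, 2, 3]

    def test_mismatched_universes_listed(self):
        sA = pd.DataFrame({"sum_r": [0.1], "mean_r": [0.1]}, index=["a"])
        sB = pd.DataFrame({"sum_r": [0.1], "mean_r": [0.1]}, index=["z"])
        with pytest.raises(ValueError, match="only in A.*'a'.*only in B.*'z'"):
            cx.delta_sum_r(sA, sB)


class TestDeltaRMatrix:
    def test_identical_matrices_no_flags(self):
        R = np.array([[1.0, 0.8], [0.8, 1.0]])
        pairs = cx.delta_r_matrix(symmetric_corr(R, ["a", "b"], "A"),
                                  symmetric_corr(R, ["a", "b"], "B"))
        assert (pairs["delta_r"] == 0).all() and (pairs["flag"] == "none").all()

    def test_pair_weaker_in_group_a_is_flagged(self):
        RA = np.array([[1.0, 0.1], [0.1, 1.0]])
        RB = np.array([[1.0, 0.7], [0.7, 1.0]])
        pairs = cx.delta_r_matrix(symmetric_corr(RA, ["a", "b"], "A"),
                                  symmetric_corr(RB, ["a", "b"], "B"))
        row = pairs.iloc[0]
        assert row["delta_r"] == pytest.approx(0.6)
        assert row["flag"] == "decoupled_in_A"
        assert row["strength_A"] == "weak" and row["strength_B"] == "moderate"

    def test_strength_class_boundaries(self):
        for r, cls in [(0.75, "strong"), (0.7499, "moderate"), (0.5, "moderate"),
                       (0.4999, "weak"), (-0.2, "weak")]:
            R = np.array([[1.0, r], [r, 1.0]])
            pairs = cx.delta_r_matrix(symmetric_corr(R, ["a", "b"], "A"),
                                      symmetric_corr(R, ["a", "b"], "B"))
            assert pairs.iloc[0]["strength_A"] == cls

    def test_column_sum_identity_with_delta_sum_r(self):
        """ΣΔR per feature equals ΔΣR exactly (same exclusion set)."""
        rng = np.random.default_rng(9)
        feats = [f"f{i}" for i in range(5)]
        def rand_corr(group):
            A = rng.uniform(-1, 1, (5, 5))
            R = (A + A.T) / 2
            np.fill_diagonal(R, 1.0)
            return symmetric_corr(R, feats, group)
        ca, cb = rand_corr("A"), rand_corr("B")
        pairs = cx.delta_r_matrix(ca, cb)
        col_sums = cx.sum_delta_r(pairs, feats)
        scores = cx.delta_sum_r(cx.sum_r(ca), cx.sum_r(cb))
        assert np.allclose(col_sums.to_numpy(),
                           scores.loc[feats, "delta_sum_r"].to_numpy(), atol=1e-12)


class TestPerFeaturePairedTest:
    def _corr_from_vectors(self, ra_vec, rb_vec, feature="f0"):
        n = len(ra_vec) + 1
        feats = [feature] + [f"p{i}" for i in range(n - 1)]
        RA, RB = np.eye(n), np.eye(n)
        RA[0, 1:] = RA[1:, 0] = ra_vec
        RB[0, 1:] = RB[1:, 0] = rb_vec
        return (symmetric_corr(RA, feats, "A"), symmetric_corr(RB, feats, "B"))

    def test_identical_matrices_give_sentinel(self, caplog):
        ca, cb = self._corr_from_vectors([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        with caplog.at_level(logging.WARNING):
            t, p, lp = cx.per_feature_paired_test(ca, cb, "f0")
        assert np.isnan(t) and np.isnan(p) and np.isnan(lp)
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_symmetric_differences_give_t_zero_p_one(self):
        ca, cb = self._corr_from_vectors([0.5, 0.2, -0.1], [-0.5, 0.2, 0.9])
        t, p, _ = cx.per_feature_paired_test(ca, cb, "f0")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula_on_random_instance(self):
        rng = np.random.default_rng(21)
        ra = rng.uniform(-0.9, 0.9, 10)
        rb = rng.uniform(-0.9, 0.9, 10)
        ca, cb = self._corr_from_vectors(ra, rb)
        t, p, lp = cx.per_feature_paired_test(ca, cb, "f0")
        t_ref, p_ref = paired_t_bruteforce(ra, rb)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)
        assert lp == pytest.approx(np.log10(p_ref), abs=1e-10)

    def test_too_few_partners_rejected(self):
        ca, cb = self._corr_from_vectors([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError, match="partner"):
            cx.per_feature_paired_test(ca, cb, "f0")


class TestGlobalMeanTest:
    def test_identical_vectors_give_sentinel(self):
        v = pd.Series([0.1, 0.2, 0.3, 0.4])
        out = cx.global_mean_test(v, v)
        assert np.isnan(out["p"]) and out["direction"] == "equal"

    def test_constant_shift_detected_with_direction(self):
        rng = np.random.default_rng(8)
        a = pd.Series(rng.uniform(0.0, 0.4, 38))
        b = a + 0.3 + rng.normal(0, 0.01, 38)
        out = cx.global_mean_test(a, b)
        assert out["p"] < 1e-10 and out["direction"] == "A lower"
        # closed-form cross-check
        _, p_ref = paired_t_bruteforce(a.tolist(), b.tolist())
        assert out["p"] == pytest.approx(p_ref, rel=1e-9)


class TestClusterSamples:
    def test_two_distinct_group_profiles_separate_perfectly(self):
        rng = np.random.default_rng(2)
        proto_a = rng.uniform(10, 200, 6)
        proto_b = rng.uniform(10, 200, 6)
        cols = [proto_a + rng.normal(0, 1, 6) for _ in range(4)]
        cols += [proto_b + rng.normal(0, 1, 6) for _ in range(4)]
        base = np.abs(np.column_stack(cols))
        E = ExpressionMatrix(pd.DataFrame(base, index=[f"f{i}" for i in range(6)],
                                          columns=[f"s{j}" for j in range(8)]),
                             "RPKM",
                             groups=pd.Series(["A"] * 4 + ["B"] * 4,
                                              index=[f"s{j}" for j in range(8)]))
        assert cx.cluster_samples(E)["ari"] == pytest.approx(1.0)

    def test_random_labels_give_near_zero_agreement(self):
        rng = np.random.default_rng(6)
        aris = []
        for rep in range(30):
            X = rng.uniform(1, 100, size=(10, 8))
            E = ExpressionMatrix(pd.DataFrame(X, index=[f"f{i}" for i in range(10)],
                                              columns=[f"s{j}" for j in range(8)]),
                                 "RPKM",
                                 groups=pd.Series(rng.permutation(["A"] * 4 + ["B"] * 4),
                                                  index=[f"s{j}" for j in range(8)]))
            aris.append(cx.cluster_samples(E)["ari"])
        assert abs(np.mean(aris)) < 0.15

    def test_duplicate_samples_merge_first(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(1, 100, size=(6, 4))
        X[:, 1] = X[:, 0]  # s1 duplicates s0
        E = ExpressionMatrix(pd.DataFrame(X, index=[f"f{i}" for i in range(6)],
                                          columns=["s0", "s1", "s2", "s3"]),
                             "RPKM", groups=pd.Series(["A", "A", "B", "B"],
                                                      index=["s0", "s1", "s2", "s3"]))
        Z = cx.cluster_samples(E)["linkage"]
        assert sorted(Z[0, :2]) == [0, 1] and Z[0, 2] == pytest.approx(0.0)


class TestModelLevelProperties:
    def test_permuted_group_labels_center_delta_sum_r_at_zero(self, cohort):
        """Permutation null: per-feature mean ΔΣR over label permutations
        stays within 3 standard errors of zero."""
        _, rpkm, _ = cohort
        rng = np.random.default_rng(0)
        X = rpkm.values.to_numpy()
        n = X.shape[1] // 2
        deltas = np.empty((500, X.shape[0]))
        for b in range(500):
            perm = rng.permutation(X.shape[1])
            RA = np.corrcoef(X[:, perm[:n]])
            RB = np.corrcoef(X[:, perm[n:]])
            np.fill_diagonal(RA, 0.0)
            np.fill_diagonal(RB, 0.0)
            deltas[b] = RB.sum(1) - RA.sum(1)
        # features are mutually correlated (the module moves as a block),
        # so the per-permutation feature-averaged delta carries the valid
        # independent-draw standard error
        grand = deltas.mean(axis=1)
        se_grand = grand.std(ddof=1) / np.sqrt(len(grand))
        assert abs(grand.mean()) < 3 * se_grand
        # marginal per-feature check, tolerant of the block correlation
        mean = deltas.mean(axis=0)
        se = deltas.std(axis=0, ddof=1) / np.sqrt(deltas.shape[0])
        assert (np.abs(mean) < 3 * se + 1e-9).mean() > 0.8

    def test_decoupled_features_lose_mean_correlation_in_group_a(self, reference):
        """Monte-Carlo: truth.decoupled features have meanR_A < meanR_B."""
        diffs = []
        for rep in range(100):
            cfg = sim.SimulationConfig(seed=5000 + rep)
            _, rpkm, truth = sim.simulate_expression(cfg, reference)
            ca = cx.pearson_matrix(rpkm, "A")
            cb = cx.pearson_matrix(rpkm, "B")
            sa, sb = cx.sum_r(ca), cx.sum_r(cb)
            for f in truth.decoupled:
                diffs.append(sb.loc[f, "mean_r"] - sa.loc[f, "mean_r"])
        diffs = np.asarray(diffs)
        # positive in expectation: mean many standard errors above zero
        assert diffs.mean() > 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))
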