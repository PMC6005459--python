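"""Tests for filtering, clustering, moderated DE, overlap and metagenes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtprofiler import expression as ex
from wtprofiler import synthetic
from wtprofiler.expression import (ExpressionMatrix, MarkerGeneSet,
                                   compare_metagene, exclude_probes,
                                   hierarchical_cluster, metagene_scores,
                                   moderated_de, select_by_fold_and_fdr,
                                   signature_overlap, variance_filter)

from conftest import make_expression


class TestVarianceFilter:
    def test_keep_all_is_identity(self, expr_matrix):
        out = variance_filter(expr_matrix, 1.0)
        pd.testing.assert_frame_equal(out.values, expr_matrix.values)

    def test_top_half_matches_brute_force(self):
        m = make_expression(n_probes=10, seed=3)
        out = variance_filter(m, 0.5)
        var = m.values.var(axis=1, ddof=1)
        expected = set(var.sort_values(ascending=False).index[:5])
        assert set(out.probe_ids) == expected

    def test_constant_probe_never_retained(self):
        m = make_expression(n_probes=9, seed=4)
        vals = m.values.copy()
        vals.loc["P00000"] = 5.0  # constant
        m2 = ExpressionMatrix(values=vals, sample_groups=m.sample_groups)
        out = variance_filter(m2, 0.5)
        assert "P00000" not in out.probe_ids

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, expr_matrix, bad):
        with pytest.raises(ValueError):
            variance_filter(expr_matrix, bad)


class TestExcludeProbes:
    def test_empty_blacklist_identity(self, expr_matrix):
        out = exclude_probes(expr_matrix, [])
        pd.testing.assert_frame_equal(out.values, expr_matrix.values)

    def test_full_blacklist_rejected(self, expr_matrix):
        with pytest.raises(ValueError):
            exclude_probes(expr_matrix, expr_matrix.probe_ids)

    def test_random_blacklist_set_difference(self):
        m = make_expression(n_probes=30, seed=5)
        rng = np.random.default_rng(5)
        bl = list(rng.choice(m.probe_ids, size=12, replace=False)) + ["NOT_A_PROBE"]
        out = exclude_probes(m, bl)
        assert set(out.probe_ids) == set(m.probe_ids) - set(bl)

    def test_filter_and_exclude_compose_to_identity(self, expr_matrix):
        out = exclude_probes(variance_filter(expr_matrix, 1.0), [])
        pd.testing.assert_frame_equal(out.values, expr_matrix.values)


class TestClustering:
    @staticmethod
    def _matrix_from_1d(values, labels):
        df = pd.DataFrame([values], index=["P0"], columns=labels)
        # second constant probe so Euclidean distance equals |x_i - x_j|
        df.loc["P1"] = 0.0
        return ExpressionMatrix(values=df,
                                sample_groups=pd.Series(["g"] * len(labels), index=labels))

    def test_hand_worked_upgma_merge_order(self):
        """Samples at 0, 2, 10, 16 on a line: UPGMA merges (A,B) at 2,
        (C,D) at 6, then the two pairs at mean distance 12."""
        m = self._matrix_from_1d([0.0, 2.0, 10.0, 16.0], ["A", "B", "C", "D"])
        res = hierarchical_cluster(m)
        Z = res.linkage_matrix
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(2.0)
        assert {int(Z[1, 0]), int(Z[1, 1])} == {2, 3}
        assert Z[1, 2] == pytest.approx(6.0)
        assert Z[2, 2] == pytest.approx((10 + 16 + 8 + 14) / 4)
        for label in ("A", "B", "C", "D"):
            assert label in res.newick

    def test_identical_samples_merge_at_zero(self):
        m = self._matrix_from_1d([1.0, 1.0, 5.0], ["A", "B", "C"])
        Z = hierarchical_cluster(m).linkage_matrix
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_merge_heights_non_decreasing(self):
        m = make_expression(n_probes=30, n_a=6, n_b=6, seed=8)
        Z = hierarchical_cluster(m).linkage_matrix
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_planted_subgroups_form_top_clades(self):
        """Two subgroups 5 SD apart split at the root in >= 95% of seeds."""
        hits = 0
        for seed in range(40):
            m = make_expression(n_probes=40, n_a=4, n_b=4, seed=seed,
                                shift_first=40, shift=5.0)
            Z = hierarchical_cluster(m).linkage_matrix
            # the last merge joins two clades; check they are the two groups
            from scipy.cluster.hierarchy import fcluster
            two = fcluster(Z, t=2, criterion="maxclust")
            if len(set(two[:4])) == 1 and len(set(two[4:])) == 1 and two[0] != two[-1]:
                hits += 1
        assert hits >= 38


# frozen oracle: Bioconductor limma (lmFit + eBayes) run once on the seeded
# fixture reproduced by _limma_fixture(); moderated t and two-sided p per probe
_LIMMA_T = np.array([
    4.890219533, 6.732618879, 4.535301096, 4.163852475, 5.195550445,
    -0.753035467, -0.424114361, -1.733730601, -1.890096238, 1.045395834,
    0.913817102, -0.962985954, 0.904693257, -2.298124900, -1.333970336,
    -1.629638239, 0.078857511, -2.011932641, 0.596512492, 0.700759602,
    1.355770105, -1.368859223, -1.124908761, 1.237983587, -0.603891776,
    0.428731903, -0.634038339, 1.106929437, -0.132280296, -0.031823328])
_LIMMA_P = np.array([
    3.758996e-04, 2.133263e-05, 6.895073e-04, 1.323603e-03, 2.261321e-04,
    4.659968e-01, 6.790125e-01, 1.086476e-01, 8.322335e-02, 3.165136e-01,
    3.788709e-01, 3.546257e-01, 3.834940e-01, 4.040600e-02, 2.070646e-01,
    1.292200e-01, 9.384503e-01, 6.731544e-02, 5.619566e-01, 4.968635e-01,
    2.002254e-01, 1.962092e-01, 2.827018e-01, 2.394788e-01, 5.571992e-01,
    6.757405e-01, 5.379964e-01, 2.900962e-01, 8.969625e-01, 9.751380e-01])
_LIMMA_D0 = 3.957337722
_LIMMA_S02 = 0.3467332245


def _limma_fixture() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    n, na, nb = 30, 5, 5
    vals = 7 + rng.standard_normal((n, na + nb)) * rng.uniform(0.3, 1.2, size=(n, 1))
    vals[:5, :na] += 1.5
    df = pd.DataFrame(vals, index=[f"P{i:03d}" for i in range(n)],
                      columns=[f"A{j}" for j in range(na)] + [f"B{j}" for j in range(nb)])
    groups = pd.Series(["a"] * na + ["b"] * nb, index=df.columns)
    return ExpressionMatrix(values=df, sample_groups=groups)


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini–Hochberg step-up adjusted p values."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestModeratedDe:
    def test_matches_reference_empirical_bayes_fit(self):
        """Moderated t, p and the fitted variance prior agree with the
        reference empirical-Bayes implementation on a frozen fixture."""
        de = moderated_de(_limma_fixture(), "a", "b")
        assert de.attrs["prior_df"] == pytest.approx(_LIMMA_D0, rel=1e-6)
        assert de.attrs["prior_var"] == pytest.approx(_LIMMA_S02, rel=1e-6)
        np.testing.assert_allclose(de["t"], _LIMMA_T, rtol=1e-6)
        np.testing.assert_allclose(de["p_value"], _LIMMA_P, rtol=1e-4)

    def test_identical_group_means_give_t_zero_p_one(self):
        m = make_expression(n_probes=10, seed=2)
        vals = m.values.copy()
        vals.loc["P00000"] = list(range(5)) + list(range(5))  # equal means
        m2 = ExpressionMatrix(values=vals, sample_groups=m.sample_groups)
        de = moderated_de(m2, "a", "b")
        assert de.loc["P00000", "t"] == 0.0
        assert de.loc["P00000", "p_value"] == 1.0

    def test_prior_df_zero_recovers_ordinary_t(self):
        """As the prior df -> 0 no shrinkage remains: the moderated t equals
        the ordinary two-sample pooled t."""
        from scipy import stats
        m = make_expression(n_probes=25, seed=6)
        de = moderated_de(m, "a", "b", prior_df=0.0)
        A = m.values.iloc[:, :5].to_numpy()
        B = m.values.iloc[:, 5:].to_numpy()
        t_ref, p_ref = stats.ttest_ind(A, B, axis=1, equal_var=True)
        np.testing.assert_allclose(de["t"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(de["p_value"], p_ref, rtol=1e-10)

    def test_insufficient_samples_rejected(self, expr_matrix):
        groups = expr_matrix.sample_groups.copy()
        groups.iloc[:] = ["a"] + ["b"] * 9
        m = ExpressionMatrix(values=expr_matrix.values, sample_groups=groups)
        with pytest.raises(ValueError, match="2 samples per group"):
            moderated_de(m, "a", "b")

    def test_bh_adjustment_matches_step_up_oracle(self):
        de = moderated_de(_limma_fixture(), "a", "b")
        np.testing.assert_allclose(de["adj_p_value"],
                                   _bh_oracle(de["p_value"].to_numpy()), rtol=1e-12)
        assert (de["adj_p_value"] >= de["p_value"] - 1e-15).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_bh_oracle_matches_library_on_any_pvalues(self, pvals):
        """The packaged BH route (statsmodels step-up) equals the brute-force
        oracle on arbitrary inputs up to 50 tests."""
        from statsmodels.stats.multitest import multipletests
        p = np.asarray(pvals)
        np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1],
                                   _bh_oracle(p), rtol=1e-12, atol=1e-15)


class TestSelection:
    def test_all_p_one_empty_lists(self):
        de = pd.DataFrame({"log_fc": [2.0, -2.0], "adj_p_value": [1.0, 1.0]},
                          index=["a", "b"])
        assert select_by_fold_and_fdr(de) == ([], [])

    def test_toy_table_matches_predicate(self):
        de = pd.DataFrame({
            "log_fc":      [1.5, 1.0, 0.5, -1.2, -3.0, 2.0],
            "adj_p_value": [0.001, 0.005, 0.001, 0.02, 0.0001, 0.5],
        }, index=list("abcdef"))
        up, down = select_by_fold_and_fdr(de, fold_min=2.0, adj_p_max=0.01)
        assert up == ["a", "b"]
        assert down == ["e"]

    def test_fold_one_reduces_to_fdr_only(self):
        de = pd.DataFrame({"log_fc": [0.1, -0.1, 0.0],
                           "adj_p_value": [0.001, 0.001, 0.001]},
                          index=list("abc"))
        up, down = select_by_fold_and_fdr(de, fold_min=1.0, adj_p_max=0.01)
        assert up == ["a"] and down == ["b"]


class TestSignatureOverlap:
    def test_printed_counts_round_to_integers(self):
        """51 of 80 and 15 of 19 give 64% and 79% at integer rounding."""
        q_up = [f"u{i}" for i in range(80)]
        r_up = q_up[:51] + [f"x{i}" for i in range(100)]
        q_down = [f"d{i}" for i in range(19)]
        r_down = q_down[:15] + ["y1"]
        res = signature_overlap(q_up, q_down, r_up, r_down)
        assert (res["up"]["n_overlap"], res["up"]["percent"]) == (51, 64)
        assert (res["down"]["n_overlap"], res["down"]["percent"]) == (15, 79)

    def test_disjoint_sets_zero_percent(self):
        res = signature_overlap(["a"], ["b"], ["c"], ["d"])
        assert res["up"]["percent"] == 0 and res["down"]["percent"] == 0

    def test_query_subset_full_percent(self):
        res = signature_overlap(["a", "b"], [], ["a", "b", "c"], ["d"])
        assert res["up"]["percent"] == 100

    def test_empty_query_reported_missing(self):
        res = signature_overlap([], [], ["a"], ["b"])
        assert res["up"]["percent"] is None


class TestMetagene:
    def test_rank_one_submatrix_full_variance_explained(self):
        """All marker genes proportional to one pattern: the first singular
        component carries everything and scores follow the pattern."""
        pattern = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        genes = [f"P{i:05d}" for i in range(4)]
        vals = pd.DataFrame([p * pattern for p in (1.0, 2.0, -1.0, 0.5)],
                            index=genes,
                            columns=[f"S{j}" for j in range(6)])
        m = ExpressionMatrix(values=vals,
                             sample_groups=pd.Series(["g"] * 6, index=vals.columns))
        score = metagene_scores(m, MarkerGeneSet("s", tuple(genes)))
        assert score.variance_explained == pytest.approx(1.0, abs=1e-8)
        z = (pattern - pattern.mean()) / pattern.std(ddof=1)
        corr = np.corrcoef(score.scores, z)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-8)

    def test_shifted_subgroup_scores_higher(self):
        ms = MarkerGeneSet("s", tuple(f"P{i:05d}" for i in range(10)))
        truth = synthetic.ExpressionTruth(
            group_labels=("hi",) * 5 + ("lo",) * 10,
            effects={"s": ("hi", 3.0)}, n_probes=60, seed=17)
        m = synthetic.gen_expression_matrix(truth, [ms])
        score = metagene_scores(m, ms)
        hi = score.scores[(m.sample_groups == "hi").to_numpy()]
        lo = score.scores[(m.sample_groups == "lo").to_numpy()]
        assert hi.mean() > lo.mean()

    def test_sign_anchor_tracks_mean_marker_expression(self):
        """The anchor resolves only the SVD sign ambiguity: scores correlate
        positively with mean marker z-score, and negating the data negates
        the scores."""
        m = make_expression(n_probes=20, seed=19, shift_first=8, shift=2.0)
        ms = MarkerGeneSet("s", tuple(f"P{i:05d}" for i in range(8)))
        score = metagene_scores(m, ms)
        sub = m.values.loc[list(ms.gene_ids)]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
        assert np.corrcoef(score.scores, z.mean(axis=0))[0, 1] > 0
        neg = ExpressionMatrix(values=-m.values, sample_groups=m.sample_groups)
        score_neg = metagene_scores(neg, ms)
        np.testing.assert_allclose(score_neg.scores, -score.scores, atol=1e-8)

    def test_invariant_to_per_gene_affine_rescaling(self):
        m = make_expression(n_probes=20, seed=23)
        ms = MarkerGeneSet("s", tuple(f"P{i:05d}" for i in range(6)))
        base = metagene_scores(m, ms)
        rng = np.random.default_rng(23)
        scale = rng.uniform(0.5, 4.0, size=(20, 1))
        offset = rng.uniform(-5, 5, size=(20, 1))
        m2 = ExpressionMatrix(values=m.values * scale + offset,
                              sample_groups=m.sample_groups)
        rescaled = metagene_scores(m2, ms)
        np.testing.assert_allclose(rescaled.scores, base.scores, atol=1e-8)

    def test_zero_variance_genes_dropped_and_too_few_rejected(self):
        m = make_expression(n_probes=6, seed=29)
        vals = m.values.copy()
        vals.loc["P00000"] = 1.0
        vals.loc["P00001"] = 2.0
        m2 = ExpressionMatrix(values=vals, sample_groups=m.sample_groups)
        with pytest.raises(ValueError, match="usable"):
            metagene_scores(m2, MarkerGeneSet("s", ("P00000", "P00001")))
        ok = metagene_scores(m2, MarkerGeneSet("s", ("P00000", "P00001", "P00002",
                                                     "P00003")))
        assert ok.n_genes_dropped == 2 and ok.n_genes_used == 2


class TestCompareMetagene:
    @staticmethod
    def _score(values, samples):
        return ex.MetageneScore("s", pd.Series(values, index=samples), 1.0, "anchor",
                                2, 0)

    def test_equal_two_by_two_values_p_one(self):
        samples = list("wxyz")
        groups = pd.Series(["a", "a", "b", "b"], index=samples)
        cmp = compare_metagene(self._score([1.0, 1.0, 1.0, 1.0], samples),
                               groups, "a", "b")
        assert cmp["p_value"] == 1.0

    def test_well_separated_groups_significant(self):
        rng = np.random.default_rng(31)
        samples = [f"s{i}" for i in range(16)]
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=samples)
        vals = np.concatenate([rng.normal(5, 1, 8), rng.normal(0, 1, 8)])
        cmp = compare_metagene(self._score(vals, samples), groups, "a", "b")
        assert cmp["p_value"] < 0.01
        assert cmp["corrected"] is False

    def test_degenerate_groups_rejected(self):
        samples = list("wxy")
        groups = pd.Series(["a", "b", "b"], index=samples)
        with pytest.raises(ValueError):
            compare_metagene(self._score([1.0, 2.0, 3.0], samples), groups, "a", "b")

    def test_null_p_values_roughly_uniform(self):
        """Permuted labels: the Welch p distribution passes a KS uniformity
        check over seeds."""
        from scipy import stats
        rng = np.random.default_rng(37)
        samples = [f"s{i}" for i in range(12)]
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=samples)
        ps = []
        for _ in range(150):
            vals = rng.normal(0, 1, 12)
            ps.append(compare_metagene(self._score(vals, samples),
                                       groups, "a", "b")["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
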