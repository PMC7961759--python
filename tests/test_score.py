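"""ssGSEA, MPscore, stemness, immune scores, AUC, RF ranking, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from mprog import (ExpressionMatrix, SignatureSet, SsgseaParams,
                   group_compare, immune_scores, log_transform, mpscore,
                   mpscore_table, rf_marker_ranking, roc_auc, ssgsea,
                   ssgsea_matrix, stemness_index)
from mprog.simcohort import CohortSpec, simulate_cohort


def brute_force_ssgsea(values, gene_ids, gene_set, tau):
    """Independent running-sum walker: explicit gene-by-gene loop over the
    expression-ranked list."""
    rho = stats.rankdata(values, method="average")
    order = sorted(range(len(gene_ids)), key=lambda i: -rho[i])
    in_set = set(gene_set)
    denom_in = sum(abs(rho[i]) ** tau for i in order if gene_ids[i] in in_set)
    n_out = sum(1 for i in order if gene_ids[i] not in in_set)
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for i in order:
        if gene_ids[i] in in_set:
            p_in += abs(rho[i]) ** tau / denom_in
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_closed_form_four_genes(self):
        """Top-ranked singleton set of 4 genes, tau = 0: the running sum is
        (1-0) + (1-1/3) + (1-2/3) + (1-1) = 2."""
        es = ssgsea(np.array([9.0, 5.0, 3.0, 1.0]), ["a"],
                    SsgseaParams(tau=0.0), gene_ids=["a", "b", "c", "d"])
        assert es == pytest.approx(2.0, abs=1e-12)

    def test_interleaved_set_near_zero(self, rng):
        values = np.arange(20, 0, -1, dtype=float)
        gene_ids = [f"g{i}" for i in range(20)]
        gene_set = [f"g{i}" for i in range(0, 20, 2)]
        es = ssgsea(values, gene_set, SsgseaParams(tau=0.0),
                    gene_ids=gene_ids)
        expected = brute_force_ssgsea(values, gene_ids, gene_set, 0.0)
        assert es == pytest.approx(expected, abs=1e-10)
        assert abs(es) < 1.5

    @pytest.mark.parametrize("tau", [0.0, 0.25, 1.0])
    def test_matches_brute_force_random(self, tau, rng):
        for _ in range(20):
            values = rng.normal(size=50)
            gene_ids = [f"g{i}" for i in range(50)]
            gene_set = list(rng.choice(gene_ids, size=rng.integers(2, 20),
                                       replace=False))
            es = ssgsea(values, gene_set, SsgseaParams(tau=tau),
                        gene_ids=gene_ids)
            ref = brute_force_ssgsea(values, gene_ids, gene_set, tau)
            assert es == pytest.approx(ref, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        values = rng.normal(size=30)
        gene_ids = [f"g{i}" for i in range(30)]
        gene_set = [f"g{i}" for i in range(5)]
        a = ssgsea(values, gene_set, gene_ids=gene_ids)
        b = ssgsea(np.exp(values), gene_set, gene_ids=gene_ids)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_or_full_set_errors(self, rng):
        values = rng.normal(size=5)
        ids = list("abcde")
        with pytest.raises(ValueError, match="no overlap"):
            ssgsea(values, ["x"], gene_ids=ids)
        with pytest.raises(ValueError, match="every measured gene"):
            ssgsea(values, ids, gene_ids=ids)

    def test_cohort_normalization_divides_by_range(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 6)),
                             index=[f"g{i}" for i in range(30)],
                             columns=[f"s{j}" for j in range(6)])
        gene_set = [f"g{i}" for i in range(4)]
        raw = ssgsea_matrix(frame, gene_set, SsgseaParams(normalize=False))
        norm = ssgsea_matrix(frame, gene_set, SsgseaParams(normalize=True))
        np.testing.assert_allclose(norm, raw / (raw.max() - raw.min()),
                                   atol=1e-12)


class TestMpscore:
    def test_identical_up_down_is_zero(self, rng):
        """Up and down scores cancel exactly when the lists coincide (the
        SignatureSet forbids overlap, so compute the difference directly)."""
        values = rng.normal(size=40)
        ids = [f"g{i}" for i in range(40)]
        genes = [f"g{i}" for i in range(7)]
        up = ssgsea(values, genes, gene_ids=ids)
        down = ssgsea(values, list(genes), gene_ids=ids)
        assert up - down == 0.0

    def test_antisymmetric_under_swap(self, rng):
        values = rng.normal(size=40)
        ids = [f"g{i}" for i in range(40)]
        sig = SignatureSet("s", up=ids[:5], down=ids[5:12])
        swapped = SignatureSet("s", up=ids[5:12], down=ids[:5])
        a = mpscore(values, sig, gene_ids=ids)
        b = mpscore(values, swapped, gene_ids=ids)
        assert a == pytest.approx(-b, abs=1e-12)

    def test_raising_up_genes_never_decreases(self, rng):
        values = rng.normal(size=30)
        ids = [f"g{i}" for i in range(30)]
        sig = SignatureSet("s", up=ids[:4], down=ids[4:8])
        base = mpscore(values, sig, gene_ids=ids)
        boosted = values.copy()
        boosted[:4] += 10.0
        assert mpscore(boosted, sig, gene_ids=ids) >= base - 1e-12

    def test_subtype3_highest_on_planted_cohort(self, small_cohort,
                                                small_log_expr):
        sig = SignatureSet("planted",
                           up=small_cohort.truth["signature_up"],
                           down=small_cohort.truth["signature_down"])
        table = mpscore_table(small_log_expr, sig)
        np.testing.assert_allclose(
            table["mpscore"],
            table["ssgsea_up"] - table["ssgsea_down"], atol=1e-12)
        subtype = small_cohort.annotations["subtype"]
        means = table["mpscore"].groupby(subtype.to_numpy()).mean()
        assert means.idxmax() == 3
        for other in (1, 2, 4):
            t = stats.ttest_ind(table["mpscore"][subtype.to_numpy() == 3],
                                table["mpscore"][subtype.to_numpy() == other])
            assert t.pvalue < 0.01


class TestStemnessIndex:
    def make(self, rng):
        n = 30
        ids = [f"g{i}" for i in range(n)]
        weights = pd.Series(rng.normal(size=n), index=ids)
        aligned = weights.rank()                      # same ranks as weights
        anti = -weights.rank()
        mid = pd.Series(rng.normal(size=n), index=ids)
        frame = pd.DataFrame({"aligned": aligned, "anti": anti, "mid": mid})
        return weights, frame

    def test_rank_aligned_sample_is_max(self, rng):
        weights, frame = self.make(rng)
        si = stemness_index(frame, weights)
        assert si.loc["aligned", "si_raw"] == pytest.approx(1.0)
        assert si.loc["aligned", "si"] == 1.0
        assert si.loc["anti", "si_raw"] == pytest.approx(-1.0)
        assert si.loc["anti", "si"] == 0.0

    def test_affine_rescale(self):
        ids = [f"g{i}" for i in range(12)]
        w = pd.Series(np.arange(12, dtype=float), index=ids)
        frame = pd.DataFrame({
            "a": np.arange(12, dtype=float),           # rho = 1
            "b": -np.arange(12, dtype=float),          # rho = -1
            "c": [6, 3, 1, 9, 4, 11, 0, 8, 2, 10, 5, 7],
        }, index=ids).astype(float)
        rho_c = stats.spearmanr(w, frame["c"]).statistic
        si = stemness_index(frame, w)
        np.testing.assert_allclose(
            si["si"], [(1 - -1) / 2, 0.0, (rho_c + 1) / 2], atol=1e-12)

    def test_insufficient_overlap_errors(self, rng):
        frame = pd.DataFrame(rng.normal(size=(5, 2)),
                             index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="overlap"):
            stemness_index(frame, pd.Series(np.ones(5),
                                            index=[f"g{i}" for i in range(5)]))


class TestImmuneScores:
    def test_single_marker_equals_gene(self, rng):
        frame = pd.DataFrame(rng.normal(5, 1, size=(10, 4)),
                             index=[f"g{i}" for i in range(10)],
                             columns=list("abcd"))
        scores = immune_scores(frame, {"pop": ["g3"]})
        np.testing.assert_allclose(scores["pop"], frame.loc["g3"])

    def test_doubling_tpm_adds_one(self, rng):
        tpm = rng.uniform(1, 100, size=(6, 3))
        ids = [f"g{i}" for i in range(6)]
        a = immune_scores(pd.DataFrame(np.log2(tpm), index=ids), {"p": ids[:3]})
        b = immune_scores(pd.DataFrame(np.log2(2 * tpm), index=ids),
                          {"p": ids[:3]})
        np.testing.assert_allclose(b["p"] - a["p"], 1.0, atol=1e-12)

    def test_missing_panel_errors(self, rng):
        frame = pd.DataFrame(rng.normal(size=(4, 2)),
                             index=[f"g{i}" for i in range(4)])
        with pytest.raises(ValueError, match="panelX"):
            immune_scores(frame, {"panelX": ["nope"]})

    def test_cytotoxic_highest_in_subtype3(self, small_cohort,
                                           small_log_expr):
        scores = immune_scores(small_log_expr,
                               small_cohort.truth["immune_markers"])
        subtype = small_cohort.annotations["subtype"].to_numpy()
        means = scores["Cytotoxic_lymphocytes"].groupby(subtype).mean()
        assert means.idxmax() == 3


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_three_of_four_concordant(self):
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_all_tied_is_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_invariance_and_complement(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert roc_auc(-scores, labels) == pytest.approx(1 - a, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestRfMarkerRanking:
    def test_perfect_separator_found(self, rng):
        n = 60
        x = rng.normal(size=(n, 100))
        y_true = np.array([0] * 30 + [1] * 30)
        x[:, 42] = y_true * 4 + rng.normal(0, 0.3, size=n)
        m = pd.DataFrame(x.T, index=[f"g{i}" for i in range(100)])

        class M:
            values = m.to_numpy()
            gene_ids = list(m.index)
            sample_ids = list(m.columns)

        ranking = rf_marker_ranking(M, y_true, 1, n_trees=80, cv_folds=5,
                                    seed=0)
        assert ranking.rank["g42"] == 1
        assert ranking.cv_error.loc[1] <= 0.05
        assert sorted(ranking.rank) == list(range(1, 101))

    def test_permuted_labels_no_signal(self, rng):
        n = 60
        x = rng.normal(size=(n, 80))
        y = rng.permutation([0] * 30 + [1] * 30)
        m = pd.DataFrame(x.T, index=[f"g{i}" for i in range(80)])

        class M:
            values = m.to_numpy()
            gene_ids = list(m.index)
            sample_ids = list(m.columns)

        ranking = rf_marker_ranking(M, y, 1, n_trees=60, cv_folds=5, seed=1)
        imp = ranking.importance
        z = (imp.max() - imp.mean()) / imp.std()
        assert z < 5.0  # no feature stands far outside the noise importance

    def test_downshifted_marker_gene_auc(self):
        """An ALPL-like gene strongly down-shifted only in the progressive
        subtype discriminates it by single-gene AUC."""
        cohort = simulate_cohort(CohortSpec(
            n_per_subtype=(20, 15, 20, 10), n_genes=300, n_signature_up=5,
            n_signature_down=5, n_program_genes=5, effect_log2fc=2.0,
            immune_panels={}, n_cpg=50, n_cpg_variable=10, n_cpg_dm=10, seed=6))
        logm = log_transform(cohort.expression)
        down_gene = cohort.truth["signature_down"][0]
        expr = logm.to_frame().loc[down_gene]
        is3 = (cohort.annotations["subtype"] == 3).astype(int)
        assert roc_auc(-expr, is3) >= 0.85

    def test_invalid_step_errors(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 20)))

        class M:
            values = m.to_numpy().T
            gene_ids = [f"g{i}" for i in range(5)]
            sample_ids = list(range(20))

        with pytest.raises(ValueError, match="step"):
            rf_marker_ranking(M, np.array([0, 1] * 10), 1, step=1.0)


class TestGroupCompare:
    def test_identical_constants(self):
        res = group_compare([3.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res["f"] == 0.0 and res["p"] == 1.0

    def test_two_groups_f_is_t_squared(self, rng):
        values = rng.normal(size=20)
        groups = np.array(["x"] * 10 + ["y"] * 10)
        res = group_compare(values, groups)
        t = stats.ttest_ind(values[:10], values[10:], equal_var=True)
        assert res["f"] == pytest.approx(t.statistic ** 2, abs=1e-10)

    def test_three_group_hand_computed(self):
        """F from explicit sums of squares: groups {1,2,3}, {2,3,4},
        {4,5,6}."""
        values = np.array([1, 2, 3, 2, 3, 4, 4, 5, 6], dtype=float)
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        grand = values.mean()
        ss_between = 3 * sum((values[groups == g].mean() - grand) ** 2
                             for g in "abc")
        ss_within = sum(((values[groups == g]
                          - values[groups == g].mean()) ** 2).sum()
                        for g in "abc")
        f_manual = (ss_between / 2) / (ss_within / 6)
        res = group_compare(values, groups)
        assert res["f"] == pytest.approx(f_manual, abs=1e-10)
        assert len(res["tukey"]) == 3

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])
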