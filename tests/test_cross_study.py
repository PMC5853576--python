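"""Cross-study harmonization, conflict sets, overlap tests, clustering."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skbio.tree import TreeNode

from kranzsep import (
    agreement_fraction,
    back_calculate_tpm,
    build_conflict_sets,
    cluster_samples,
    developmental_switch_classification,
    keyword_set_expression,
    make_study_result,
    overlap_test,
    quantile_normalize_lfc,
)


def enum_fisher_p(k, K, n, N):
    """Exact two-sided hypergeometric enumeration in integer arithmetic."""
    lo, hi = max(0, K + n - N), min(K, n)
    weights = [comb(K, x) * comb(N - K, n - x) for x in range(lo, hi + 1)]
    wk = weights[k - lo]
    return sum(w for w in weights if w <= wk) / comb(N, n)


def study(genes, lfc, p=None, fdr=None, stage="s1", study_id="A"):
    n = len(genes)
    p = [0.5] * n if p is None else p
    fdr = p if fdr is None else fdr
    return make_study_result(genes, lfc, p, fdr, [10.0] * n, study_id=study_id, stage_id=stage)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [1.0, -2.0, 3.0], "b": [1.0, -2.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize_lfc(df), df)

    def test_mean_of_order_statistics(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 20.0, 30.0]})
        out = quantile_normalize_lfc(df)
        np.testing.assert_allclose(out["a"], [5.5, 11.0, 16.5])
        np.testing.assert_allclose(out["b"], [5.5, 11.0, 16.5])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_sorted_columns_identical_and_ranks_preserved(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        out = quantile_normalize_lfc(df)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 3):
            np.testing.assert_array_equal(sorted_cols[:, 0], sorted_cols[:, j])
        for c in df.columns:
            np.testing.assert_array_equal(np.argsort(df[c].to_numpy()), np.argsort(out[c].to_numpy()))

    def test_ties_get_mean_of_spanned_quantiles(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [0.0, 10.0, 20.0]})
        out = quantile_normalize_lfc(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx((ref[0] + ref[1]) / 2)


class TestBackCalculateTPM:
    @pytest.mark.parametrize("l, m, expected", [(0.0, 7.0, (7.0, 7.0)), (1.0, 3.0, (4.0, 2.0))])
    def test_closed_form_pairs(self, l, m, expected):
        bs, mm = back_calculate_tpm(np.array([l]), np.array([m]))
        assert (bs[0], mm[0]) == pytest.approx(expected)

    def test_zero_mean_yields_zero_pair(self):
        bs, m = back_calculate_tpm(np.array([2.0]), np.array([0.0]))
        assert bs[0] == 0.0 and m[0] == 0.0

    def test_round_trip_identity(self, rng):
        l = rng.normal(0, 3, 10_000)
        m = rng.uniform(0.01, 1e4, 10_000)
        bs, mm = back_calculate_tpm(l, m)
        np.testing.assert_allclose((bs + mm) / 2, m, rtol=1e-12)
        np.testing.assert_allclose(np.log2(bs / mm), l, rtol=1e-9, atol=1e-12)


class TestConflictSets:
    def fixture_results(self):
        genes = [f"g{i}" for i in range(1, 7)]
        lfc_a = [0.1, 2.0, -0.1, 0.5, -2.0, 1.0]
        fdr_a = [0.9, 0.01, 0.8, 0.4, 0.01, 0.6]
        lfc_b = [0.2, -1.5, 0.3, -0.4, 1.8, -1.0]
        fdr_b = [0.7, 0.02, 0.9, 0.5, 0.03, 0.9]
        res_a = study(genes, lfc_a, fdr=fdr_a, study_id="A")
        res_b = study(genes, lfc_b, fdr=fdr_b, study_id="B")
        return res_a, res_b

    def test_toy_fixture_sets(self):
        res_a, res_b = self.fixture_results()
        c = build_conflict_sets(res_a, res_b, [("s1", "s1")], alpha=0.05)
        assert c.set1 == ["g2"]
        assert c.set2 == ["g5"]
        assert set(c.provenance["gene_id"]) == {"g2", "g5"}

    def test_no_significance_no_conflicts(self):
        genes = ["g1", "g2"]
        res_a = study(genes, [1.0, -1.0], fdr=[0.5, 0.5])
        res_b = study(genes, [-1.0, 1.0], fdr=[0.5, 0.5], study_id="B")
        c = build_conflict_sets(res_a, res_b, [("s1", "s1")])
        assert c.set1 == [] and c.set2 == []

    def test_sign_flip_swaps_sets(self):
        res_a, res_b = self.fixture_results()
        flip_a = res_a.assign(log2fc=-res_a["log2fc"])
        flip_b = res_b.assign(log2fc=-res_b["log2fc"])
        c = build_conflict_sets(res_a, res_b, [("s1", "s1")])
        cf = build_conflict_sets(flip_a, flip_b, [("s1", "s1")])
        assert cf.set1 == c.set2 and cf.set2 == c.set1

    def test_unpaired_stage_is_error(self):
        res_a, res_b = self.fixture_results()
        with pytest.raises(ValueError, match="stage"):
            build_conflict_sets(res_a, res_b, [("s1", "nope")])

    def test_sets_are_disjoint(self):
        res_a, res_b = self.fixture_results()
        c = build_conflict_sets(res_a, res_b, [("s1", "s1")], sig_col="p_value")
        assert not set(c.set1) & set(c.set2)


class TestOverlapTest:
    def test_matches_exhaustive_enumeration_small_margins(self):
        universe = [f"g{i}" for i in range(12)]
        for na in range(13):
            for nb in range(13):
                for k in range(max(0, na + nb - 12), min(na, nb) + 1):
                    a = set(universe[:k]) | set(universe[k : na])
                    b = set(universe[:k]) | set(universe[na : na + nb - k])
                    _, p, table = overlap_test(a, b, universe)
                    assert table[0, 0] == k
                    assert p == pytest.approx(enum_fisher_p(k, na, nb, 12), rel=1e-10)

    def test_independent_random_subsets_have_unit_odds_on_average(self, rng):
        universe = [f"g{i}" for i in range(400)]
        log_ors = []
        for _ in range(40):
            a = rng.choice(universe, 120, replace=False)
            b = rng.choice(universe, 120, replace=False)
            orr, _, _ = overlap_test(a, b, universe)
            log_ors.append(np.log(orr))
        assert abs(np.mean(log_ors)) < 0.15

    def test_disjoint_halves_give_zero_odds_minimal_p(self):
        universe = [f"g{i}" for i in range(20)]
        orr, p, _ = overlap_test(universe[:10], universe[10:], universe)
        assert orr == 0.0
        assert p == pytest.approx(enum_fisher_p(0, 10, 10, 20), rel=1e-10)


class TestAgreement:
    def test_perfect_agreement(self):
        dirs = pd.Series({"g1": "BS", "g2": "M"})
        other = study(["o1", "o2"], [3.0, -2.0], study_id="B")
        ortho = {"g1": "o1", "g2": "o2"}
        assert agreement_fraction(dirs, ortho, other) == (2, 2, 1.0)

    def test_orthologless_genes_leave_denominator(self):
        dirs = pd.Series({f"g{i}": "BS" for i in range(10)})
        ortho = {f"g{i}": f"o{i}" for i in range(4)}  # only 4 mapped
        other = study([f"o{i}" for i in range(4)], [1.0, 2.0, 0.5, -1.0], study_id="B")
        n_mapped, n_same, frac = agreement_fraction(dirs, ortho, other)
        assert (n_mapped, n_same, frac) == (4, 3, 0.75)

    def test_direction_ignores_significance_in_other_study(self):
        dirs = pd.Series({"g1": "M"})
        other = study(["o1"], [-0.01], p=[0.99], fdr=[0.99], study_id="B")
        assert agreement_fraction(dirs, {"g1": "o1"}, other)[2] == 1.0

    def test_empty_mapping_is_nan(self):
        dirs = pd.Series({"g1": "BS"})
        other = study(["o9"], [1.0], study_id="B")
        assert np.isnan(agreement_fraction(dirs, {}, other)[2])


class TestClustering:
    def make_tpm(self, rng):
        genes = [f"g{i}" for i in range(40)]
        base = rng.uniform(60, 500, 40)
        data = {
            "x1": base,
            "x2": base * rng.uniform(0.95, 1.05, 40),
            "y1": base[::-1] * rng.uniform(0.95, 1.05, 40),
        }
        return pd.DataFrame(data, index=genes)

    def test_duplicate_samples_merge_first_at_zero_distance(self, rng):
        tpm = self.make_tpm(rng)
        tpm["x1b"] = tpm["x1"]
        _, sample_newick, _ = cluster_samples(tpm)
        tree = TreeNode.read([sample_newick])
        assert tree.find("x1").distance(tree.find("x1b")) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_samples_have_distance_two(self):
        # construct exact anti-correlation in log2 space
        genes = [f"g{i}" for i in range(10)]
        up = np.linspace(6, 10, 10)
        tpm = pd.DataFrame({"u": 2.0**up, "d": 2.0 ** up[::-1]}, index=genes)
        _, sample_newick, _ = cluster_samples(tpm)
        tree = TreeNode.read([sample_newick])
        assert tree.find("u").distance(tree.find("d")) == pytest.approx(2.0, abs=1e-9)

    def test_expression_filter_keeps_expected_genes(self):
        tpm = pd.DataFrame(
            {
                "s1": [100.0, 0.0, 30.0, 200.0, 60.0],
                "s2": [80.0, 50.0, 40.0, 150.0, 70.0],
            },
            index=["keep1", "haszero", "lowmax", "keep2", "keep3"],
        )
        _, _, filtered = cluster_samples(tpm)
        assert sorted(filtered.index) == ["keep1", "keep2", "keep3"]

    def test_no_surviving_genes_is_error(self):
        tpm = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="filter"):
            cluster_samples(tpm)


class TestDevelopmentalSwitch:
    def four_studies(self, flip_b=False):
        genes = [f"g{i}" for i in range(8)]
        # g0-3 consistent (BS-BS or M-M), g4-7 switching
        young_lfc = [2.0, 1.5, -1.0, -2.0, 2.0, 1.0, -1.5, -1.0]
        old_lfc = [1.0, 2.0, -2.0, -1.0, -2.0, -1.0, 1.5, 1.0]
        fdr = [0.01] * 8
        sign = -1.0 if flip_b else 1.0
        ya = study(genes, young_lfc, fdr=fdr, stage="young")
        oa = study(genes, old_lfc, fdr=fdr, stage="old")
        yb = study(genes, [sign * v for v in young_lfc], fdr=fdr, stage="young", study_id="B")
        ob = study(genes, [sign * v for v in old_lfc], fdr=fdr, stage="old", study_id="B")
        return ya, oa, yb, ob

    def test_replicating_study_supports_everything(self):
        per_gene, table, _ = developmental_switch_classification(*self.four_studies())
        assert per_gene["supported"].all()
        assert table.loc["consistent", "supported"] == 4
        assert table.loc["switching", "supported"] == 4

    def test_sign_flipped_study_supports_nothing(self):
        per_gene, table, _ = developmental_switch_classification(*self.four_studies(flip_b=True))
        assert not per_gene["supported"].any()
        assert table["supported"].sum() == 0

    def test_fisher_p_matches_enumeration_oracle(self):
        ya, oa, yb, ob = self.four_studies()
        # make support differ by class: flip B's old stage for switching genes
        ob2 = ob.copy()
        ob2.loc[ob2["gene_id"].isin([f"g{i}" for i in range(4, 8)]), "log2fc"] *= -1
        _, table, p = developmental_switch_classification(ya, oa, yb, ob2)
        k, K = int(table.iloc[0, 0]), int(table.iloc[0].sum())
        n, N = int(table["supported"].sum()), int(table.to_numpy().sum())
        assert p == pytest.approx(enum_fisher_p(k, K, n, N), rel=1e-10)

    def test_insignificant_genes_are_unclassified(self):
        ya, oa, yb, ob = self.four_studies()
        ya.loc[ya["gene_id"] == "g0", "fdr"] = 0.9
        per_gene, _, _ = developmental_switch_classification(ya, oa, yb, ob)
        assert "g0" not in set(per_gene["gene_id"])


class TestKeywordSets:
    def pairs(self):
        return pd.DataFrame(
            {
                "study_id": ["A"] * 3 + ["B"] * 3,
                "stage_id": "s1",
                "gene_id": ["g1", "g2", "g3"] * 2,
                "tpm_bs": [1.0, 2.0, 4.0, 10.0, 20.0, 40.0],
                "tpm_m": [0.5, 1.0, 2.0, 5.0, 10.0, 20.0],
            }
        )

    def test_singleton_set_equals_gene_pair(self):
        out = keyword_set_expression(self.pairs(), {"g2"})
        row = out[out["study_id"] == "A"].iloc[0]
        assert (row["tpm_bs"], row["tpm_m"]) == (2.0, 1.0)

    def test_additive_over_disjoint_sets(self):
        full = keyword_set_expression(self.pairs(), {"g1", "g2", "g3"})
        parts = [keyword_set_expression(self.pairs(), s) for s in ({"g1"}, {"g2", "g3"})]
        total = parts[0][["tpm_bs", "tpm_m"]] + parts[1][["tpm_bs", "tpm_m"]]
        np.testing.assert_allclose(full[["tpm_bs", "tpm_m"]], total)

    def test_balanced_genes_have_equal_sums(self):
        pairs = self.pairs()
        pairs["tpm_m"] = pairs["tpm_bs"]  # l = 0 everywhere
        out = keyword_set_expression(pairs, {"g1", "g2", "g3"})
        np.testing.assert_allclose(out["tpm_bs"], out["tpm_m"])
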