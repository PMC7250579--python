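import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from survscreen import (
    ScoringParams,
    call_hits,
    filter_gene_list,
    fold_representation,
    normalize_to_frequencies,
    rank_genes,
    read_hit_table,
    rescore_hit_table,
    score_genes,
    write_hit_table,
)

from .conftest import library_from_mapping, make_count_table, random_count_instance
from .oracles import brute_force_folds, brute_force_rank, brute_force_scores


def scored_instance(counts, guide_to_gene, params=None):
    params = params or ScoringParams()
    lib = library_from_mapping(guide_to_gene)
    table = make_count_table(counts, guide_to_gene)
    folds = fold_representation(table, params)
    return lib, table, folds, score_genes(folds, lib, params)


class TestFrequencies:
    def test_uniform_counts_give_uniform_frequencies(self):
        g2g = {f"g{i}": "A" for i in range(4)}
        table = make_count_table({g: (5, 5) for g in g2g}, g2g)
        freq = normalize_to_frequencies(table, "control")
        assert np.allclose(freq, 0.25)

    def test_hand_computed_frequencies(self):
        g2g = {"g1": "A", "g2": "A"}
        table = make_count_table({"g1": (10, 1), "g2": (30, 1)}, g2g)
        freq = normalize_to_frequencies(table, "control")
        assert freq.tolist() == [0.25, 0.75]

    def test_scale_invariance(self):
        g2g = {"g1": "A", "g2": "A", "g3": "B"}
        t1 = make_count_table({"g1": (1, 0), "g2": (2, 0), "g3": (3, 0)}, g2g)
        t2 = make_count_table({"g1": (7, 0), "g2": (14, 0), "g3": (21, 0)}, g2g)
        pd.testing.assert_series_equal(
            normalize_to_frequencies(t1, "control"),
            normalize_to_frequencies(t2, "control"),
        )

    def test_zero_total_without_pseudocount_fails(self):
        g2g = {"g1": "A"}
        table = make_count_table({"g1": (0, 1)}, g2g)
        with pytest.raises(ValueError, match="zero total"):
            normalize_to_frequencies(table, "control")
        assert normalize_to_frequencies(table, "control", pseudocount=1).tolist() == [1.0]


class TestFoldRepresentation:
    def test_identical_conditions_give_unit_folds(self):
        g2g = {f"g{i}": "A" for i in range(5)}
        table = make_count_table({g: (i + 1, i + 1) for i, g in enumerate(g2g)}, g2g)
        folds = fold_representation(table).folds
        assert np.allclose(folds, 1.0)

    def test_na_inf_and_zero_fold_cases(self):
        g2g = {"g1": "A", "g2": "A", "g3": "B", "g4": "B"}
        table = make_count_table(
            {"g1": (0, 0), "g2": (0, 5), "g3": (5, 0), "g4": (5, 5)}, g2g
        )
        folds = fold_representation(table).folds
        assert math.isnan(folds["g1"])  # absent from both samples
        assert folds["g2"] == math.inf  # survivor-only
        assert folds["g3"] == 0.0  # control-only
        assert folds["g4"] > 0

    def test_hand_computed_fold(self):
        # totals 1000 vs 500; 10/1000 -> 20/500 is a four-fold enrichment
        g2g = {"g1": "A", "g2": "A"}
        table = make_count_table({"g1": (10, 20), "g2": (990, 480)}, g2g)
        assert fold_representation(table).folds["g1"] == pytest.approx(4.0)

    def test_pseudocount_removes_na_and_inf(self):
        g2g = {"g1": "A", "g2": "A"}
        table = make_count_table({"g1": (0, 0), "g2": (0, 5)}, g2g)
        folds = fold_representation(table, ScoringParams(pseudocount=1)).folds
        assert np.isfinite(folds).all()


class TestScoreGenes:
    def test_null_gene(self):
        g2g = {f"g{i}": "A" for i in range(5)}
        _, _, _, scores = scored_instance({g: (10, 10) for g in g2g}, g2g)
        row = scores.loc["A"]
        assert row["pct_overrepresented"] == 0
        assert row["median_fold"] == 1.0
        assert not row["is_hit"]

    def test_mixed_gene_with_na_guide(self):
        # folds {3.0, 1.5, NA, 2.0, 0.5}: 4 identified, 2 overrepresented,
        # pct 50 meets the inclusive >=50% rule, median 1.75
        g2g = {f"g{i}": "A" for i in range(5)}
        counts = {
            "g0": (100, 300),
            "g1": (100, 150),
            "g2": (0, 0),
            "g3": (100, 200),
            "g4": (100, 50),
        }
        # equalise totals so frequency ratios equal count ratios
        g2g["pad"] = "PAD"
        counts["pad"] = (700, 400)
        _, _, folds, scores = scored_instance(counts, g2g)
        observed = folds.folds[["g0", "g1", "g3", "g4"]].tolist()
        assert observed == pytest.approx([3.0, 1.5, 2.0, 0.5])
        row = scores.loc["A"]
        assert row["n_identified"] == 4
        assert row["n_overrepresented"] == 2
        assert row["pct_overrepresented"] == 50
        assert row["median_fold"] == pytest.approx(1.75)
        assert row["is_hit"]

    def test_exclusive_fraction_flips_borderline_gene(self):
        g2g = {f"g{i}": "A" for i in range(5)}
        counts = {
            "g0": (100, 300),
            "g1": (100, 150),
            "g2": (0, 0),
            "g3": (100, 200),
            "g4": (100, 50),
            "pad": (700, 400),
        }
        g2g["pad"] = "PAD"
        params = ScoringParams(fraction_inclusive=False)
        _, _, _, scores = scored_instance(counts, g2g, params)
        assert not scores.loc["A", "is_hit"]  # 50% is not > 50%

    def test_infinite_folds_count_as_overrepresented(self):
        g2g = {"g1": "A", "g2": "A", "pad": "PAD"}
        _, _, _, scores = scored_instance(
            {"g1": (0, 50), "g2": (0, 0), "pad": (100, 50)}, g2g
        )
        row = scores.loc["A"]
        assert row["n_identified"] == 1
        assert row["pct_overrepresented"] == 100
        assert row["median_fold"] == math.inf
        assert row["is_hit"]

    def test_gene_with_no_identified_guides_is_never_hit(self):
        g2g = {"g1": "A", "g2": "A", "pad": "PAD"}
        _, _, _, scores = scored_instance(
            {"g1": (0, 0), "g2": (0, 0), "pad": (10, 10)}, g2g
        )
        row = scores.loc["A"]
        assert math.isnan(row["pct_overrepresented"])
        assert math.isnan(row["median_fold"])
        assert not row["is_hit"]

    def test_denominator_total_mode(self):
        g2g = {"g1": "A", "g2": "A", "g3": "A", "g4": "A", "pad": "PAD"}
        counts = {"g1": (10, 90), "g2": (10, 80), "g3": (0, 0), "g4": (0, 0),
                  "pad": (80, 30)}
        _, _, _, ident = scored_instance(counts, g2g)
        _, _, _, total = scored_instance(counts, g2g, ScoringParams(denominator_mode="total"))
        assert ident.loc["A", "pct_overrepresented"] == 100
        assert total.loc["A", "pct_overrepresented"] == 50

    def test_unknown_guide_rejected(self):
        g2g = {"g1": "A"}
        lib = library_from_mapping(g2g)
        table = make_count_table({"g1": (1, 1), "gX": (1, 1)}, {"g1": "A", "gX": "X"})
        folds = fold_representation(table)
        with pytest.raises(ValueError, match="absent from library"):
            score_genes(folds, lib)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_scores_and_ranking_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        counts, g2g = random_count_instance(rng, n_genes=60)
        params = ScoringParams()
        lib, _, folds, scores = scored_instance(counts, g2g, params)
        expected_folds = brute_force_folds(counts)
        for g, f in expected_folds.items():
            observed = folds.folds[g]
            if math.isnan(f):
                assert math.isnan(observed)
            else:
                assert observed == pytest.approx(f)
        expected = brute_force_scores(counts, g2g)
        for gene, exp in expected.items():
            row = scores.loc[gene]
            for key in ("n_guides_total", "n_identified", "n_overrepresented", "is_hit"):
                assert row[key] == exp[key], (gene, key)
            for key in ("pct_overrepresented", "median_fold", "mean_fold"):
                if math.isnan(exp[key]):
                    assert math.isnan(row[key])
                else:
                    assert row[key] == pytest.approx(exp[key]), (gene, key)
        assert rank_genes(scores).gene_ids == brute_force_rank(expected)

    @pytest.mark.parametrize(
        "params",
        [
            ScoringParams(threshold_inclusive=False),
            ScoringParams(fraction_inclusive=False),
            ScoringParams(denominator_mode="total"),
            ScoringParams(fold_threshold=3.0, min_overrep_fraction=0.8),
        ],
        ids=["excl-fold", "excl-frac", "total-denom", "strict"],
    )
    def test_parameter_variants_match_brute_force(self, params):
        rng = np.random.default_rng(99)
        counts, g2g = random_count_instance(rng, n_genes=40)
        _, _, _, scores = scored_instance(counts, g2g, params)
        expected = brute_force_scores(
            counts,
            g2g,
            fold_threshold=params.fold_threshold,
            threshold_inclusive=params.threshold_inclusive,
            min_overrep_fraction=params.min_overrep_fraction,
            fraction_inclusive=params.fraction_inclusive,
            denominator_mode=params.denominator_mode,
        )
        assert call_hits(scores) == {g for g, e in expected.items() if e["is_hit"]}


class TestProperties:
    @given(factor=st.integers(min_value=1, max_value=50), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance_of_scores(self, factor, seed):
        rng = np.random.default_rng(seed)
        counts, g2g = random_count_instance(rng, n_genes=8)
        scaled = {g: (c * factor, t) for g, (c, t) in counts.items()}
        _, _, f1, s1 = scored_instance(counts, g2g)
        _, _, f2, s2 = scored_instance(scaled, g2g)
        pd.testing.assert_series_equal(f1.folds, f2.folds)
        pd.testing.assert_frame_equal(s1, s2)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=20, deadline=None)
    def test_raising_a_treated_count_never_lowers_fold_or_pct(self, seed):
        rng = np.random.default_rng(seed)
        counts, g2g = random_count_instance(rng, n_genes=6)
        guide = list(counts)[int(rng.integers(len(counts)))]
        gene = g2g[guide]
        bumped = dict(counts)
        c, t = counts[guide]
        bumped[guide] = (c, t + int(rng.integers(1, 50)))
        _, _, f1, s1 = scored_instance(counts, g2g)
        _, _, f2, s2 = scored_instance(bumped, g2g)
        before, after = f1.folds[guide], f2.folds[guide]
        if not math.isnan(before):
            assert after >= before or after == math.inf
        # gene-level pct is monotone unless the treated-total shift pushed a
        # sibling guide back below the threshold (normalisation coupling)
        params = ScoringParams()
        siblings = [g for g in counts if g2g[g] == gene and g != guide]
        sibling_dropped = any(
            params.is_overrepresented(f1.folds[s])
            and not params.is_overrepresented(f2.folds[s])
            for s in siblings
        )
        p1 = s1.loc[gene, "pct_overrepresented"]
        p2 = s2.loc[gene, "pct_overrepresented"]
        if not math.isnan(p1) and not sibling_dropped:
            assert p2 >= p1

    def test_identical_conditions_produce_zero_hits(self):
        rng = np.random.default_rng(1)
        counts, g2g = random_count_instance(rng, n_genes=50)
        same = {g: (max(c, 1), max(c, 1)) for g, (c, _) in counts.items()}
        _, _, _, scores = scored_instance(same, g2g)
        assert call_hits(scores) == set()


class TestRanking:
    def test_pct_dominates_median(self):
        scores = pd.DataFrame(
            {
                "n_guides_total": [5, 5],
                "n_identified": [5, 5],
                "n_overrepresented": [5, 2],
                "pct_overrepresented": [100.0, 50.0],
                "median_fold": [2.0, 99.0],
                "mean_fold": [2.0, 99.0],
                "is_hit": [True, True],
            },
            index=pd.Index(["B", "A"], name="gene_id"),
        )
        assert rank_genes(scores).gene_ids == ["B", "A"]

    def test_median_breaks_pct_ties(self):
        scores = pd.DataFrame(
            {
                "n_guides_total": [5, 5],
                "n_identified": [5, 5],
                "n_overrepresented": [5, 5],
                "pct_overrepresented": [100.0, 100.0],
                "median_fold": [3.5, 8.0],
                "mean_fold": [3.5, 8.0],
                "is_hit": [True, True],
            },
            index=pd.Index(["A", "B"], name="gene_id"),
        )
        assert rank_genes(scores).gene_ids == ["B", "A"]

    def test_na_pct_ranks_last_and_gene_id_breaks_full_ties(self):
        scores = pd.DataFrame(
            {
                "n_guides_total": [5, 5, 5],
                "n_identified": [0, 5, 5],
                "n_overrepresented": [0, 1, 1],
                "pct_overrepresented": [math.nan, 20.0, 20.0],
                "median_fold": [math.nan, 1.0, 1.0],
                "mean_fold": [math.nan, 1.0, 1.0],
                "is_hit": [False, False, False],
            },
            index=pd.Index(["A", "Z", "B"], name="gene_id"),
        )
        assert rank_genes(scores).gene_ids == ["B", "Z", "A"]

    def test_filter_preserves_relative_order(self):
        rng = np.random.default_rng(7)
        counts, g2g = random_count_instance(rng, n_genes=30)
        _, _, _, scores = scored_instance(counts, g2g)
        ranked = rank_genes(scores)
        keep = set(list(scores.index)[::3]) | {"NOT_A_GENE"}
        filtered = filter_gene_list(ranked, keep, name="every-third")
        assert filtered.gene_ids == [g for g in ranked.gene_ids if g in keep]
        assert filtered.n_filter_missing == 1
        assert filter_gene_list(ranked, set()).gene_ids == []
        assert filter_gene_list(ranked, set(scores.index)).gene_ids == ranked.gene_ids

    def test_rank_filter_applied_after_global_ranking(self):
        rng = np.random.default_rng(8)
        counts, g2g = random_count_instance(rng, n_genes=20)
        _, _, _, scores = scored_instance(counts, g2g)
        keep = list(scores.index)[:7]
        direct = rank_genes(scores, gene_filter=keep)
        via_filter = filter_gene_list(rank_genes(scores), keep)
        assert direct.gene_ids == via_filter.gene_ids


class TestHitTableIO:
    def test_round_trip_and_na_serialization(self, tmp_path):
        rng = np.random.default_rng(3)
        counts, g2g = random_count_instance(rng, n_genes=25)
        counts[next(iter(counts))] = (0, 0)  # ensure an unidentified guide
        lib, _, folds, scores = scored_instance(counts, g2g)
        path = tmp_path / "hits.tsv"
        write_hit_table(scores, folds, lib, path)
        text = path.read_text()
        assert "NA" in text  # unidentified guides serialised as the NA literal
        assert len(text.strip().split("\n")) == len(scores) + 1
        table = read_hit_table(path)
        for gene in scores.index:
            for key in ("median_fold", "mean_fold", "pct_overrepresented"):
                a, b = scores.loc[gene, key], table.scores.loc[gene, key]
                assert (math.isnan(a) and math.isnan(b)) or a == b
            assert bool(scores.loc[gene, "is_hit"]) == bool(table.scores.loc[gene, "is_hit"])

    def test_rescoring_from_raw_folds_reproduces_statistics(self, tmp_path):
        rng = np.random.default_rng(4)
        counts, g2g = random_count_instance(rng, n_genes=25)
        lib, _, folds, scores = scored_instance(counts, g2g)
        path = tmp_path / "hits.tsv"
        write_hit_table(scores, folds, lib, path)
        rescored = rescore_hit_table(read_hit_table(path))
        for gene in scores.index:
            a = scores.loc[gene, "pct_overrepresented"]
            b = rescored.loc[gene, "pct_overrepresented"]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)
            assert bool(scores.loc[gene, "is_hit"]) == bool(rescored.loc[gene, "is_hit"])
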