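"""Differential expression, clustering and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest

from oracles import gsea_running_sum, hypergeom_upper_tail
from trfscreen.expression import (
    call_degs,
    gsea_es,
    hierarchical_bicluster,
    hypergeom_ora,
    ora_table,
    tpm_normalize,
)
from trfscreen.simulate import SimConfig, generate_counts


def _groups(columns):
    return {s: ("treated" if s.startswith("treated") else "control") for s in columns}


class TestTpmNormalize:
    def test_single_gene_gets_one_million(self):
        counts = pd.DataFrame({"s1": [7]}, index=["g1"])
        tpm = tpm_normalize(counts, pd.Series({"g1": 1000}))
        assert tpm.loc["g1", "s1"] == pytest.approx(1e6)

    def test_length_ratio(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        tpm = tpm_normalize(counts, pd.Series({"a": 100, "b": 200}))
        assert tpm.loc["a", "s1"] / tpm.loc["b", "s1"] == pytest.approx(2.0)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(30, 4)),
                              index=[f"g{i}" for i in range(30)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 2000, 30), index=counts.index)
        tpm = tpm_normalize(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_missing_length_names_gene(self):
        counts = pd.DataFrame({"s1": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            tpm_normalize(counts, pd.Series({"a": 100}))


class TestCallDegs:
    def test_planted_down_gene_called(self):
        cfg = SimConfig(n_genes=400, de_log2fc=2.0)
        counts, truth, lengths, _ = generate_counts(cfg)
        tpm = tpm_normalize(counts, lengths)
        degs = {r.gene_id: r for r in call_degs(tpm, _groups(tpm.columns))}
        de_down = truth[(truth.source == "de") & (truth.direction == "down")]
        recovered = sum(degs[g].call == "down" for g in de_down.gene_id)
        assert recovered >= 0.8 * len(de_down)

    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(1)
        half = rng.integers(1, 1000, size=(50, 3))
        tpm = pd.DataFrame(
            np.hstack([half, half]).astype(float),
            index=[f"g{i}" for i in range(50)],
            columns=[f"control_{i}" for i in range(3)] + [f"treated_{i}" for i in range(3)],
        )
        assert all(r.call == "ns" for r in call_degs(tpm, _groups(tpm.columns)))

    def test_constant_gene_p_one(self):
        tpm = pd.DataFrame(
            {"control_1": [5.0, 1.0], "control_2": [5.0, 2.0],
             "treated_1": [5.0, 9.0], "treated_2": [5.0, 8.0]},
            index=["flat", "moving"],
        )
        recs = {r.gene_id: r for r in call_degs(tpm, _groups(tpm.columns))}
        assert recs["flat"].p == 1.0 and recs["flat"].call == "ns"

    def test_call_matches_thresholds_and_fdr_dominates_p(self):
        cfg = SimConfig(n_genes=300)
        counts, _, lengths, _ = generate_counts(cfg)
        tpm = tpm_normalize(counts, lengths)
        recs = call_degs(tpm, _groups(tpm.columns), log2fc_thresh=1.0, alpha=0.05)
        for r in recs:
            expected = (
                "up" if (r.p < 0.05 and r.log2fc > 1.0)
                else "down" if (r.p < 0.05 and r.log2fc < -1.0)
                else "ns"
            )
            assert r.call == expected
            assert r.fdr >= r.p

    def test_fdr_monotone_in_sorted_p(self):
        cfg = SimConfig(n_genes=300)
        counts, _, lengths, _ = generate_counts(cfg)
        recs = call_degs(tpm_normalize(counts, lengths), _groups(counts.columns))
        df = pd.DataFrame([(r.p, r.fdr) for r in recs], columns=["p", "fdr"]).sort_values("p")
        assert (np.diff(df["fdr"].to_numpy()) >= -1e-12).all()

    def test_too_few_samples_rejected(self):
        tpm = pd.DataFrame({"control_1": [1.0], "treated_1": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            call_degs(tpm, _groups(tpm.columns))


class TestHierarchicalBicluster:
    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(2)
        base = rng.random(20) * 100
        tpm = pd.DataFrame(
            {"twin_a": base, "twin_b": base, "other": rng.random(20) * 100},
            index=[f"g{i}" for i in range(20)],
        )
        res = hierarchical_bicluster(tpm)
        first_merge = res["col_linkage"][0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == 0.0

    def test_groups_separate_at_root(self):
        cfg = SimConfig(n_genes=300, de_fraction=0.3, de_log2fc=3.0)
        counts, _, lengths, _ = generate_counts(cfg)
        res = hierarchical_bicluster(tpm_normalize(counts, lengths))
        order = res["col_order"]
        labels = ["".join(filter(str.isalpha, s)) for s in order]
        k = labels.count("control")
        assert sorted(set(labels[:k])) in (["control"], ["treated"])
        assert len(set(labels[:k])) == 1 and len(set(labels[k:])) == 1

    def test_row_permutation_does_not_change_column_tree(self):
        cfg = SimConfig(n_genes=100)
        counts, _, lengths, _ = generate_counts(cfg)
        tpm = tpm_normalize(counts, lengths)
        res1 = hierarchical_bicluster(tpm)
        rng = np.random.default_rng(3)
        res2 = hierarchical_bicluster(tpm.iloc[rng.permutation(len(tpm))])
        assert res1["col_order"] == res2["col_order"]

    def test_nan_rejected(self):
        tpm = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            hierarchical_bicluster(tpm)


class TestGseaEs:
    def test_top_k_set_matches_enumeration_oracle(self):
        # N = 10, k = 3, p = 0: frozen against the direct running-sum oracle
        genes = [f"g{i}" for i in range(10)]
        stat = list(np.linspace(5, -5, 10))
        in_set = [True] * 3 + [False] * 7
        oracle = gsea_running_sum(in_set, stat, p=0.0)
        res = gsea_es(genes, stat, genes[:3], weight_p=0.0, n_perm=50, seed=0)
        assert res.es == pytest.approx(oracle, abs=1e-12)
        assert oracle == pytest.approx(1.0)  # all hits precede any miss

    def test_weighted_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        stat = sorted(rng.normal(size=40), reverse=True)
        members = list(rng.choice(genes, size=8, replace=False))
        in_set = [g in members for g in genes]
        oracle = gsea_running_sum(in_set, stat, p=1.0)
        res = gsea_es(genes, stat, members, weight_p=1.0, n_perm=10, seed=0)
        assert res.es == pytest.approx(oracle, abs=1e-12)

    def test_es_bounded_and_reversal_negates_at_p0(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        stat = sorted(rng.normal(size=30), reverse=True)
        members = list(rng.choice(genes, size=6, replace=False))
        fwd = gsea_es(genes, stat, members, weight_p=0.0, n_perm=10, seed=0)
        rev = gsea_es(genes[::-1], stat[::-1], members, weight_p=0.0, n_perm=10, seed=0)
        assert -1.0 <= fwd.es <= 1.0
        assert fwd.es == pytest.approx(-rev.es, abs=1e-12)

    def test_set_covering_everything_rejected(self):
        genes = ["a", "b", "c"]
        with pytest.raises(ValueError):
            gsea_es(genes, [3.0, 2.0, 1.0], genes)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            gsea_es(["a", "b"], [1.0, -1.0], ["zzz"])

    def test_planted_pathway_negative_es(self):
        cfg = SimConfig(n_genes=800)
        counts, _, lengths, sets = generate_counts(cfg)
        tpm = tpm_normalize(counts, lengths)
        degs = call_degs(tpm, _groups(tpm.columns))
        ranked = sorted(degs, key=lambda r: r.log2fc, reverse=True)
        res = gsea_es([r.gene_id for r in ranked], [r.log2fc for r in ranked],
                      sets["PI3K_AKT_LIKE"], n_perm=200, seed=1)
        assert res.es < 0
        assert res.p_perm < 0.05


class TestHypergeomOra:
    def test_full_overlap_matches_combinatorial_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        res = hypergeom_ora(universe[:5], universe[:5], universe)
        expected = hypergeom_upper_tail(20, 5, 5, 5)
        assert expected == pytest.approx(1 / 15504)
        assert res.p_hyper == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_tail_is_one(self):
        universe = [f"g{i}" for i in range(15)]
        res = hypergeom_ora(universe[:4], universe[10:13], universe)
        assert res.overlap_k == 0
        assert res.p_hyper == pytest.approx(hypergeom_upper_tail(15, 3, 4, 0))
        assert res.p_hyper == pytest.approx(1.0)

    def test_selected_equals_universe(self):
        universe = [f"g{i}" for i in range(12)]
        res = hypergeom_ora(universe, universe[:4], universe)
        assert res.overlap_k == 4
        assert res.p_hyper == pytest.approx(1.0)

    def test_random_cases_match_enumeration(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(25)]
        for _ in range(20):
            sel = list(rng.choice(universe, size=rng.integers(1, 12), replace=False))
            mem = list(rng.choice(universe, size=rng.integers(1, 10), replace=False))
            res = hypergeom_ora(sel, mem, universe)
            expected = hypergeom_upper_tail(25, len(mem), len(sel), res.overlap_k)
            assert res.p_hyper == pytest.approx(expected, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_ora(["a"], ["a"], [])

    def test_ora_table_bh_dominates_p(self):
        universe = [f"g{i}" for i in range(25)]
        sets = {"s1": universe[:5], "s2": universe[5:15], "s3": universe[20:]}
        df = ora_table(universe[:8], sets, universe)
        assert (df["fdr"] >= df["p_hyper"] - 1e-12).all()
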