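"""Probe collapsing, above-average calls, organ frequency and the organ network."""

import numpy as np
import pandas as pd
import pytest

from herbnet.core_io import ExpressionMatrix
from herbnet.errors import ValidationError
from herbnet.organ_expression import (above_average_calls, build_organ_network,
                                      collapse_probes,
                                      genes_in_all_panel_organs,
                                      genes_in_at_least_k_organs,
                                      organ_frequency)
from herbnet.synthetic import gen_expression_matrix


def matrix_from(rows: dict, tissues):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=tissues,
                                dtype=float)
    return ExpressionMatrix(values=df)


def planted_matrix(seed=0, n_genes=200, n_tissues=20, n_planted_genes=30,
                   tissues_per_gene=3, boost=8.0):
    rng = np.random.default_rng(seed)
    tissues = [f"T{j:02d}" for j in range(n_tissues)]
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    planted = set()
    for g in rng.choice(genes, size=n_planted_genes, replace=False):
        for t in rng.choice(tissues, size=tissues_per_gene, replace=False):
            planted.add((str(g), str(t)))
    matrix, truth = gen_expression_matrix(n_genes, tissues, planted, boost,
                                          sigma=0.5, seed=seed)
    return matrix, truth, tissues


class TestCollapseProbes:
    def test_max_collapse_example(self):
        m = matrix_from({"p1": [1, 2], "p2": [3, 0]}, ["A", "B"])
        out = collapse_probes(m, {"p1": "G", "p2": "G"}, "max")
        assert list(out.values.loc["G"]) == [3.0, 2.0]

    def test_mean_collapse(self):
        m = matrix_from({"p1": [1, 2], "p2": [3, 0]}, ["A", "B"])
        out = collapse_probes(m, {"p1": "G", "p2": "G"}, "mean")
        assert list(out.values.loc["G"]) == [2.0, 1.0]

    def test_one_probe_per_gene_is_identity(self):
        m = matrix_from({"p1": [1, 2], "p2": [3, 4]}, ["A", "B"])
        out = collapse_probes(m, {"p1": "G1", "p2": "G2"}, "max")
        assert out.values.loc["G1"].tolist() == [1.0, 2.0]
        assert out.values.loc["G2"].tolist() == [3.0, 4.0]

    def test_unmapped_probes_dropped_with_count(self):
        m = matrix_from({"p1": [1, 2], "p2": [3, 4]}, ["A", "B"])
        out = collapse_probes(m, {"p1": "G1"}, "max")
        assert out.values.attrs["n_unmapped_probes"] == 1
        assert list(out.values.index) == ["G1"]

    def test_empty_mapping_rejected(self):
        m = matrix_from({"p1": [1, 2]}, ["A", "B"])
        with pytest.raises(ValidationError, match="mapping"):
            collapse_probes(m, {}, "max")

    def test_seeded_probes_equal_brute_aggregation(self):
        rng = np.random.default_rng(5)
        probes = [f"p{i}" for i in range(40)]
        mapping = {p: f"G{i % 12}" for i, p in enumerate(probes)}
        df = pd.DataFrame(rng.lognormal(size=(40, 6)), index=probes,
                          columns=[f"T{j}" for j in range(6)])
        out = collapse_probes(ExpressionMatrix(values=df), mapping, "max")
        for gene in out.values.index:
            members = [p for p in probes if mapping[p] == gene]
            brute = df.loc[members].max(axis=0)
            assert np.allclose(out.values.loc[gene], brute)


class TestAboveAverageCalls:
    def test_hand_example(self):
        m = matrix_from({"g": [1, 1, 4]}, ["A", "B", "C"])
        calls = above_average_calls(m)
        assert calls.gene_means["g"] == pytest.approx(2.0)
        assert calls.calls.loc["g"].tolist() == [False, False, True]

    def test_constant_gene_called_nowhere(self):
        m = matrix_from({"g": [5, 5, 5]}, ["A", "B", "C"])
        calls = above_average_calls(m)
        assert not calls.calls.loc["g"].any()

    def test_single_tissue_rejected(self):
        m = matrix_from({"g": [5]}, ["A"])
        with pytest.raises(ValidationError, match="two tissues"):
            above_average_calls(m)

    def test_no_gene_called_everywhere(self):
        matrix, _, _ = planted_matrix(seed=2)
        calls = above_average_calls(matrix)
        assert not calls.calls.all(axis=1).any()

    def test_planted_pairs_all_recovered(self):
        matrix, truth, tissues = planted_matrix(seed=0)
        calls = above_average_calls(matrix, organ_panel=tissues)
        for g, t in truth.planted_calls:
            assert bool(calls.calls.at[g, t]), (g, t)


class TestOrganFrequency:
    def test_ordering_and_counts(self):
        m = matrix_from({"g1": [9, 1, 1], "g2": [9, 1, 1], "g3": [9, 8, 1]},
                        ["A", "B", "C"])
        calls = above_average_calls(m, organ_panel=["A", "B"])
        freq = organ_frequency(calls)
        assert freq == [("A", 3), ("B", 1)]

    def test_zero_counts_retained(self):
        m = matrix_from({"g": [5, 5, 5]}, ["A", "B", "C"])
        calls = above_average_calls(m, organ_panel=["A", "B"])
        assert organ_frequency(calls) == [("A", 0), ("B", 0)]

    def test_counts_sum_to_total_panel_calls(self):
        matrix, _, tissues = planted_matrix(seed=3)
        panel = tissues[:7]
        calls = above_average_calls(matrix, organ_panel=panel)
        freq = organ_frequency(calls)
        assert sum(c for _t, c in freq) == int(
            calls.panel_calls().to_numpy().sum())

    def test_empty_panel_rejected(self):
        m = matrix_from({"g": [1, 2]}, ["A", "B"])
        calls = above_average_calls(m, organ_panel=[])
        with pytest.raises(ValidationError, match="panel"):
            organ_frequency(calls)


class TestGeneCounts:
    def test_k1_selects_only_active_gene(self):
        m = matrix_from({"g1": [9, 1, 1], "g2": [4, 4, 4]}, ["A", "B", "C"])
        calls = above_average_calls(m, organ_panel=["A"])
        assert genes_in_at_least_k_organs(calls, 1) == {"g1"}

    def test_k_above_panel_size_empty(self):
        matrix, _, tissues = planted_matrix(seed=1)
        calls = above_average_calls(matrix, organ_panel=tissues[:4])
        assert genes_in_at_least_k_organs(calls, 5) == set()

    def test_matches_brute_recount(self):
        matrix, _, tissues = planted_matrix(seed=4)
        panel = tissues[:9]
        calls = above_average_calls(matrix, organ_panel=panel)
        for k in (1, 2, 3):
            got = genes_in_at_least_k_organs(calls, k)
            brute = {g for g in calls.calls.index
                     if sum(bool(calls.calls.at[g, t]) for t in panel) >= k}
            assert got == brute

    def test_all_panel_organs(self):
        m = matrix_from({"g1": [9, 9, 9, 0], "g2": [9, 0, 9, 1]},
                        ["A", "B", "C", "D"])
        calls = above_average_calls(m, organ_panel=["A", "B", "C"])
        assert genes_in_all_panel_organs(calls) == {"g1"}

    def test_panel_call_count_bounded_by_tissues_minus_one(self):
        matrix, _, tissues = planted_matrix(seed=6)
        calls = above_average_calls(matrix, organ_panel=tissues)
        per_gene = calls.panel_calls().sum(axis=1)
        assert (per_gene <= len(tissues) - 1).all()


class TestOrganNetwork:
    def test_two_calls_give_two_edges(self):
        m = matrix_from({"g1": [9, 1, 1], "g2": [1, 9, 1]}, ["A", "B", "C"])
        calls = above_average_calls(m, organ_panel=["A", "B"])
        net = build_organ_network(calls)
        assert net.n_edges() == 2
        assert set(net.edges()) == {("A", "g1"), ("B", "g2")}

    def test_no_calls_empty_network(self):
        m = matrix_from({"g": [5, 5, 5]}, ["A", "B", "C"])
        calls = above_average_calls(m, organ_panel=["A", "B"])
        net = build_organ_network(calls)
        assert net.n_nodes() == 0 and net.n_edges() == 0

    def test_planted_matrix_edges_cover_planted_truth(self):
        matrix, truth, tissues = planted_matrix(seed=0)
        calls = above_average_calls(matrix, organ_panel=tissues)
        net = build_organ_network(calls)
        edge_set = {(u, v) for u, v in net.edges()}
        for g, t in truth.planted_calls:
            assert (t, g) in edge_set
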