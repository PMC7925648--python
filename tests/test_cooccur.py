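"""Chi-square gene graph, Louvain communities, co-occurrence clustering,
and set-level survival stratification."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx
from scipy.stats import chi2_contingency

import drugsurv as ds
from conftest import records_from_arrays
from oracles import chi2_2x2


def planted_block_calls(n_patients=200, blocks=(20, 20), n_noise=0,
                        flip=0.05, seed=0):
    """Binary calls for genes in shared-factor blocks plus independent
    noise genes.  Returns (DataFrame, block membership list)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(blocks):
        factor = rng.random(n_patients) < 0.5
        for _ in range(size):
            flips = rng.random(n_patients) < flip
            rows.append(factor ^ flips)
            labels.append(b)
    for _ in range(n_noise):
        rows.append(rng.random(n_patients) < 0.5)
        labels.append(-1)
    genes = [f"g{i:03d}" for i in range(len(rows))]
    calls = pd.DataFrame(rows, index=genes,
                         columns=[f"P{i}" for i in range(n_patients)])
    return calls, labels


class TestChi2Pair:
    def test_proportional_table_is_zero(self):
        assert ds.chi2_pair([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_identical_vectors_give_n(self):
        x = np.tile([0, 1], 10)
        assert ds.chi2_pair(x, x) == pytest.approx(20.0)

    def test_closed_form_oracle(self):
        # table (a,b,c,d) = (8,2,3,7): x high & y high 8 times, etc.
        x = [1] * 10 + [0] * 10
        y = [1] * 8 + [0] * 2 + [1] * 3 + [0] * 7
        assert ds.chi2_pair(x, y) == pytest.approx(chi2_2x2(8, 2, 3, 7))

    def test_zero_margin_is_zero(self):
        assert ds.chi2_pair([0, 0, 0], [0, 1, 1]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ds.UsageError):
            ds.chi2_pair([0, 1], [0, 1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_random_tables_match_scipy_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(40) < rng.random()
        y = rng.random(40) < rng.random()
        ours = ds.chi2_pair(x, y)
        assert ours == pytest.approx(ds.chi2_pair(y, x))
        assert ours == pytest.approx(ds.chi2_pair(~x, ~y))
        table = pd.crosstab(pd.Series(x), pd.Series(y))
        if table.shape == (2, 2):
            ref = chi2_contingency(table.to_numpy(), correction=False)[0]
            assert ours == pytest.approx(ref, rel=1e-12)


class TestBuildGeneGraph:
    def test_identical_genes_edge_weight_n(self):
        x = np.tile([True, False], 25)
        calls = pd.DataFrame([x, x], index=["a", "b"],
                             columns=[f"P{i}" for i in range(50)])
        g = ds.build_gene_graph(calls)
        assert g.has_edge("a", "b")
        assert g["a"]["b"]["weight"] == pytest.approx(50.0)

    def test_independent_genes_nearly_edgeless(self):
        calls, _ = planted_block_calls(n_patients=100, blocks=(),
                                       n_noise=20, seed=4)
        g = ds.build_gene_graph(calls, alpha=1e-3)
        assert g.number_of_edges() <= 5  # 190 pairs at alpha 1e-3

    def test_planted_blocks_fully_connected_no_cross_edges(self):
        calls, labels = planted_block_calls(seed=1)
        g = ds.build_gene_graph(calls)
        genes = list(calls.index)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if labels[i] == labels[j]:
                    assert g.has_edge(genes[i], genes[j])
                else:
                    assert not g.has_edge(genes[i], genes[j])

    def test_mutually_exclusive_genes_not_linked(self):
        x = np.tile([True, False], 30)
        calls = pd.DataFrame([x, ~x], index=["a", "b"],
                             columns=[f"P{i}" for i in range(60)])
        g = ds.build_gene_graph(calls)
        assert not g.has_edge("a", "b")  # association strong but negative


class TestLouvain:
    def test_two_disconnected_cliques(self):
        g = nx.union(
            nx.complete_graph(range(5)),
            nx.complete_graph(range(5, 10)),
        )
        nx.set_edge_attributes(g, 1.0, "weight")
        parts = ds.louvain_partition(g, seed=0)
        assert sorted(sorted(p) for p in parts) == [
            [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]
        ]

    def test_seed_determinism(self):
        calls, _ = planted_block_calls(seed=2)
        g = ds.build_gene_graph(calls)
        p1 = ds.louvain_partition(g, seed=3)
        p2 = ds.louvain_partition(g, seed=3)
        assert sorted(map(sorted, p1)) == sorted(map(sorted, p2))

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        calls, labels = planted_block_calls(n_noise=0, seed=5)
        g = ds.build_gene_graph(calls)
        parts = ds.louvain_partition(g, seed=0)
        pred = {gene: k for k, comm in enumerate(parts) for gene in comm}
        ari = adjusted_rand_score(labels, [pred[g] for g in calls.index])
        assert ari >= 0.9


class TestSetFraction:
    def test_extremes_and_half(self):
        calls = pd.DataFrame(
            [[True, False, True]] * 7 + [[False, False, True]] * 7,
            index=[f"g{i}" for i in range(14)],
            columns=["all", "none", "mixed"],
        )
        frac = ds.set_fraction(calls, calls.index)
        assert frac["none"] == 0.0
        assert frac["mixed"] == 1.0
        assert frac["all"] == pytest.approx(0.5)

    def test_empty_members_rejected(self):
        calls = pd.DataFrame([[True]], index=["g"], columns=["p"])
        with pytest.raises(ds.UsageError):
            ds.set_fraction(calls, [])


class TestCooccurrenceCluster:
    def test_single_block_recovered(self):
        calls, _ = planted_block_calls(blocks=(15,), n_noise=30, seed=7)
        sets = ds.cooccurrence_cluster(calls, seed=0, min_set_size=10)
        assert len(sets) >= 1
        block = set(calls.index[:15])
        jacc = max(
            len(block & set(s)) / len(block | set(s)) for s in sets
        )
        assert jacc >= 0.8

    def test_independent_genes_emit_nothing(self):
        calls, _ = planted_block_calls(blocks=(), n_noise=25, seed=8)
        assert ds.cooccurrence_cluster(calls, seed=0) == []

    def test_nested_subpopulation_block_found_by_iteration(self):
        """A block co-expressed only within one patient subpopulation is
        found after the first-level patient split."""
        rng = np.random.default_rng(9)
        n = 240
        top_factor = np.arange(n) < n // 2  # defines the patient split
        rows = []
        for _ in range(12):  # top-level block
            rows.append(top_factor ^ (rng.random(n) < 0.02))
        sub_factor = rng.random(n) < 0.5
        for _ in range(12):  # active only inside the top-high subpopulation
            state = np.where(top_factor, sub_factor, rng.random(n) < 0.05)
            rows.append(state.astype(bool) ^ (rng.random(n) < 0.02))
        calls = pd.DataFrame(
            rows, index=[f"g{i}" for i in range(24)],
            columns=[f"P{i}" for i in range(n)],
        )
        sets = ds.cooccurrence_cluster(calls, seed=0, min_set_size=10)
        top = set(calls.index[:12])
        nested = set(calls.index[12:])
        best_top = max(len(top & set(s)) / len(top | set(s)) for s in sets)
        best_nested = max(
            len(nested & set(s)) / len(nested | set(s)) for s in sets
        )
        assert best_top >= 0.8 and best_nested >= 0.8

    def test_deterministic_given_seed(self):
        calls, _ = planted_block_calls(n_noise=10, seed=10)
        s1 = ds.cooccurrence_cluster(calls, seed=1)
        s2 = ds.cooccurrence_cluster(calls, seed=1)
        assert s1 == s2


class TestSetStratifyAndTest:
    def _fixture(self, seed=0, hr=4.0, flip=0.05, n=200, size=15):
        rng = np.random.default_rng(seed)
        factor = rng.random(n) < 0.5
        pids = [f"P{i}" for i in range(n)]
        calls = pd.DataFrame(
            [factor ^ (rng.random(n) < flip) for _ in range(size)],
            index=[f"g{i}" for i in range(size)], columns=pids,
        )
        hazard = 0.001 * np.where(factor, hr, 1.0)
        t = rng.exponential(1 / hazard)
        c = rng.exponential(1 / 5e-4, size=n)
        surv = [
            ds.SurvivalRecord(p, float(min(a, b)), bool(a <= b))
            for p, a, b in zip(pids, t, c)
        ]
        group = ds.PatientGroup("LUAD", "cisplatin", frozenset(pids))
        return group, calls, surv

    def test_percent_extremes(self):
        group, calls, surv = self._fixture()
        results, _ = ds.screen_group(
            group,
            ds.BinaryMatrix(calls=calls,
                            thresholds=pd.Series(0.5, index=calls.index)),
            surv,
        )
        gs = ds.set_stratify_and_test(
            group, list(calls.index), calls, surv, gene_results=results
        )
        assert 0.0 <= gs.percent_members_more_significant <= 100.0
        assert gs.n_low + gs.n_high == 200
        # percent definition: members with smaller p than the set
        member_p = [r.p_value for r in results]
        expected = 100 * sum(p < gs.p_value for p in member_p) / len(calls)
        assert gs.percent_members_more_significant == pytest.approx(expected)

    def test_coherent_block_set_beats_median_member(self):
        wins = 0
        for seed in range(5):
            group, calls, surv = self._fixture(seed=seed)
            results, _ = ds.screen_group(
                group,
                ds.BinaryMatrix(calls=calls,
                                thresholds=pd.Series(0.5, index=calls.index)),
                surv,
            )
            gs = ds.set_stratify_and_test(
                group, list(calls.index), calls, surv, gene_results=results
            )
            if gs.p_value <= np.median([r.p_value for r in results]):
                wins += 1
        assert wins >= 4

    def test_degenerate_fraction_flagged(self):
        group, calls, surv = self._fixture()
        const = calls.copy()
        const.loc[:, :] = True  # every member high for everyone
        gs = ds.set_stratify_and_test(group, list(const.index), const, surv)
        assert gs.degenerate and gs.p_value == 1.0
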