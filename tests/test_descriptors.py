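"""Descriptor families: frozen hand values, oracle equivalence, invariances."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from aptaclass import descriptors, folding, pool_io
from aptaclass.descriptors import chi_average, path_walk_shape, topological_charge

P3, P4, P5 = nx.path_graph(3), nx.path_graph(4), nx.path_graph(5)
C4, K2 = nx.cycle_graph(4), nx.complete_graph(2)


class TestHandValues:
    """Frozen values derived by hand enumeration of tiny graphs."""

    @pytest.mark.parametrize(
        "graph,k,expected",
        [(P5, 3, 0.3535533905932738), (C4, 3, 0.25), (K2, 3, 0.0)],
    )
    def test_chi_average(self, graph, k, expected):
        assert chi_average(graph, k) == pytest.approx(expected, abs=1e-12)

    def test_charge_indices_p4(self):
        ggi, jgi = topological_charge(P4, 2)
        assert ggi == pytest.approx(2 / 9, abs=1e-12)
        assert jgi == pytest.approx(1 / 9, abs=1e-12)

    def test_charge_indices_edge_cases(self):
        assert topological_charge(K2, 2) == (0.0, 0.0)
        # symmetry of the 3-path makes CT_13 vanish
        assert topological_charge(P3, 2)[1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("graph,k,expected", [(K2, 4, 0.0), (P5, 4, 1 / 15)])
    def test_path_walk(self, graph, k, expected):
        assert path_walk_shape(graph, k) == pytest.approx(expected, abs=1e-12)

    def test_pw1_is_always_one(self, rng):
        for _ in range(5):
            g = _oracles.random_connected_graph(rng)
            assert path_walk_shape(g, 1) == pytest.approx(1.0)


class TestOracleEquivalence:
    def test_families_match_brute_force(self, rng):
        for _ in range(60):
            g = _oracles.random_connected_graph(rng)
            for k in (1, 2, 3, 4):
                assert chi_average(g, k) == pytest.approx(
                    _oracles.chi_average_oracle(g, k), abs=1e-10
                )
                assert topological_charge(g, k) == pytest.approx(
                    _oracles.topological_charge_oracle(g, k), abs=1e-10
                )
            for k in (2, 3, 4, 5):
                assert path_walk_shape(g, k) == pytest.approx(
                    _oracles.path_walk_oracle(g, k), abs=1e-10
                )


class TestInvariances:
    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_permutation_invariance(self, graph_seed, perm_seed):
        g = _oracles.random_connected_graph(np.random.default_rng(graph_seed))
        perm = np.random.default_rng(perm_seed).permutation(g.number_of_nodes())
        h = nx.relabel_nodes(g, {v: int(perm[i]) for i, v in enumerate(sorted(g.nodes))})
        for k in (2, 3, 4):
            assert chi_average(h, k) == pytest.approx(chi_average(g, k), abs=1e-10)
            assert topological_charge(h, k)[1] == pytest.approx(
                topological_charge(g, k)[1], abs=1e-10
            )
            assert path_walk_shape(h, k) == pytest.approx(path_walk_shape(g, k), abs=1e-10)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_charge_term_antisymmetry_and_degree_diagonal(self, seed):
        g = _oracles.random_connected_graph(np.random.default_rng(seed))
        ct = descriptors.charge_term_matrix(g)
        off = ct + ct.T - 2 * np.diag(np.diag(ct))
        assert np.allclose(off, 0, atol=1e-12)
        degs = [d for _, d in sorted(g.degree)]
        assert np.allclose(np.diag(ct), degs)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10**6), st.sampled_from([2, 3, 4, 5]))
    def test_pw_bounds(self, seed, k):
        g = _oracles.random_connected_graph(np.random.default_rng(seed))
        assert 0.0 <= path_walk_shape(g, k) <= 1.0


class TestDescriptorVector:
    def test_same_loop_different_stem_shares_topology(self):
        rec = pool_io.SequenceRecord(1, "1", "")
        weak = folding.fold_mfe("ATGCAACTAGCAT")
        strong = folding.fold_mfe("GCGCAACTAGCGC")
        assert weak.energy_E != strong.energy_E
        vecs = []
        for stc in (weak, strong):
            loop = folding.select_loop(folding.enumerate_loops(stc))
            assert folding.loop_sequence(stc, loop) == "AACTA"
            vecs.append(descriptors.descriptor_vector(rec, stc, loop))
        a, b = vecs
        assert (a.PW4, a.X3A, a.JGI2) == (b.PW4, b.X3A, b.JGI2)
        assert a.E != b.E

    def test_vector_bounds_on_real_loops(self):
        for loop_seq in ("AACAA", "CACACA", "GATTACA"):
            pw4, x3a, jgi2 = descriptors.loop_descriptors(loop_seq)
            assert 0 <= pw4 <= 1
            assert x3a >= 0
            assert jgi2 >= 0

    def test_binders_fold_lower_than_nonbinders(self, small_pool, small_structures):
        pool, truth = small_pool
        e_b = [small_structures[r.key].energy_E for r in pool if truth[r.key]]
        e_n = [small_structures[r.key].energy_E for r in pool if not truth[r.key]]
        assert np.mean(e_b) < np.mean(e_n)

    def test_table_has_expected_columns(self, small_pool, small_structures):
        pool, _ = small_pool
        filtered = pool_io.filter_pool(pool, small_structures)
        loops = {
            r.key: folding.select_loop(folding.enumerate_loops(small_structures[r.key]))
            for r in filtered
        }
        table = descriptors.descriptor_table(filtered.records, small_structures, loops)
        assert list(table.columns) == ["id", "round", "PW4", "X3A", "JGI2", "E"]
        assert len(table) == len(filtered)
        assert (table["E"] <= 0).all()
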