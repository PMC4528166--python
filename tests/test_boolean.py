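"""Boolean network representation and synchronous dynamics."""

import json

import numpy as np
import pytest

from ltpnet.boolean import (
    RuleSet,
    TopologyError,
    constant_rules,
    copy_rules,
    find_attractor,
    load_topology,
    read_edge_list,
    rules_from_json,
    rules_to_json,
    sample_rules,
    step,
    write_edge_list,
)
from conftest import brute_force_attractor, random_topology


class TestLoadTopology:
    def test_single_edge(self):
        t = load_topology([("A", "B")])
        assert t.n_nodes == 2
        assert t.n_edges == 1
        assert list(t.in_degree) == [0, 1]

    def test_three_cycle_degrees(self, ring3):
        assert list(ring3.in_degree) == [1, 1, 1]
        assert list(ring3.out_degree) == [1, 1, 1]

    def test_duplicate_edge_rejected(self):
        with pytest.raises(TopologyError, match="duplicate edge 'A' -> 'B'"):
            load_topology([("A", "B"), ("A", "B")])

    def test_empty_input_rejected(self):
        with pytest.raises(TopologyError):
            load_topology([])

    def test_isolated_nodes_via_node_list(self):
        t = load_topology([("A", "B")], nodes=["A", "B", "C"])
        assert t.n_nodes == 3
        assert t.in_degree[2] == 0

    def test_self_loop_legal(self):
        t = load_topology([("A", "A")])
        assert t.regulators[0] == (0,)

    def test_degree_sums_match_edge_count(self):
        t = random_topology(12, 30, seed=5)
        assert t.in_degree.sum() == t.out_degree.sum() == 30

    def test_edge_list_roundtrip_with_comments(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("# header comment\nA\tB\nB\tC\textra_annotation\n\nC\tA\n")
        t = read_edge_list(p)
        assert t.n_edges == 3 and t.n_nodes == 3
        out = tmp_path / "copy.tsv"
        write_edge_list(t, out)
        t2 = read_edge_list(out)
        assert t2.edge_set() == t.edge_set() and t2.labels == t.labels


class TestSampleRules:
    def test_table_lengths_are_powers_of_in_degree(self):
        t = load_topology([("A", "C"), ("B", "C"), ("C", "A")], nodes="ABCD")
        r = sample_rules(t, seed=0)
        assert [len(x) for x in r.tables] == [2, 1, 4, 1]  # k = 1, 0, 2, 0

    def test_same_seed_reproduces(self):
        t = random_topology(10, 25, seed=1)
        assert sample_rules(t, seed=7) == sample_rules(t, seed=7)
        assert sample_rules(t, seed=7) != sample_rules(t, seed=8)

    def test_flat_distribution_fraction(self):
        # 128 nodes x in-degree 10 -> 131072 Bernoulli(0.5) entries
        edges = [(f"s{j}", f"t{i}") for i in range(128) for j in range(10)]
        t = load_topology(edges)
        r = sample_rules(t, seed=3)
        bits = np.concatenate([x for x in r.tables if len(x) > 1])
        frac = bits.mean()
        se = 0.5 / np.sqrt(len(bits))
        assert abs(frac - 0.5) < 4 * se

    def test_bias_validation(self, ring3):
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                sample_rules(ring3, bias=bad)

    def test_in_degree_guard(self):
        edges = [(f"s{j}", "hub") for j in range(21)]
        t = load_topology(edges)
        with pytest.raises(ValueError, match="max_in_degree"):
            sample_rules(t, seed=0)
        # override accepted
        sample_rules(t, seed=0, max_in_degree=21)


class TestStep:
    def test_copy_rules_rotate_ring(self, ring3):
        out = step(ring3, copy_rules(ring3), np.array([1, 0, 0], dtype=np.uint8))
        assert list(out) == [0, 1, 0]

    def test_not_rules_hand_enumeration(self, ring3):
        # A<-C, B<-A, C<-B; NOT of (1,0,0): (not 0, not 1, not 0) = (1,0,1)
        out = step(ring3, copy_rules(ring3, negate=True), np.array([1, 0, 0], dtype=np.uint8))
        assert list(out) == [1, 0, 1]

    def test_constant_rules_freeze(self):
        t = random_topology(9, 20, seed=2)
        out = step(t, constant_rules(t, 0), np.ones(9, dtype=np.uint8))
        assert not out.any()

    def test_input_state_unmodified_and_deterministic(self, ring3):
        r = sample_rules(ring3, seed=4)
        s = np.array([1, 1, 0], dtype=np.uint8)
        before = s.copy()
        o1 = step(ring3, r, s)
        o2 = step(ring3, r, s)
        assert np.array_equal(s, before)
        assert np.array_equal(o1, o2)

    def test_dimension_mismatch(self, ring3):
        with pytest.raises(ValueError, match="does not match"):
            step(ring3, sample_rules(ring3, seed=0), np.zeros(4, dtype=np.uint8))

    @pytest.mark.parametrize("seed", range(4))
    def test_locality_exhaustive_flips(self, seed):
        """Flipping a non-regulator never changes a node's next value."""
        t = random_topology(8, 18, seed=seed)
        r = sample_rules(t, seed=seed + 100)
        rng = np.random.default_rng(seed)
        s = (rng.random(8) < 0.5).astype(np.uint8)
        base = step(t, r, s)
        for flip in range(8):
            s2 = s.copy()
            s2[flip] ^= 1
            out = step(t, r, s2)
            for node in range(8):
                if flip not in t.regulators[node]:
                    assert out[node] == base[node]


class TestFindAttractor:
    def test_constant_rules_fixed_point(self):
        t = random_topology(7, 15, seed=3)
        att = find_attractor(t, constant_rules(t, 1), np.zeros(7, dtype=np.uint8))
        assert att.length == 1
        assert att.transient_length <= 1

    def test_copy_ring_three_cycle(self, ring3):
        att = find_attractor(ring3, copy_rules(ring3), np.array([1, 0, 0], dtype=np.uint8))
        assert att.length == 3
        assert att.transient_length == 0

    def test_not_ring_cycles(self, ring3):
        # brute-force derivation: the uniform states swap with each other,
        # the six mixed states form a single 6-cycle
        rules = copy_rules(ring3, negate=True)
        att_uniform = find_attractor(ring3, rules, np.array([0, 0, 0], dtype=np.uint8))
        assert att_uniform.length == 2
        att_mixed = find_attractor(ring3, rules, np.array([1, 0, 0], dtype=np.uint8))
        assert att_mixed.length == 6

    def test_attractor_closure(self):
        t = random_topology(8, 20, seed=9)
        r = sample_rules(t, seed=9)
        att = find_attractor(t, r, np.zeros(8, dtype=np.uint8))
        cycle = set(att.cycle)
        for s in att.cycle:
            nxt = tuple(int(b) for b in step(t, r, np.array(s, dtype=np.uint8)))
            assert nxt in cycle

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_transition_graph_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        t = random_topology(n, int(rng.integers(n, 3 * n)), seed=seed + 50)
        r = sample_rules(t, seed=seed + 500)
        init = (rng.random(n) < 0.5).astype(np.uint8)
        att = find_attractor(t, r, init, max_steps=2**n + 1)
        cycle, transient = brute_force_attractor(t, r, init)
        assert att.length == len(cycle)
        assert att.transient_length == transient
        assert set(att.cycle) == set(cycle)

    def test_not_converged_error(self, ring3):
        with pytest.raises(RuntimeError, match="no attractor"):
            find_attractor(ring3, copy_rules(ring3), np.array([1, 0, 0], dtype=np.uint8), max_steps=2)


def test_rules_json_roundtrip(ring3):
    r = sample_rules(ring3, seed=11)
    text = rules_to_json(ring3, r)
    payload = json.loads(text)
    assert "least-significant" in payload["encoding"]
    assert rules_from_json(ring3, text) == r


def test_ruleset_rejects_bad_table_length():
    with pytest.raises(ValueError):
        RuleSet((np.array([0, 1, 1], dtype=np.uint8),))
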