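import numpy as np
import pytest

from ltpnet.boolean import DirectedTopology, RuleSet, load_topology, step


@pytest.fixture
def ring3() -> DirectedTopology:
    """Directed 3-cycle A->B->C->A (every in/out-degree 1)."""
    return load_topology([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def ring20() -> DirectedTopology:
    labels = [f"n{i}" for i in range(20)]
    return load_topology([(labels[i], labels[(i + 1) % 20]) for i in range(20)])


def random_topology(n_nodes: int, n_edges: int, seed: int) -> DirectedTopology:
    """Uniform random directed topology without self-loops (test helper)."""
    rng = np.random.default_rng(seed)
    capacity = n_nodes * (n_nodes - 1)
    codes = rng.choice(capacity, size=n_edges, replace=False)
    edges = []
    for c in codes:
        src, off = divmod(int(c), n_nodes - 1)
        tgt = off if off < src else off + 1
        edges.append((chr(65 + src), chr(65 + tgt)))
    return load_topology(edges, nodes=[chr(65 + i) for i in range(n_nodes)])


def brute_force_attractor(topology: DirectedTopology, rules: RuleSet, init):
    """Independent attractor oracle: full 2^N transition graph walk.

    Enumerates the trajectory state by state using only single `step`
    calls and plain python bookkeeping; returns (cycle_states, transient).
    """
    n = topology.n_nodes
    assert n <= 12, "oracle is exponential"
    state = tuple(int(b) for b in init)
    path = []
    seen = {}
    while state not in seen:
        seen[state] = len(path)
        path.append(state)
        state = tuple(int(b) for b in step(topology, rules, np.array(state, dtype=np.uint8)))
    start = seen[state]
    return path[start:], start


def to_triple_loop(adj: np.ndarray) -> np.ndarray:
    """Brute-force O(N^3) topological overlap oracle (diagonal ignored)."""
    a = adj.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    n = len(a)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return out
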