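"""Synchronous Boolean gene-network dynamics.

A gene network is a directed graph in which an edge ``j -> i`` means gene
*j* acts upon gene *i*.  The state of an *N*-gene network is a bit vector
``G = (x_1, ..., x_N)``, each gene being transcriptionally active (1) or
inactive (0).  Every gene *i* carries a fixed Boolean function ``b_i``
mapping each combination of its ``k_i`` regulator values at time ``t-1``
to its own value at time ``t``; all genes update synchronously, so the
dynamics are deterministic and every trajectory eventually enters a
recurring cycle of states (an attractor), the classic model of
homeostatic cell states.

Truth-table convention
----------------------
For a node with regulators listed in ascending node-index order, an input
combination is encoded as the integer whose *least-significant bit* is the
value of the first (lowest-index) regulator.  A node with in-degree 0 has
a single-entry table: a constant output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DirectedTopology",
    "RuleSet",
    "Attractor",
    "TopologyError",
    "load_topology",
    "read_edge_list",
    "write_edge_list",
    "sample_rules",
    "step",
    "find_attractor",
    "rules_to_json",
    "rules_from_json",
]

#: guard against astronomically large truth tables (2^k entries per node)
MAX_IN_DEGREE = 20

ENCODING_CONVENTION = "ascending-regulator-index; first regulator = least-significant bit"


class TopologyError(ValueError):
    """Raised for malformed edge lists or infeasible graph requests."""


@dataclass(frozen=True)
class DirectedTopology:
    """Labeled directed graph housing the wiring of a Boolean network.

    ``edges`` are (source, target) node-index pairs: source acts upon
    target.  Self-loops are legal (a gene may regulate itself); duplicate
    edges are not.
    """

    labels: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    regulators: tuple[tuple[int, ...], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n == 0:
            raise TopologyError("topology needs at least one node")
        if len(set(self.labels)) != n:
            raise TopologyError("node labels must be unique")
        seen: set[tuple[int, int]] = set()
        for e in self.edges:
            if e in seen:
                raise TopologyError(f"duplicate edge {self.labels[e[0]]!r} -> {self.labels[e[1]]!r}")
            seen.add(e)
            for idx in e:
                if not 0 <= idx < n:
                    raise TopologyError(f"edge index {idx} outside [0, {n})")
        regs: list[list[int]] = [[] for _ in range(n)]
        for src, tgt in self.edges:
            regs[tgt].append(src)
        object.__setattr__(
            self, "regulators", tuple(tuple(sorted(r)) for r in regs)
        )

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def in_degree(self) -> np.ndarray:
        return np.array([len(r) for r in self.regulators], dtype=int)

    @property
    def out_degree(self) -> np.ndarray:
        out = np.zeros(self.n_nodes, dtype=int)
        for src, _ in self.edges:
            out[src] += 1
        return out

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.edges)


@dataclass(frozen=True)
class RuleSet:
    """Per-node Boolean truth tables.

    ``tables[i]`` is a uint8 array of length ``2**k_i`` giving node *i*'s
    next value for every encoded combination of its regulators' current
    values.  An in-degree-0 node has a single constant entry.
    """

    tables: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        for i, t in enumerate(self.tables):
            if t.ndim != 1 or len(t) == 0 or len(t) & (len(t) - 1):
                raise ValueError(f"table {i} length {len(t)} is not a power of two")

    def __eq__(self, other: object) -> bool:  # arrays break dataclass eq
        if not isinstance(other, RuleSet):
            return NotImplemented
        return len(self.tables) == len(other.tables) and all(
            np.array_equal(a, b) for a, b in zip(self.tables, other.tables)
        )


@dataclass(frozen=True)
class Attractor:
    """A recurring state cycle together with the transient that led to it."""

    cycle: tuple[tuple[int, ...], ...]
    transient_length: int

    @property
    def length(self) -> int:
        return len(self.cycle)


# ---------------------------------------------------------------------------
# topology construction and I/O


def load_topology(
    edge_list: Sequence[tuple[str, str]],
    nodes: Iterable[str] | None = None,
) -> DirectedTopology:
    """Build a :class:`DirectedTopology` from labeled (source, target) pairs.

    Node set is the union of labels appearing in edges plus any extra
    isolated nodes supplied via ``nodes``; label order of first appearance
    is preserved.  Duplicate edges raise :class:`TopologyError`.
    """
    if nodes is None and len(edge_list) == 0:
        raise TopologyError("empty edge list and no node list supplied")
    labels: dict[str, int] = {}
    if nodes is not None:
        for lab in nodes:
            labels.setdefault(str(lab), len(labels))
    for pair in edge_list:
        if len(pair) != 2:
            raise TopologyError(f"malformed edge {pair!r}")
        for lab in pair:
            labels.setdefault(str(lab), len(labels))
    idx = {lab: i for lab, i in labels.items()}
    edges = []
    seen = set()
    for src, tgt in edge_list:
        e = (idx[str(src)], idx[str(tgt)])
        if e in seen:
            raise TopologyError(f"duplicate edge {src!r} -> {tgt!r}")
        seen.add(e)
        edges.append(e)
    return DirectedTopology(tuple(labels), tuple(edges))


def read_edge_list(path: str | Path, nodes: Iterable[str] | None = None) -> DirectedTopology:
    """Read a tab-separated ``source<TAB>target`` edge-list file.

    Lines starting with ``#`` are comments; a third column, if present,
    is ignored (annotated exports).
    """
    pairs: list[tuple[str, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise TopologyError(f"line {raw!r} has fewer than two tab-separated columns")
        pairs.append((fields[0], fields[1]))
    return load_topology(pairs, nodes=nodes)


def write_edge_list(topology: DirectedTopology, path: str | Path) -> None:
    lines = [
        f"{topology.labels[s]}\t{topology.labels[t]}" for s, t in topology.edges
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# rules


def sample_rules(
    topology: DirectedTopology,
    bias: float = 0.5,
    seed: int | np.random.Generator = 0,
    max_in_degree: int = MAX_IN_DEGREE,
) -> RuleSet:
    """Draw a random rule set from the flat distribution.

    Every truth-table entry is an independent Bernoulli(``bias``) draw;
    the default ``bias=0.5`` is the unbiased flat construction
    ``P(b_i = 1) = 0.5``.  In-degree-0 nodes receive a single constant
    output drawn the same way.
    """
    if not 0.0 < bias < 1.0:
        raise ValueError(f"bias must lie strictly inside (0, 1), got {bias}")
    kmax = int(topology.in_degree.max(initial=0))
    if kmax > max_in_degree:
        raise ValueError(
            f"in-degree {kmax} exceeds the guard {max_in_degree} "
            "(pass max_in_degree=... to override)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = tuple(
        (rng.random(2 ** len(regs)) < bias).astype(np.uint8)
        for regs in topology.regulators
    )
    return RuleSet(tables)


def constant_rules(topology: DirectedTopology, value: int = 0) -> RuleSet:
    """All-constant rule set: every node outputs ``value`` regardless of input."""
    return RuleSet(
        tuple(
            np.full(2 ** len(r), value, dtype=np.uint8) for r in topology.regulators
        )
    )


def copy_rules(topology: DirectedTopology, negate: bool = False) -> RuleSet:
    """Copy (or NOT) rules for a topology where every node has in-degree 1.

    Each node outputs its sole regulator's value (negated when ``negate``).
    Useful for rings and permutation topologies where the dynamics are
    exactly solvable.
    """
    tables = []
    for regs in topology.regulators:
        if len(regs) != 1:
            raise ValueError("copy rules require every node to have in-degree 1")
        t = np.array([0, 1], dtype=np.uint8)
        tables.append(1 - t if negate else t)
    return RuleSet(tuple(tables))


def rules_to_json(topology: DirectedTopology, rules: RuleSet) -> str:
    """Serialize truth tables as label -> bit string, with the encoding note."""
    payload = {
        "encoding": ENCODING_CONVENTION,
        "tables": {
            topology.labels[i]: "".join(map(str, rules.tables[i].tolist()))
            for i in range(topology.n_nodes)
        },
    }
    return json.dumps(payload, indent=2)


def rules_from_json(topology: DirectedTopology, text: str) -> RuleSet:
    payload = json.loads(text)
    tables = []
    for i, lab in enumerate(topology.labels):
        bits = payload["tables"][lab]
        expected = 2 ** len(topology.regulators[i])
        if len(bits) != expected:
            raise ValueError(f"table for {lab!r} has {len(bits)} entries, expected {expected}")
        tables.append(np.array([int(b) for b in bits], dtype=np.uint8))
    return RuleSet(tuple(tables))


# ---------------------------------------------------------------------------
# dynamics


def _check_state(topology: DirectedTopology, state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=np.uint8)
    if state.shape[-1] != topology.n_nodes:
        raise ValueError(
            f"state length {state.shape[-1]} does not match N={topology.n_nodes}"
        )
    return state


def step(topology: DirectedTopology, rules: RuleSet, state: np.ndarray) -> np.ndarray:
    """One synchronous update of a single state vector.

    Node *i*'s next value depends only on the time-(t-1) values of its
    regulators, looked up in its truth table; the input state is not
    modified.
    """
    state = _check_state(topology, state)
    return step_batch(topology, rules, state[None, :])[0]


def step_batch(
    topology: DirectedTopology, rules: RuleSet, states: np.ndarray
) -> np.ndarray:
    """Synchronous update of a (batch, N) array of states, vectorized per node."""
    states = np.asarray(states, dtype=np.uint8)
    if states.ndim != 2 or states.shape[1] != topology.n_nodes:
        raise ValueError("states must be a (batch, N) array")
    if len(rules.tables) != topology.n_nodes:
        raise ValueError("rule set size does not match topology")
    out = np.empty_like(states)
    for i, regs in enumerate(topology.regulators):
        table = rules.tables[i]
        if len(table) != 2 ** len(regs):
            raise ValueError(f"table {i} length {len(table)} != 2^{len(regs)}")
        if not regs:
            out[:, i] = table[0]
            continue
        idx = np.zeros(states.shape[0], dtype=np.intp)
        for j, r in enumerate(regs):  # first regulator = least-significant bit
            idx |= states[:, r].astype(np.intp) << j
        out[:, i] = table[idx]
    return out


def find_attractor(
    topology: DirectedTopology,
    rules: RuleSet,
    init: np.ndarray,
    max_steps: int = 10_000,
) -> Attractor:
    """Iterate synchronous dynamics until a state repeats.

    Keeps a hash of every visited state; on the first revisit, the states
    from the earlier visit onward form the attractor cycle and the steps
    before it the transient.  Raises ``RuntimeError`` when no repeat
    occurs within ``max_steps`` (impossible for ``max_steps >= 2**N``).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = _check_state(topology, init)
    seen: dict[tuple[int, ...], int] = {}
    trajectory: list[tuple[int, ...]] = []
    for _ in range(max_steps + 1):
        key = tuple(int(b) for b in state)
        if key in seen:
            start = seen[key]
            return Attractor(cycle=tuple(trajectory[start:]), transient_length=start)
        seen[key] = len(trajectory)
        trajectory.append(key)
        state = step(topology, rules, state)
    raise RuntimeError(f"no attractor found within {max_steps} steps")
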