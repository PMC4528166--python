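"""Null-model network ensembles for stability comparisons.

Two nulls isolate what drives a topology's robustness:

* *random same-size* — same nodes and edge count, pairs connected
  uniformly at random: controls only for density (average degree);
* *rewired* — repeated double-edge swaps (A→B, C→D become A→D, C→B,
  rejected if either new edge already exists) preserve every node's in-
  and out-degree exactly: controls for the full degree sequence, so only
  higher-order wiring differs from the input.

Ensemble Derrida curves are summarized as pointwise min/max envelopes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .boolean import DirectedTopology, TopologyError, write_edge_list
from .derrida import DerridaCurve

__all__ = [
    "EnsembleEnvelope",
    "RewireError",
    "random_same_size",
    "rewire",
    "ensemble",
    "envelope",
    "write_ensemble",
]


class RewireError(RuntimeError):
    """Swap budget exhausted before reaching the requested successful swaps."""

    def __init__(self, requested: int, achieved: int, attempts: int):
        self.requested = requested
        self.achieved = achieved
        self.attempts = attempts
        super().__init__(
            f"achieved {achieved}/{requested} successful swaps in {attempts} attempts"
        )


@dataclass(frozen=True)
class EnsembleEnvelope:
    """Pointwise range of Derrida curves across an ensemble."""

    tau: int
    h0_norm: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    ensemble_size: int
    kind: str

    def to_csv(self, path: str | Path) -> None:
        lines = ["h0_norm,lower,upper"]
        lines += [
            f"{h:.10g},{lo:.10g},{hi:.10g}"
            for h, lo, hi in zip(self.h0_norm, self.lower, self.upper)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def random_same_size(
    topology: DirectedTopology,
    seed: int | np.random.Generator = 0,
    allow_self_loops: bool = False,
) -> DirectedTopology:
    """Random directed graph with the same labels and edge count.

    Edges are drawn uniformly without duplicates until the input's edge
    count is reached.  Weak connectivity is not enforced; isolated nodes
    may occur.
    """
    n = topology.n_nodes
    e = topology.n_edges
    capacity = n * n if allow_self_loops else n * (n - 1)
    if e > capacity:
        raise TopologyError(f"{e} edges exceed capacity {capacity} for N={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # sample e distinct pair codes out of the full capacity
    codes = rng.choice(capacity, size=e, replace=False)
    edges = []
    for c in codes:
        if allow_self_loops:
            src, tgt = divmod(int(c), n)
        else:
            src, off = divmod(int(c), n - 1)
            tgt = off if off < src else off + 1
        edges.append((src, tgt))
    return DirectedTopology(topology.labels, tuple(edges))


def rewire(
    topology: DirectedTopology,
    n_successful_swaps: int | None = None,
    seed: int | np.random.Generator = 0,
    attempt_factor: int = 100,
    allow_self_loops: bool = False,
) -> DirectedTopology:
    """Degree-preserving randomization by double-edge swaps.

    Picks two distinct edges A→B and C→D and replaces them with A→D and
    C→B; the swap is rejected if either replacement already exists, would
    duplicate the other, or (by default) would create a self-loop.  Every
    node's in- and out-degree is conserved exactly.  Default swap count
    is ``10 * E`` (a standard Markov-chain mixing heuristic); the attempt
    budget is ``attempt_factor`` times the requested swaps, and
    exhausting it raises :class:`RewireError`.
    """
    if topology.n_edges < 2:
        raise TopologyError("rewiring needs at least 2 edges")
    if n_successful_swaps is None:
        n_successful_swaps = 10 * topology.n_edges
    if n_successful_swaps < 1:
        raise ValueError("n_successful_swaps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = list(topology.edges)
    present = set(edges)
    budget = attempt_factor * n_successful_swaps
    done = 0
    for attempt in range(budget):
        i, j = rng.choice(len(edges), size=2, replace=False)
        a, b = edges[i]
        c, d = edges[j]
        new1, new2 = (a, d), (c, b)
        if new1 == new2 or new1 in present or new2 in present:
            continue
        if not allow_self_loops and (a == d or c == b):
            continue
        present.discard(edges[i])
        present.discard(edges[j])
        present.add(new1)
        present.add(new2)
        edges[i] = new1
        edges[j] = new2
        done += 1
        if done == n_successful_swaps:
            return DirectedTopology(topology.labels, tuple(edges))
    raise RewireError(n_successful_swaps, done, budget)


def ensemble(
    topology: DirectedTopology,
    kind: str,
    size: int = 100,
    seed: int = 0,
    n_successful_swaps: int | None = None,
    allow_self_loops: bool = False,
) -> list[DirectedTopology]:
    """Generate ``size`` independent seeded null networks of the given kind."""
    if size < 1:
        raise ValueError("ensemble size must be >= 1")
    if kind not in ("random", "rewired"):
        raise ValueError(f"kind must be 'random' or 'rewired', got {kind!r}")
    members = []
    for child in np.random.SeedSequence(seed).spawn(size):
        rng = np.random.default_rng(child)
        if kind == "random":
            members.append(
                random_same_size(topology, seed=rng, allow_self_loops=allow_self_loops)
            )
        else:
            members.append(
                rewire(
                    topology,
                    n_successful_swaps=n_successful_swaps,
                    seed=rng,
                    allow_self_loops=allow_self_loops,
                )
            )
    return members


def envelope(curves: Sequence[DerridaCurve], kind: str = "random") -> EnsembleEnvelope:
    """Pointwise minimum and maximum across member Derrida curves."""
    if not curves:
        raise ValueError("need at least one curve")
    tau = curves[0].tau
    grid = tuple(curves[0].h0_norm.tolist())
    for c in curves[1:]:
        if c.tau != tau or tuple(c.h0_norm.tolist()) != grid:
            raise ValueError("curves must share tau and the h0 grid")
    stack = np.vstack([c.mean_h_tau_norm for c in curves])
    return EnsembleEnvelope(
        tau=tau,
        h0_norm=grid,
        lower=tuple(stack.min(axis=0).tolist()),
        upper=tuple(stack.max(axis=0).tolist()),
        ensemble_size=len(curves),
        kind=kind,
    )


def write_ensemble(
    members: Sequence[DirectedTopology],
    outdir: str | Path,
    kind: str,
    seed: int,
    **params,
) -> None:
    """Write members as numbered edge-list files plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = len(str(len(members)))
    for i, m in enumerate(members):
        write_edge_list(m, outdir / f"member_{i:0{width}d}.tsv")
    manifest = {"kind": kind, "seed": seed, "size": len(members), **params}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def edge_jaccard(a: DirectedTopology, b: DirectedTopology) -> float:
    """Jaccard overlap of two topologies' edge sets (randomization check)."""
    ea, eb = a.edge_set(), b.edge_set()
    union = len(ea | eb)
    return len(ea & eb) / union if union else 1.0
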