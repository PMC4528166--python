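"""Synthetic inputs: directed topologies with controlled degree structure
and multi-condition expression matrices with planted co-expression
modules whose connectivity changes over conditions.

The expression generator uses a Gaussian latent-factor model.  For
module *m* in condition *c* with target intra-module correlation
``rho_mc``, each sample draws one latent factor ``f ~ N(0, 1)`` and each
member gene takes

    value = mu_mc + sqrt(rho_mc) * f + sqrt(1 - rho_mc) * eps,

``eps ~ N(0, 1)`` i.i.d., so the expected Pearson correlation between
any two members is exactly ``rho_mc``; background genes are pure noise.
Everything is scaled by ``noise_sd`` and shifted by ``baseline`` to sit
on a log-intensity-like scale.  Per-contrast p-value rankings come from
two-sample t-tests of each condition against the first (control)
condition, so the gene-selection stage is exercised end to end.

Every bundle carries its ground truth (module map, correlation
schedule) for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .boolean import DirectedTopology, TopologyError
from .coexpr import ExpressionMatrix

__all__ = [
    "PlantedModule",
    "ScenarioSpec",
    "ExpressionBundle",
    "make_topology",
    "simulate_expression",
    "paper_like_scenario",
]


@dataclass(frozen=True)
class PlantedModule:
    """One planted module: size, per-condition correlation, per-condition mean shift."""

    size: int
    rho: tuple[float, ...]
    effect: tuple[float, ...] = ()


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of a multi-condition expression scenario."""

    n_genes: int
    conditions: tuple[str, ...]
    samples_per_condition: int
    modules: tuple[PlantedModule, ...]
    noise_sd: float = 1.0
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_condition < 3:
            raise ValueError("need >= 3 samples per condition")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ValueError(
                f"module sizes sum to {total} > n_genes={self.n_genes}"
            )
        nc = len(self.conditions)
        for m in self.modules:
            if len(m.rho) != nc:
                raise ValueError("each module needs one rho per condition")
            if any(not 0.0 <= r < 1.0 for r in m.rho):
                raise ValueError("rho values must lie in [0, 1)")
            if m.effect and len(m.effect) != nc:
                raise ValueError("effect schedule must match conditions")


@dataclass
class ExpressionBundle:
    """Generated expression data plus its ground truth.

    ``expression`` holds all conditions in one matrix (sample condition
    tags distinguish them); ``rankings`` maps contrast names
    (``"<condition>_vs_<control>"``) to p-value Series; ``truth`` maps
    gene -> planted module name (background genes absent).
    """

    spec: ScenarioSpec
    expression: ExpressionMatrix
    rankings: dict[str, pd.Series]
    truth: dict[str, str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
        for name, pv in self.rankings.items():
            pv.rename("p").to_csv(outdir / f"ranking_{name}.tsv", sep="\t", index_label="gene")
        truth = {
            "modules": self.truth,
            "rho": {
                f"pm{i:02d}": list(m.rho) for i, m in enumerate(self.spec.modules, 1)
            },
            "conditions": list(self.spec.conditions),
            "seed": self.spec.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


# ---------------------------------------------------------------------------
# topologies


def make_topology(
    n_nodes: int,
    n_edges: int | None = None,
    style: str = "uniform_random",
    seed: int = 0,
    in_degrees: Sequence[int] | None = None,
    pa_out: int = 2,
    label_prefix: str = "g",
) -> DirectedTopology:
    """Directed topology generator with controlled degree structure.

    Styles
    ------
    ``uniform_random``
        ``n_edges`` distinct directed edges drawn uniformly (no
        self-loops).
    ``preferential_attachment``
        A Barabási–Albert graph with ``pa_out`` attachments per new
        node, each edge oriented from the older endpoint to the newer
        one: older nodes accumulate heavy-tailed out-degree while
        in-degrees stay near ``pa_out`` (keeps Boolean truth tables
        small).  ``n_edges`` is ignored.
    ``in_degree_sequence``
        Realizes an exact in-degree sequence by stub matching with
        duplicate/self-loop rejection; sources are drawn uniformly.
    """
    labels = tuple(f"{label_prefix}{i:03d}" for i in range(n_nodes))
    rng = np.random.default_rng(seed)
    if style == "uniform_random":
        if n_edges is None:
            raise ValueError("uniform_random needs n_edges")
        capacity = n_nodes * (n_nodes - 1)
        if n_edges > capacity:
            raise TopologyError(f"{n_edges} edges exceed capacity {capacity}")
        codes = rng.choice(capacity, size=n_edges, replace=False)
        edges = []
        for c in codes:
            src, off = divmod(int(c), n_nodes - 1)
            tgt = off if off < src else off + 1
            edges.append((src, tgt))
        return DirectedTopology(labels, tuple(edges))
    if style == "preferential_attachment":
        g = nx.barabasi_albert_graph(
            n_nodes, pa_out, seed=int(rng.integers(2**31))
        )
        edges = tuple((min(u, v), max(u, v)) for u, v in g.edges())
        return DirectedTopology(labels, edges)
    if style == "in_degree_sequence":
        if in_degrees is None:
            raise ValueError("in_degree_sequence needs in_degrees")
        if len(in_degrees) != n_nodes:
            raise ValueError("in_degrees length must equal n_nodes")
        if any(k < 0 or k > n_nodes - 1 for k in in_degrees):
            raise TopologyError("in-degree outside [0, N-1] is not realizable without self-loops")
        edges_set: set[tuple[int, int]] = set()
        for tgt, k in enumerate(in_degrees):
            # choose k distinct sources != tgt
            pool = np.array([i for i in range(n_nodes) if i != tgt])
            srcs = rng.choice(pool, size=k, replace=False)
            for s in srcs:
                edges_set.add((int(s), tgt))
        return DirectedTopology(labels, tuple(sorted(edges_set)))
    raise ValueError(f"unknown style {style!r}")


# ---------------------------------------------------------------------------
# expression


def simulate_expression(spec: ScenarioSpec) -> ExpressionBundle:
    """Draw one expression bundle from the latent-factor model.

    Deterministic given ``spec.seed``; see the module docstring for the
    generative model.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    truth: dict[str, str] = {}
    bounds = []
    start = 0
    for i, m in enumerate(spec.modules, 1):
        name = f"pm{i:02d}"
        for g in genes[start : start + m.size]:
            truth[g] = name
        bounds.append((start, start + m.size, m))
        start += m.size

    columns: list[str] = []
    cond_tags: list[str] = []
    blocks: list[np.ndarray] = []
    for ci, cond in enumerate(spec.conditions):
        ns = spec.samples_per_condition
        x = rng.standard_normal((spec.n_genes, ns))
        for lo, hi, m in bounds:
            rho = m.rho[ci]
            f = rng.standard_normal(ns)
            x[lo:hi] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * x[lo:hi]
            if m.effect:
                x[lo:hi] += m.effect[ci]
        blocks.append(spec.baseline + spec.noise_sd * x)
        columns += [f"{cond}_s{j:02d}" for j in range(ns)]
        cond_tags += [cond] * ns
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    expr = ExpressionMatrix(values, pd.Series(cond_tags, index=columns))

    control = spec.conditions[0]
    rankings: dict[str, pd.Series] = {}
    ctrl_block = expr.condition_samples(control).to_numpy()
    for cond in spec.conditions[1:]:
        block = expr.condition_samples(cond).to_numpy()
        _, p = stats.ttest_ind(block, ctrl_block, axis=1)
        rankings[f"{cond}_vs_{control}"] = pd.Series(p, index=genes)
    return ExpressionBundle(spec=spec, expression=expr, rankings=rankings, truth=truth)


def paper_like_scenario(
    seed: int = 0,
    n_genes: int = 1200,
    samples_per_condition: int = 20,
    n_modules: int = 14,
    module_size: int = 60,
) -> ExpressionBundle:
    """Four-condition scenario emulating an LTP-style time course.

    Conditions are control, 20min, 5h, 24h.  Most planted modules follow
    a rise-then-fall correlation schedule — loose under control, tightly
    co-regulated at 20 min, then progressively dissociating at 5 h and
    24 h — so intramodular connectivity gains dominate the first
    transition and losses accumulate over the later ones.  A minority of
    modules stay stable as a conserved background.  Mean shifts
    accompany the correlation changes so differential-expression
    rankings enrich for module genes.
    """
    conditions = ("control", "20min", "5h", "24h")
    rng = np.random.default_rng(seed)
    modules = []
    for i in range(n_modules):
        if i % 6 == 5:  # stable background module
            rho = (0.45, 0.45, 0.45, 0.45)
            effect = (0.0, 0.0, 0.0, 0.0)
        else:  # rise then fall
            hi = 0.55 + 0.1 * rng.random()
            rho = (0.15, hi, 0.30, 0.18)
            effect = (0.0, 0.8, 0.4, 0.1)
        modules.append(PlantedModule(size=module_size, rho=rho, effect=effect))
    spec = ScenarioSpec(
        n_genes=n_genes,
        conditions=conditions,
        samples_per_condition=samples_per_condition,
        modules=tuple(modules),
        noise_sd=1.0,
        seed=int(rng.integers(2**31)),
    )
    return simulate_expression(spec)
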