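"""End-to-end orchestration of the two analysis tracks.

``run_stability`` takes directed topologies and produces Derrida curves
at each configured tau, null-ensemble envelopes, and regime calls,
ordering the networks by origin slope.  ``run_coexpression`` takes an
expression bundle and produces per-condition TO matrices, scale-free
fit reports, modules, hubs, and the MDC transition summary.  Every
stochastic stage derives its seed from the master seed, so a run is
reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .boolean import DirectedTopology
from .coexpr import (
    ExpressionMatrix,
    SimilarityMatrix,
    adjacency,
    correlation,
    scale_free_fit,
    select_genes,
    soft_threshold_scan,
    top_hubs,
    topological_overlap,
)
from .derrida import DerridaCurve, RegimeCall, classify_regime, derrida_map
from .mdc import MDCResult, transition_summary
from .modules import ModuleAssignment, cluster_modules
from .nulls import EnsembleEnvelope, ensemble, envelope
from .synth import ExpressionBundle

log = logging.getLogger("ltpnet")

__all__ = ["RunConfig", "StabilityReport", "CoexpressionReport", "run_stability", "run_coexpression"]


@dataclass
class RunConfig:
    """Master configuration; round-trips losslessly through YAML."""

    seed: int = 0
    taus: tuple[int, ...] = (1, 5)
    n_rule_sets: int = 1000
    n_inits: int = 100
    ensemble_size: int = 100
    swap_factor: int = 10          # successful swaps = swap_factor * E
    power: float = 5.0
    signed: bool = False
    min_module_size: int = 50
    top_k_genes: int = 1700
    n_perm: int = 1000
    alpha: float = 0.10
    n_bins: int = 10

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["taus"] = list(data["taus"])  # yaml has no tuple notion
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.taus = tuple(cfg.taus)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


@dataclass
class StabilityReport:
    """Per-network Derrida curves, envelopes, and regime calls."""

    curves: dict[str, dict[int, DerridaCurve]]            # name -> tau -> curve
    envelopes: dict[str, dict[str, dict[int, EnsembleEnvelope]]]  # name -> kind -> tau
    regimes: dict[str, RegimeCall]                        # from the smallest tau
    ordering: list[str]                                   # by origin slope, most ordered first
    config_digest: str = ""
    seed: int = 0


@dataclass
class CoexpressionReport:
    """Full co-expression artifact set for one expression bundle."""

    selected_genes: list[str]
    to_matrices: dict[str, SimilarityMatrix]
    fit_reports: dict[str, object]
    scans: dict[str, list]
    hubs: dict[str, object]
    assignments: list[ModuleAssignment]
    mdc_results: list[MDCResult]
    transition_counts: object
    config_digest: str = ""
    seed: int = 0

    def manifest(self) -> dict:
        return {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "n_selected_genes": len(self.selected_genes),
            "conditions": list(self.to_matrices),
            "modules": {a.condition: list(a.module_names) for a in self.assignments},
        }


def run_stability(
    config: RunConfig,
    topologies: Mapping[str, DirectedTopology],
    with_envelopes: bool = True,
) -> StabilityReport:
    """Derrida characterization of each topology plus its null ensembles."""
    if not topologies:
        raise ValueError("need at least one topology")
    root = np.random.SeedSequence(config.seed)
    curves: dict[str, dict[int, DerridaCurve]] = {}
    envelopes: dict[str, dict[str, dict[int, EnsembleEnvelope]]] = {}
    regimes: dict[str, RegimeCall] = {}
    for name, topo in topologies.items():
        t0 = time.perf_counter()
        name_key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
        sub = np.random.SeedSequence((config.seed, name_key))
        seeds = sub.generate_state(len(config.taus) + 1)
        curves[name] = {}
        for tau, s in zip(config.taus, seeds):
            curves[name][tau] = derrida_map(
                topo,
                tau=tau,
                n_rule_sets=config.n_rule_sets,
                n_inits=config.n_inits,
                seed=int(s & 0x7FFFFFFF),
            )
        regimes[name] = classify_regime(curves[name][min(config.taus)])
        if with_envelopes:
            envelopes[name] = {}
            for kind in ("random", "rewired"):
                members = ensemble(
                    topo,
                    kind,
                    size=config.ensemble_size,
                    seed=int(seeds[-1] & 0x7FFFFFFF) + (0 if kind == "random" else 1),
                    n_successful_swaps=config.swap_factor * topo.n_edges,
                )
                envelopes[name][kind] = {}
                for tau in config.taus:
                    member_curves = [
                        derrida_map(
                            m,
                            tau=tau,
                            n_rule_sets=config.n_rule_sets,
                            n_inits=config.n_inits,
                            seed=i,
                        )
                        for i, m in enumerate(members)
                    ]
                    envelopes[name][kind][tau] = envelope(member_curves, kind=kind)
        log.info("stability[%s]: %.1fs", name, time.perf_counter() - t0)
    ordering = sorted(regimes, key=lambda n: regimes[n].slope_at_origin)
    return StabilityReport(
        curves=curves,
        envelopes=envelopes,
        regimes=regimes,
        ordering=ordering,
        config_digest=config.digest(),
        seed=config.seed,
    )


def run_coexpression(
    config: RunConfig,
    bundle: ExpressionBundle | ExpressionMatrix,
    rankings: Mapping[str, "object"] | None = None,
    conditions: Sequence[str] | None = None,
    scan_powers: Sequence[float] | None = None,
) -> CoexpressionReport:
    """Gene selection -> TO per condition -> modules -> hubs -> MDC summary."""
    if isinstance(bundle, ExpressionBundle):
        expr = bundle.expression
        rankings = rankings or bundle.rankings
        conditions = conditions or list(bundle.spec.conditions)
    else:
        expr = bundle
        if conditions is None:
            conditions = list(dict.fromkeys(expr.conditions))
    if len(conditions) < 2:
        raise ValueError("MDC needs at least 2 conditions")

    if rankings:
        k = min(config.top_k_genes, min(len(r) for r in rankings.values()))
        selected = select_genes(rankings, k=k)
    else:
        selected = list(expr.genes)
    sub = expr.subset(selected)

    to_matrices: dict[str, SimilarityMatrix] = {}
    fit_reports: dict[str, object] = {}
    scans: dict[str, list] = {}
    hubs: dict[str, object] = {}
    assignments: list[ModuleAssignment] = []
    for cond in conditions:
        t0 = time.perf_counter()
        corr = correlation(sub, cond)
        adj = adjacency(corr, power=config.power, signed=config.signed)
        fit_reports[cond] = scale_free_fit(adj, n_bins=config.n_bins)
        if scan_powers:
            scans[cond] = soft_threshold_scan(
                sub, cond, powers=scan_powers, n_bins=config.n_bins, signed=config.signed
            )
        to = topological_overlap(adj)
        to_matrices[cond] = to
        hubs[cond] = top_hubs(to, n=min(10, len(to.genes)))
        assignments.append(
            cluster_modules(to, min_size=config.min_module_size, condition=cond)
        )
        log.info("coexpr[%s]: %.1fs", cond, time.perf_counter() - t0)

    transitions = list(zip(conditions[:-1], conditions[1:]))
    mdc_results, counts = transition_summary(
        assignments,
        to_matrices,
        transitions,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    return CoexpressionReport(
        selected_genes=selected,
        to_matrices=to_matrices,
        fit_reports=fit_reports,
        scans=scans,
        hubs=hubs,
        assignments=assignments,
        mdc_results=mdc_results,
        transition_counts=counts,
        config_digest=config.digest(),
        seed=config.seed,
    )
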