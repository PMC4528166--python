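"""Weighted gene co-expression networks: correlation, soft-threshold
adjacency, topological overlap, and scale-free diagnostics.

The construction follows the standard weighted co-expression protocol:
per condition, the Pearson correlation of every gene pair is raised to a
soft-thresholding power ``p`` to give an adjacency in [0, 1] (unsigned by
default, ``|cor|^p``), and the topological overlap (TO) then scores each
pair by the agreement of their network neighborhoods,

    TO_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

a similarity better suited to module detection than raw adjacency.  The
scale-free fit index (signed R^2 of the log-log regression of the binned
degree distribution) diagnoses whether a chosen power yields the
heavy-tailed connectivity typical of robust biological networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "SimilarityMatrix",
    "ScaleFreeFitReport",
    "select_genes",
    "correlation",
    "adjacency",
    "topological_overlap",
    "scale_free_fit",
    "soft_threshold_scan",
    "top_hubs",
    "read_expression_tsv",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log-scale expression values with a condition tag per sample.

    ``values`` is a DataFrame with unique gene labels as the index and
    sample IDs as columns; ``conditions`` maps each sample ID to its
    condition label.  Missing values are rejected (handled upstream).
    """

    values: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene labels")
        if self.values.isna().any().any():
            raise ValueError("missing values are not supported; impute or drop upstream")
        self.conditions = pd.Series(self.conditions).reindex(self.values.columns)
        if self.conditions.isna().any():
            missing = list(self.conditions[self.conditions.isna()].index)
            raise ValueError(f"samples without a condition tag: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def condition_samples(self, condition: str) -> pd.DataFrame:
        cols = self.conditions[self.conditions == condition].index
        if len(cols) == 0:
            raise KeyError(f"no samples tagged {condition!r}")
        return self.values[cols]

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.conditions)

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")
        if sidecar is not None:
            self.conditions.rename("condition").to_csv(
                sidecar, sep="\t", index_label="sample"
            )


def read_expression_tsv(path: str | Path, sidecar: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV plus a ``sample<TAB>condition`` sidecar."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    cond = pd.read_csv(sidecar, sep="\t", index_col=0)["condition"]
    return ExpressionMatrix(values, cond)


@dataclass
class SimilarityMatrix:
    """Symmetric gene-gene similarity in [0, 1] (adjacency or TO), diagonal 1."""

    genes: list[str]
    values: np.ndarray
    kind: str  # adjacency | topological_overlap
    power: float | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} genes")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if v.min() < -1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("entries must lie in [0, 1]")
        self.values = v
        self._index = {g: i for i, g in enumerate(self.genes)}

    def loc(self, genes: Sequence[str]) -> np.ndarray:
        idx = [self._index[g] for g in genes]
        return self.values[np.ix_(idx, idx)]

    def connectivity(self) -> pd.Series:
        """Row sums excluding the diagonal (whole-network degree k)."""
        k = self.values.sum(axis=1) - np.diag(self.values)
        return pd.Series(k, index=self.genes, name="k")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.genes, columns=self.genes).to_csv(
            path, sep="\t", index_label="gene"
        )


@dataclass(frozen=True)
class ScaleFreeFitReport:
    """Log-log linear fit of the binned degree distribution at one power."""

    power: float
    fit_index: float  # signed R^2; negative when the slope is positive
    slope: float
    mean_connectivity: float
    n_bins: int


# ---------------------------------------------------------------------------


def select_genes(
    rankings: Mapping[str, pd.Series], k: int = 1700
) -> list[str]:
    """Union of the ``k`` most significant genes of each contrast.

    ``rankings`` maps contrast name to a p-value Series over one shared
    gene universe.  Ties are broken by stable gene-label order.  Returns
    the union sorted by label.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    universes = [frozenset(r.index) for r in rankings.values()]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("rankings must cover the same gene universe")
    selected: set[str] = set()
    for name, pvals in rankings.items():
        if k > len(pvals):
            raise ValueError(f"k={k} exceeds ranking size {len(pvals)} for {name!r}")
        order = pvals.reset_index()
        order.columns = ["gene", "p"]
        order = order.sort_values(["p", "gene"], kind="stable")
        selected.update(order["gene"].head(k))
    return sorted(selected)


def correlation(expr: ExpressionMatrix, condition: str) -> pd.DataFrame:
    """Pearson correlation of every gene pair across one condition's samples."""
    block = expr.condition_samples(condition)
    if block.shape[1] < 3:
        raise ValueError(
            f"condition {condition!r} has {block.shape[1]} samples; need >= 3"
        )
    sd = block.std(axis=1, ddof=1)
    dead = list(sd.index[sd == 0])
    if dead:
        raise ValueError(f"zero-variance genes in condition {condition!r}: {dead[:10]}")
    corr = np.corrcoef(block.to_numpy())
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=block.index, columns=block.index)


def adjacency(
    corr: pd.DataFrame, power: float = 5.0, signed: bool = False
) -> SimilarityMatrix:
    """Soft-threshold adjacency ``a_ij = |cor_ij|^p`` (unsigned default).

    The signed variant uses ``((1 + cor)/2)^p`` so anti-correlated pairs
    get near-zero weight.  Diagonal is set to 1 by convention.
    """
    if power <= 0:
        raise ValueError(f"power must be positive, got {power}")
    c = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if c.min() < -1 - 1e-9 or c.max() > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1.0 + c) / 2.0) ** power if signed else np.abs(c) ** power
    np.fill_diagonal(a, 1.0)
    genes = list(corr.index) if isinstance(corr, pd.DataFrame) else [
        str(i) for i in range(len(a))
    ]
    return SimilarityMatrix(genes=genes, values=a, kind="adjacency", power=power)


def topological_overlap(adj: SimilarityMatrix) -> SimilarityMatrix:
    """Topological overlap matrix of a soft-threshold adjacency.

    Matrix form of the pairwise formula: with the diagonal zeroed,
    ``l = A @ A`` already equals the shared-neighbor sums (terms with
    u = i or u = j vanish) and ``k`` the row sums.
    """
    if adj.kind != "adjacency":
        raise ValueError("topological overlap expects an adjacency matrix")
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    to = (l + a) / denom
    np.fill_diagonal(to, 1.0)
    to = np.clip((to + to.T) / 2.0, 0.0, 1.0)  # symmetrize away float noise
    return SimilarityMatrix(
        genes=adj.genes, values=to, kind="topological_overlap", power=adj.power
    )


def scale_free_fit(adj: SimilarityMatrix, n_bins: int = 10) -> ScaleFreeFitReport:
    """Scale-free topology fit of the (weighted) degree distribution.

    Connectivities ``k_i`` are binned into ``n_bins`` equal-width bins;
    empty bins are dropped and log10 frequency is regressed on log10 mean
    connectivity per bin.  ``fit_index = -sign(slope) * R^2``: close to
    +1 for a decaying power law, negative when frequency *rises* with
    degree.
    """
    k = adj.connectivity().to_numpy()
    n = len(k)
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes, got {n}")
    if np.ptp(k) == 0:
        raise ValueError("degenerate degree sequence: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        freqs.append(mask.sum() / n)
        means.append(k[mask].mean())
    if len(freqs) < 3:
        raise ValueError(f"only {len(freqs)} nonempty bins; need >= 3 for a fit")
    x = np.log10(np.asarray(means))
    y = np.log10(np.asarray(freqs))
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    fit_index = -np.sign(fit.slope) * r2 if fit.slope != 0 else 0.0
    return ScaleFreeFitReport(
        power=adj.power if adj.power is not None else float("nan"),
        fit_index=float(fit_index),
        slope=float(fit.slope),
        mean_connectivity=float(k.mean()),
        n_bins=n_bins,
    )


def soft_threshold_scan(
    expr: ExpressionMatrix,
    condition: str,
    powers: Sequence[float] | None = None,
    n_bins: int = 10,
    signed: bool = False,
) -> list[ScaleFreeFitReport]:
    """Scale-free fit reports over a grid of soft-thresholding powers.

    Supports the scale-free topology criterion for choosing ``p`` (e.g.,
    smallest power whose fit index exceeds a threshold); the correlation
    matrix is computed once and re-powered.
    """
    if powers is None:
        powers = list(range(1, 21))
    powers = [float(p) for p in powers]
    if not powers or any(p <= 0 for p in powers):
        raise ValueError("powers must be a nonempty list of positive reals")
    corr = correlation(expr, condition)
    return [scale_free_fit(adjacency(corr, p, signed=signed), n_bins) for p in powers]


def pick_power(
    reports: Sequence[ScaleFreeFitReport], fit_threshold: float = 0.8
) -> float:
    """Smallest power whose fit index reaches the threshold (scale-free criterion).

    Falls back to the power with the best fit index when none reaches it.
    """
    ordered = sorted(reports, key=lambda r: r.power)
    for r in ordered:
        if r.fit_index >= fit_threshold:
            return r.power
    return max(ordered, key=lambda r: r.fit_index).power


def top_hubs(to: SimilarityMatrix, n: int = 10) -> pd.Series:
    """Top hub genes ranked by whole-network TO connectivity ``k_TO``.

    Descending ``k_TO`` with stable label tie-break; returns a Series of
    length ``n`` indexed by gene.
    """
    if to.kind != "topological_overlap":
        raise ValueError("hubs are ranked on a topological-overlap matrix")
    if n > len(to.genes):
        raise ValueError(f"asked for {n} hubs from {len(to.genes)} genes")
    k = to.connectivity()
    order = k.reset_index()
    order.columns = ["gene", "k"]
    # rank on rounded values so summation-order float noise cannot break
    # what should be an exact tie; report the unrounded connectivities
    order["k_rank"] = order["k"].round(10)
    order = order.sort_values(["k_rank", "gene"], ascending=[False, True], kind="stable")
    head = order.head(n)
    return pd.Series(head["k"].to_numpy(), index=head["gene"], name="k_TO")
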