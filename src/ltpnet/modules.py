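"""Co-expression module detection on topological-overlap similarity.

Modules are clusters of densely interconnected genes: average-linkage
hierarchical clustering on the dissimilarity ``1 - TO``, branches cut
either at a fixed height or by a simplified dynamic-hybrid procedure,
with clusters below a minimum size pooled into the reserved label
``"unassigned"`` (reported, never dropped).

The dynamic cut implemented here mimics the goal of adaptive branch
cutting in simplified form: candidate cut heights are scanned and the
one yielding the most clusters of at least the minimum size is kept;
retained clusters must additionally satisfy a core-scatter criterion
(internally tighter than their distances to the rest of the network),
which keeps arbitrary slices of background noise from being reported as
modules.  Exact numerical agreement with any particular external
implementation is not promised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .coexpr import SimilarityMatrix

__all__ = ["ModuleAssignment", "cluster_modules", "module_overlap"]

UNASSIGNED = "unassigned"


@dataclass
class ModuleAssignment:
    """Gene -> module labels for one condition's network.

    Modules are named ``m01, m02, ...`` by descending size, suffixed with
    the source condition (e.g., ``m01_20min``); genes in no retained
    module carry the reserved label ``"unassigned"``.
    """

    labels: pd.Series  # index = genes, values = module names
    condition: str
    min_size: int
    _sizes: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, dtype=object)
        sizes = self.labels[self.labels != UNASSIGNED].value_counts()
        if (sizes < self.min_size).any():
            small = sizes[sizes < self.min_size]
            raise ValueError(f"modules below min_size={self.min_size}: {dict(small)}")
        self._sizes = sizes

    @property
    def genes(self) -> list[str]:
        return list(self.labels.index)

    @property
    def module_names(self) -> list[str]:
        return list(self._sizes.index)

    @property
    def sizes(self) -> pd.Series:
        return self._sizes.copy()

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == UNASSIGNED).sum())

    def to_tsv(self, path: str | Path) -> None:
        self.labels.rename("module").to_csv(path, sep="\t", index_label="gene")


def _name_modules(
    raw: np.ndarray, genes: Sequence[str], min_size: int, condition: str
) -> pd.Series:
    """Relabel raw cluster ids: size filter, then m01.. by descending size.

    Ties in size break by the smallest member label so naming is
    independent of input gene order.
    """
    labels = pd.Series([UNASSIGNED] * len(genes), index=list(genes), dtype=object)
    ids, counts = np.unique(raw, return_counts=True)
    kept = [
        (int(c), min(np.asarray(genes)[raw == i]), int(i))
        for i, c in zip(ids, counts)
        if i >= 0 and c >= min_size
    ]
    kept.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, cid) in enumerate(kept, start=1):
        name = f"m{rank:02d}_{condition}" if condition else f"m{rank:02d}"
        labels.iloc[np.flatnonzero(raw == cid)] = name
    return labels


def cluster_modules(
    to: SimilarityMatrix,
    min_size: int = 50,
    condition: str = "",
    method: str = "dynamic",
    cut_height: float | None = None,
    scatter_tolerance: float = 0.10,
) -> ModuleAssignment:
    """Detect modules by average-linkage clustering on ``1 - TO``.

    Parameters
    ----------
    to
        Topological-overlap similarity matrix.
    min_size
        Minimum genes per retained module; smaller clusters become
        ``"unassigned"``.
    method
        ``"static"`` cuts the dendrogram at a fixed height;
        ``"dynamic"`` (default) picks the cut adaptively and applies the
        core-scatter validity criterion (see module docstring).
    cut_height
        Static cut height as a fraction of the maximum merge height
        (default 0.99); ignored by the dynamic method.
    scatter_tolerance
        Dynamic validity criterion: a cluster is retained only if its
        mean internal TO exceeds ``(1 + tol)`` times the mean TO of its
        members to all other genes, so a retained module must be
        visibly tighter than background (a cluster spanning the whole
        network has no background and is never a module).

    A constant TO matrix yields a single all-gene module with a warning
    rather than an error.
    """
    if to.kind != "topological_overlap":
        raise ValueError("module detection runs on a topological-overlap matrix")
    n = len(to.genes)
    if n < min_size:
        raise ValueError(f"{n} genes cannot host a module of min_size={min_size}")
    if method not in ("static", "dynamic"):
        raise ValueError(f"unknown method {method!r}")
    if cut_height is None:
        cut_height = 0.99
    dis = 1.0 - to.values
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
    if np.ptp(dis[np.triu_indices(n, 1)]) < 1e-12:
        warnings.warn("constant TO matrix: returning a single module")
        raw = np.zeros(n, dtype=int)
        return ModuleAssignment(
            _name_modules(raw, to.genes, min_size, condition), condition, min_size
        )
    link = hierarchy.linkage(squareform(dis, checks=False), method="average")
    if method == "dynamic":
        raw = _adaptive_cut(link, min_size)
        raw = _apply_core_scatter(dis, raw, min_size, scatter_tolerance)
    else:
        height = cut_height * link[:, 2].max()
        raw = hierarchy.fcluster(link, t=height, criterion="distance").astype(int)
    # members of undersized clusters become unclustered (-1)
    ids, counts = np.unique(raw, return_counts=True)
    small = {int(i) for i, c in zip(ids, counts) if c < min_size}
    raw = np.array([-1 if r in small else r for r in raw])
    labels = _name_modules(raw, to.genes, min_size, condition)
    return ModuleAssignment(labels, condition, min_size)


def _adaptive_cut(link: np.ndarray, min_size: int, n_grid: int = 60) -> np.ndarray:
    """Choose the cut height yielding the most clusters of >= min_size genes.

    Candidate heights span the merge-height range; among heights tied on
    the retained-module count, the greatest is kept (coarsest partition
    with that count), then the fewest stray singleton clusters.
    """
    heights = link[:, 2]
    lo, hi = float(heights.min()), float(heights.max())
    best = None
    for frac in np.linspace(1.0, 0.0, n_grid + 1):
        t = lo + frac * (hi - lo)
        raw = hierarchy.fcluster(link, t=t, criterion="distance").astype(int)
        _, counts = np.unique(raw, return_counts=True)
        n_big = int((counts >= min_size).sum())
        n_small = int((counts < min_size).sum())
        score = (n_big, -n_small)
        if best is None or score > best[0]:
            best = (score, raw)
    return best[1]


def _apply_core_scatter(
    dis: np.ndarray, raw: np.ndarray, min_size: int, tol: float
) -> np.ndarray:
    """Demote candidate clusters that are not tighter than background.

    Works on the similarity scale (1 - dissimilarity), which stays
    discriminative when TO values are small and dissimilarities all
    crowd toward 1.  A cluster of >= min_size genes survives only when
    its mean internal similarity exceeds ``(1 + tol)`` times the mean
    similarity of its members to the rest of the network; others —
    including a cluster spanning the whole network, which has no
    background to stand out from — are marked -1.
    """
    ids, counts = np.unique(raw, return_counts=True)
    out = raw.copy()
    for cid, c in zip(ids, counts):
        mask = raw == cid
        if c < min_size:
            continue  # handled by the size filter downstream
        if mask.all():
            out[mask] = -1
            continue
        m = int(mask.sum())
        intra = 1.0 - dis[np.ix_(mask, mask)].sum() / (m * (m - 1))
        background = 1.0 - float(dis[~mask][:, mask].mean())
        if intra <= (1.0 + tol) * background:
            out[mask] = -1
    return out


def dendrogram_newick(to: SimilarityMatrix) -> str:
    """Average-linkage dendrogram of ``1 - TO`` in Newick form, for inspection."""
    dis = 1.0 - to.values
    np.fill_diagonal(dis, 0.0)
    link = hierarchy.linkage(squareform(np.clip(dis, 0, None), checks=False), "average")
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return f"{to.genes[node.id]}:{node.dist:.6g}"
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

    return f"({walk(tree.left)},{walk(tree.right)});"


def module_overlap(
    a: ModuleAssignment, b: ModuleAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate two assignments over one gene universe.

    Returns (contingency table, pairwise Jaccard index), rows = modules
    of ``a``, columns = modules of ``b`` (unassigned pools included in
    the contingency table, excluded from Jaccard).
    """
    if set(a.genes) != set(b.genes):
        raise ValueError("assignments cover different gene universes")
    bl = b.labels.reindex(a.labels.index)
    table = pd.crosstab(a.labels, bl)
    table.index.name = a.condition or "a"
    table.columns.name = b.condition or "b"
    mods_a = a.module_names
    mods_b = b.module_names
    jac = pd.DataFrame(0.0, index=mods_a, columns=mods_b)
    for ma, mb in product(mods_a, mods_b):
        sa, sb = set(a.members(ma)), set(b.members(mb))
        union = len(sa | sb)
        jac.loc[ma, mb] = len(sa & sb) / union if union else 0.0
    return table, jac
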