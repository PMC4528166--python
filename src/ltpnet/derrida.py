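"""Perturbation spreading and Derrida-plot stability characterization.

Two copies of a Boolean network are run in parallel under *identical*
rules: copy B starts a Hamming distance ``H(0)`` away from copy A
(``H(0)`` genes flipped to the opposite value).  After ``tau`` synchronous
steps the new distance ``H(tau)`` tells whether the perturbation was
absorbed (``H(tau) < H(0)``, ordered regime) or amplified
(``H(tau) > H(0)``, chaotic regime).  Averaging over many random rule
sets and initial conditions and plotting mean ``H(tau)`` against ``H(0)``
yields the Derrida plot; the slope at the origin classifies the regime,
with slope 1 (tangent to the diagonal) marking criticality.

Distances are normalized by the number of nodes N throughout the curve
containers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .boolean import DirectedTopology, RuleSet, sample_rules, step_batch

__all__ = [
    "DerridaCurve",
    "AvalancheTrajectory",
    "RegimeCall",
    "hamming",
    "perturb",
    "derrida_map",
    "avalanche",
    "classify_regime",
    "origin_slope",
]


@dataclass(frozen=True)
class DerridaCurve:
    """Averaged H(0) -> H(tau) mapping with sampling metadata.

    ``points`` holds (h0_norm, mean_h_tau_norm, n_samples) triples on the
    normalized [0, 1] scale; ``sems`` the matching Monte-Carlo standard
    errors of the means.
    """

    tau: int
    points: tuple[tuple[float, float, int], ...]
    sems: tuple[float, ...]
    n_rule_sets: int
    n_inits_per_rule_set: int
    seed: int

    def __post_init__(self) -> None:
        h0s = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(h0s, h0s[1:])):
            raise ValueError("h0_norm values must be strictly increasing")
        for h0, mean, _ in self.points:
            if not 0.0 <= mean <= 1.0:
                raise ValueError(f"mean {mean} outside [0, 1]")
            if h0 == 0.0 and mean != 0.0:
                raise ValueError("H(tau) at H(0)=0 must be exactly 0")

    @property
    def h0_norm(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def mean_h_tau_norm(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def to_csv(self, path: str | Path) -> None:
        lines = ["h0_norm,mean_h_tau_norm,n"]
        lines += [f"{h0:.10g},{m:.10g},{n}" for h0, m, n in self.points]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass(frozen=True)
class AvalancheTrajectory:
    """Mean normalized Hamming distance at each step of a perturbation's spread."""

    h0: int
    means: tuple[float, ...]  # index t = 0..t_max, normalized by N
    n_samples: int

    def __post_init__(self) -> None:
        if self.h0 < 1:
            raise ValueError("avalanche requires h0 >= 1")


@dataclass(frozen=True)
class RegimeCall:
    """Origin-slope regime classification of a Derrida curve."""

    slope_at_origin: float
    regime: str  # ordered | critical | chaotic
    epsilon: float
    slope_se: float = float("nan")


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of positions at which two equal-length bit vectors differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def perturb(
    state: np.ndarray, h0: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Flip exactly ``h0`` distinct, uniformly chosen positions of a state."""
    state = np.asarray(state, dtype=np.uint8)
    n = state.shape[-1]
    if not 0 <= h0 <= n:
        raise ValueError(f"h0={h0} outside [0, {n}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = state.copy()
    if h0:
        pos = rng.choice(n, size=h0, replace=False)
        out[pos] ^= 1
    return out


def _resolve_h0_values(
    topology: DirectedTopology, h0_values: Iterable[int] | None
) -> list[int]:
    n = topology.n_nodes
    if h0_values is None:
        vals = list(range(0, n + 1))  # every integer perturbation size
    else:
        vals = sorted(set(int(h) for h in h0_values))
    if not vals:
        raise ValueError("h0_values must be nonempty")
    if vals[0] < 0 or vals[-1] > n:
        raise ValueError(f"h0 values must lie in [0, {n}]")
    return vals


def _paired_distances(
    topology: DirectedTopology,
    h0_values: Sequence[int],
    t_max: int,
    n_rule_sets: int,
    n_inits: int,
    seed: int,
    rules: RuleSet | None,
    record_trajectory: bool,
) -> np.ndarray:
    """Core paired-run protocol.

    Returns an array of per-sample normalized distances with shape
    (n_rule_sets, n_inits, n_h0) when ``record_trajectory`` is False
    (distance at t = t_max only) or (t_max + 1, n_rule_sets, n_inits,
    n_h0) when True.

    Each rule-set index draws one rule set (unless fixed ``rules`` are
    supplied) and ``n_inits`` fresh random initial states; every
    (init, h0) pair draws a fresh flip set.  A and B evolve under the
    same rules.
    """
    n = topology.n_nodes
    root = np.random.default_rng(seed)
    n_h0 = len(h0_values)
    if record_trajectory:
        out = np.empty((t_max + 1, n_rule_sets, n_inits, n_h0))
    else:
        out = np.empty((n_rule_sets, n_inits, n_h0))
    for r in range(n_rule_sets):
        ruleset = rules if rules is not None else sample_rules(topology, seed=root)
        a0 = (root.random((n_inits, n)) < 0.5).astype(np.uint8)
        # one perturbed copy of every init per h0, stacked below the originals
        b0 = np.repeat(a0, n_h0, axis=0).reshape(n_inits, n_h0, n)
        for i in range(n_inits):
            for j, h0 in enumerate(h0_values):
                if h0:
                    pos = root.choice(n, size=h0, replace=False)
                    b0[i, j, pos] ^= 1
        a = a0
        b = b0.reshape(n_inits * n_h0, n)
        if record_trajectory:
            diff = a[:, None, :] != b.reshape(n_inits, n_h0, n)
            out[0, r] = diff.sum(axis=2) / n
        for t in range(1, t_max + 1):
            a = step_batch(topology, ruleset, a)
            b = step_batch(topology, ruleset, b)
            if record_trajectory:
                diff = a[:, None, :] != b.reshape(n_inits, n_h0, n)
                out[t, r] = diff.sum(axis=2) / n
        if not record_trajectory:
            diff = a[:, None, :] != b.reshape(n_inits, n_h0, n)
            out[r] = diff.sum(axis=2) / n
    return out


def derrida_map(
    topology: DirectedTopology,
    tau: int = 1,
    h0_values: Iterable[int] | None = None,
    n_rule_sets: int = 1000,
    n_inits: int = 100,
    seed: int = 0,
    rules: RuleSet | None = None,
) -> DerridaCurve:
    """Monte-Carlo Derrida map of a topology under flat random rules.

    For each of ``n_rule_sets`` random rule sets, ``n_inits`` paired
    simulations are run per perturbation size: trajectory B starts ``h0``
    flips away from A and both evolve ``tau`` steps under the same rules;
    the normalized Hamming distance at ``tau`` is averaged per ``h0``.
    ``h0_values=None`` evaluates every integer size 0..N.  A fixed
    ``rules`` argument replaces rule sampling (useful for exactly
    solvable configurations).
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    vals = _resolve_h0_values(topology, h0_values)
    dist = _paired_distances(
        topology, vals, tau, n_rule_sets, n_inits, seed, rules, record_trajectory=False
    )
    flat = dist.reshape(-1, len(vals))
    means = flat.mean(axis=0)
    # samples sharing a rule set are correlated, so the Monte-Carlo SEM is
    # computed across per-rule-set means (cluster level), not raw samples
    per_rule = dist.mean(axis=1)  # (n_rule_sets, n_h0)
    if n_rule_sets > 1:
        sems = per_rule.std(axis=0, ddof=1) / np.sqrt(n_rule_sets)
    elif flat.shape[0] > 1:
        sems = flat.std(axis=0, ddof=1) / np.sqrt(flat.shape[0])
    else:
        sems = np.zeros(len(vals))
    n = topology.n_nodes
    points = tuple(
        (h0 / n, float(means[j]), flat.shape[0]) for j, h0 in enumerate(vals)
    )
    return DerridaCurve(
        tau=tau,
        points=points,
        sems=tuple(float(s) for s in sems),
        n_rule_sets=n_rule_sets,
        n_inits_per_rule_set=n_inits,
        seed=seed,
    )


def avalanche(
    topology: DirectedTopology,
    h0: int = 1,
    t_max: int = 5,
    n_rule_sets: int = 1000,
    n_inits: int = 100,
    seed: int = 0,
    rules: RuleSet | None = None,
) -> AvalancheTrajectory:
    """Average time evolution of a perturbation of initial size ``h0``.

    Records the mean normalized Hamming distance at every step
    t = 0..t_max of the paired-run protocol; ``means[0]`` equals
    ``h0 / N`` exactly by construction.
    """
    if h0 < 1:
        raise ValueError("avalanche requires h0 >= 1")
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    dist = _paired_distances(
        topology, [h0], t_max, n_rule_sets, n_inits, seed, rules, record_trajectory=True
    )
    means = dist.reshape(t_max + 1, -1).mean(axis=1)
    return AvalancheTrajectory(
        h0=h0,
        means=tuple(float(m) for m in means),
        n_samples=n_rule_sets * n_inits,
    )


def origin_slope(
    curve: DerridaCurve, small_h0_fraction: float = 0.1
) -> tuple[float, float]:
    """Least-squares slope through the origin over the small-H(0) window.

    Uses the smallest ``small_h0_fraction`` of nonzero h0 values (at
    least 2 points).  Returns (slope, standard error) with the SE
    propagated from the per-point Monte-Carlo SEMs.
    """
    nz = [(p, s) for p, s in zip(curve.points, curve.sems) if p[0] > 0]
    if len(nz) < 2:
        raise ValueError("need at least 2 nonzero-h0 points for a slope")
    k = max(2, int(round(small_h0_fraction * len(nz))))
    window = nz[:k]
    x = np.array([p[0] for p, _ in window])
    y = np.array([p[1] for p, _ in window])
    s = np.array([se for _, se in window])
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y) / sxx)
    se = float(np.sqrt(np.sum((x * s) ** 2)) / sxx)
    return slope, se


def origin_secant_slope(curve: DerridaCurve) -> tuple[float, float]:
    """Secant slope at the smallest nonzero perturbation size.

    For a single-flip perturbation the expected distance after one step
    equals the annealed-approximation value exactly (no finite-size
    curvature enters at H(0) = 1), so this secant is the unbiased
    estimator of the origin tangent.  Returns (slope, standard error).
    """
    for (h0, mean, _), sem in zip(curve.points, curve.sems):
        if h0 > 0:
            return mean / h0, sem / h0
    raise ValueError("curve has no nonzero-h0 point")


def classify_regime(
    curve: DerridaCurve,
    small_h0_fraction: float = 0.1,
    epsilon: float = 0.05,
) -> RegimeCall:
    """Classify ordered / critical / chaotic from the origin slope.

    Ordered when slope < 1 - epsilon, chaotic when slope > 1 + epsilon,
    critical in between (the curve hugs the diagonal).
    """
    slope, se = origin_slope(curve, small_h0_fraction)
    if slope < 1.0 - epsilon:
        regime = "ordered"
    elif slope > 1.0 + epsilon:
        regime = "chaotic"
    else:
        regime = "critical"
    return RegimeCall(slope_at_origin=slope, regime=regime, epsilon=epsilon, slope_se=se)


def plot_derrida(curves: dict[str, DerridaCurve], ax=None, shade: bool = True):
    """Derrida plot with the diagonal and ordered/chaotic shading.

    ``curves`` maps legend labels to curves sharing a tau.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    grid = np.linspace(0, 1, 2)
    if shade:
        ax.fill_between(grid, grid, 1.0, color="0.97")       # chaotic half
        ax.fill_between(grid, 0.0, grid, color="0.88")       # ordered half
    ax.plot(grid, grid, "k--", lw=1, label="H(τ) = H(0)")
    for label, curve in curves.items():
        ax.plot(curve.h0_norm, curve.mean_h_tau_norm, marker="o", ms=3, label=label)
    ax.set_xlabel("H(0) / N")
    ax.set_ylabel("mean H(τ) / N")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax
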