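"""Classify the dynamical regime of two architectures with Derrida maps.

Compares a sparse heavy-tailed topology against a dense homogeneous one
(both 35 genes).  For each, pairs of trajectories are run under the
same random rules, the second starting H(0) flips away from the first;
the mean Hamming distance after one step, plotted against H(0), gives
the Derrida map, and its slope at the origin classifies the network as
ordered (slope < 1), critical, or chaotic (slope > 1).
"""

from ltpnet import classify_regime, derrida_map, make_topology
from ltpnet.derrida import origin_secant_slope

sparse = make_topology(35, style="preferential_attachment", seed=1, pa_out=1)
dense = make_topology(35, 140, style="uniform_random", seed=2)

for name, topo in [("sparse heavy-tailed", sparse), ("dense homogeneous", dense)]:
    curve = derrida_map(topo, tau=1, n_rule_sets=300, n_inits=50, seed=3)
    call = classify_regime(curve)
    secant, se = origin_secant_slope(curve)
    mean_k = topo.n_edges / topo.n_nodes
    print(f"{name}: mean in-degree K = {mean_k:.2f}")
    print(f"  origin slope {call.slope_at_origin:.3f} -> {call.regime}"
          f"  (single-flip secant {secant:.3f} +/- {se:.3f})")

print(
    "\nUnder unbiased rules the mean-field origin slope is K/2, so sparse\n"
    "wiring (K < 2) absorbs perturbations while dense wiring (K > 2)\n"
    "amplifies them — the slope read off the curves above shows exactly that."
)
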