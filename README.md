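# ltpnet

Dynamical stability and differential co-expression analysis of temporally
specific gene regulatory networks, built around the genomic response to
long-term potentiation (LTP) — the synaptic strengthening that underlies
long-term memory.  After LTP induction, distinct gene networks are recruited
at different times (minutes to a day); the hypothesis this toolkit serves is
that early, transiently recruited networks have unstable architectures while
the network active a day later is stable, marking a new homeostatic state.

The package is aimed at systems-biology researchers who want to ask the same
two questions of their own (or simulated) networks:

1. **Is a network architecture ordered or chaotic?**  Model each gene as a
   binary variable updated synchronously by a fixed random Boolean function
   of its regulators (a random Boolean network, RBN).  Perturb a trajectory
   by flipping `H(0)` genes and measure the Hamming distance `H(τ)` after τ
   steps, averaged over many rule sets and initial states.  The curve of
   `H(0)` vs `H(τ)` is the *Derrida map*; its slope at the origin classifies
   the regime (slope < 1 ordered, ≈ 1 critical, > 1 chaotic; under unbiased
   rules with mean in-degree K the mean-field slope is `2·K·p(1−p) = K/2`).
   Null ensembles — random same-size networks and degree-preserving rewired
   networks (double-edge swaps: A→B, C→D become A→D, C→B) — separate the
   effects of density, degree sequence, and specific wiring.

2. **How does co-expression rewire across conditions?**  Per condition,
   Pearson correlation between gene pairs is soft-thresholded into an
   adjacency `a_ij = |cor_ij|^p` (default p = 5) and converted to the
   topological overlap `TO_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`,
   a similarity that rewards shared network neighborhoods.  Hierarchical
   clustering on `1 − TO` yields modules (≥ 50 genes); the *modular
   differential connectivity* `MDC = mean TO_later / mean TO_earlier` over a
   module's gene pairs quantifies gain (MDC > 1) or loss (MDC < 1) of
   co-regulation across a transition, with significance from a gene-label
   permutation null and Benjamini–Hochberg FDR.

A fully ground-truthed synthetic-data generator (`ltpnet.synth`) supplies
directed topologies with controlled degree structure and multi-condition
expression matrices with planted modules whose intramodular correlation
rises then falls over the time course — so the entire pipeline is testable
without any external data.

## Worked example

`examples/05_differential_connectivity.py` runs the co-expression track end
to end on the synthetic four-condition time course:

```
selected genes: 728
  control: 2 modules, 606 unassigned
  20min: 9 modules, 195 unassigned
  5h: 6 modules, 259 unassigned
  24h: 3 modules, 561 unassigned

calls per transition (gain / loss / conserved):
call            gain  loss  conserved
transition
control->20min    17     0          3
20min->5h          0    14          6
5h->24h            3    13          4

strongest reconfiguration: m01_20min on control->20min: MDC = 23.27, FDR = 0.004 -> gain
```

Reading: 20 modules were detected across the four conditions and each was
scored on every transition.  Gains dominate the first transition (17 of 20
modules significantly tighten their co-regulation right after stimulation)
while losses accumulate over the later transitions — the planted
rise-then-fall schedule, recovered by the method.  The strongest module
raised its mean intramodular TO 23-fold from control to 20 min.

The stability track reads the same way (`examples/02_derrida_stability.py`):

```
sparse heavy-tailed: mean in-degree K = 0.97
  origin slope 0.480 -> ordered  (single-flip secant 0.481 +/- 0.012)
dense homogeneous: mean in-degree K = 4.00
  origin slope 1.736 -> chaotic  (single-flip secant 1.997 +/- 0.011)
```

The other examples cover attractor detection (`01`), null-ensemble envelopes
(`03`), and module detection with hubs and scale-free diagnostics (`04`).
`ltpnet.derrida.plot_derrida` draws Derrida plots with the diagonal and the
ordered/chaotic shading.

A thin CLI wraps the pipeline for shell use:

```bash
ltpnet simulate-data --seed 1 --outdir data/
ltpnet coexpr --expression data/expression.tsv --samples data/samples.tsv --outdir out/
ltpnet stability my_network.tsv --outdir out/ --seed 1
ltpnet report --coexpr-dir out/ --out summary.md
```

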