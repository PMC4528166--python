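# Methods

## Random Boolean network model

A gene network is a labeled directed graph; an edge j → i means gene j acts
upon gene i.  Gene states are binary (transcriptionally active/inactive),
collected in a state vector G of length N.  Each gene i carries a fixed
Boolean function over its k_i regulators, stored as a truth table of length
2^k_i; all genes update synchronously from the time-(t−1) regulator values,
so the dynamics are deterministic and every trajectory enters a recurring
cycle (attractor).  Asynchronous or stochastic update schemes are out of
scope: the expression data the model abstracts are population averages, for
which a particular asynchronous schedule has no justification.

Rules are sampled from the flat distribution — every truth-table entry an
independent Bernoulli(0.5) draw — because the input topologies carry no
information about interaction logic and the object of study is the
stability conferred by architecture alone.  The bias is exposed as a
parameter (0 < bias < 1) for sensitivity analyses.

**In-degree-0 nodes.**  Real curated networks contain nodes with no
incoming edge.  These receive a 2^0 = 1-entry table: a constant output
drawn from the same Bernoulli law, i.e., the flat rule construction applied
uniformly.  They freeze after one step.

**Truth-table encoding.**  Regulators are ordered by ascending node index;
an input combination is encoded as the integer whose least-significant bit
is the first regulator's value.  The convention is written into the JSON
rule serialization so tables are portable.

**Guards.**  Truth tables are refused above in-degree 20 (2^20 entries)
unless the caller raises the guard explicitly.  Attractor search keeps a
hash of visited states and is exact; it fails loudly if no repeat occurs
within `max_steps` (impossible when max_steps ≥ 2^N).

## Perturbation spreading and Derrida maps

A perturbation experiment runs two trajectories under *identical* rules:
G_B starts H(0) flips (uniformly chosen, without replacement) away from
G_A; both evolve τ steps; the normalized Hamming distance H(τ)/N is
averaged.  Defaults follow the standard protocol at these network sizes:
1000 random rule sets × 100 random initial conditions per rule set, each
(initial condition, H(0)) pair drawing a fresh flip set; initial states are
uniform over {0,1}^N.  Every integer H(0) in 1..N is evaluated by default —
at N ≤ ~40 a full grid is cheap and avoids guessing a sparser design.  τ is
exposed with defaults {1, 5}: τ = 1 probes local motifs, τ = 5 lets
information spread and reflects global structure.

**Monte-Carlo error.**  Samples sharing a rule set are strongly correlated
(a rule set rich in constant functions absorbs everything).  Standard
errors are therefore computed across per-rule-set means, not across raw
samples; raw-sample SEMs understate the error several-fold.

**Origin slope and regime.**  `classify_regime` fits a least-squares slope
through the origin over the smallest 10% of H(0) values (≥ 2 points) and
calls ordered / critical / chaotic with tolerance ε = 0.05 around slope 1.
The windowed slope carries a small, exactly computable finite-size bias: at
H(0) = h the probability that a K-input gene sees a changed input is
hypergeometric, 1 − C(N−K, h)/C(N, h), which is below the linear
extrapolation of the h = 1 value for h ≥ 2 (e.g., expected window slope
0.979 rather than 1.0 for K = 2, N = 20).  Where the mean-field tangent
itself is the quantity of interest, `origin_secant_slope` uses the H(0) = 1
point alone: E[H(1) | h=1] = N · ½ · K/N = K/2 exactly, so the single-flip
secant is an unbiased estimator of the annealed slope 2·K·p(1−p).  The
regime call keeps the windowed definition; ε absorbs the bias at the
default design.

**Avalanches.**  The same paired protocol recorded at every t in 0..t_max,
means[0] = h0/N by construction.  The trajectory perturbs random states by
default; perturbing a state on a detected attractor is available by
composing `find_attractor` with `perturb`, but is not the default because
the curve-level protocol samples initial conditions uniformly.

## Null ensembles

*Random same-size*: same labels and edge count, edges drawn uniformly
without duplicates.  Weak connectivity is not enforced — isolated nodes can
occur, faithful to "connected randomly with equal probability".

*Rewired*: double-edge swaps A→B, C→D → A→D, C→B, rejected if either new
edge exists, if the two replacements coincide, or (by default) if a
self-loop would appear.  Every node's in- and out-degree is conserved
exactly.  The literature leaves the swap count unspecified; the default is
10 × E successful swaps — the common Markov-chain mixing heuristic —
with an attempt budget of 100 × the requested swaps, and an explicit error
reporting progress if the budget is exhausted (e.g., a directed 3-cycle
admits no swap at all).  On 35-node/80-edge graphs this leaves a mean
edge-set Jaccard overlap with the input of ~0.07, i.e., thorough mixing.

Self-loops are excluded from generated nulls by default (absent from
typical curated exports); both generators accept `allow_self_loops=True`.

Ensemble Derrida curves are summarized as pointwise min/max envelopes over
members sharing a τ and H(0) grid.

## Co-expression construction

Gene selection takes the union of the k smallest-p genes per contrast
(default k = 1700), ties broken by stable label order.  Pearson correlation
per condition requires ≥ 3 samples and rejects zero-variance genes and
missing values outright (imputation is upstream's business).  Adjacency is
unsigned, a_ij = |cor_ij|^p with default p = 5 — the original
Zhang–Horvath default for the protocol family; a signed variant
((1+cor)/2)^p sits behind a flag.  Topological overlap uses the standard
matrix form (with zeroed diagonal A: l = A·A, k = row sums,
TO_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), diagonal 1), verified in
the tests against an independent triple-loop implementation.

The scale-free fit index bins connectivities into 10 equal-width bins,
drops empty bins, regresses log10 frequency on log10 mean connectivity,
and reports −sign(slope)·R², so a decaying power law scores +1 and an
increasing density is penalized.  A k-regular (single-bin) degree sequence
is an error, not a silent 0.  `pick_power` implements the scale-free
topology criterion (smallest power with fit ≥ 0.8, falling back to the
best fit); an explicitly given p always wins.

Hubs are ranked by whole-network TO connectivity k_TO with a stable label
tie-break computed on values rounded to 10 decimals, so summation-order
float noise cannot reorder exact ties.

## Module detection

Average-linkage hierarchical clustering on 1 − TO.  Two cut procedures:

* `static`: fixed cut at a configurable fraction of the maximum merge
  height (default 0.99).
* `dynamic` (default): candidate cut heights are scanned over the merge
  range and the height yielding the most clusters of ≥ min_size genes is
  kept (ties resolved toward the higher cut, then fewer stray fragments).
  Retained clusters must additionally pass a core-scatter validity check
  *on the similarity scale*: mean intra-module TO must exceed 1.1 × the
  mean TO of members to the rest of the network.  The similarity scale
  matters because TO dissimilarities crowd toward 1 in weakly correlated
  data, where a dissimilarity-scale margin loses all discrimination.  A
  cluster spanning the whole network has no background to stand out from
  and is never a module (the constant-TO matrix is the exception: it
  returns a single module with a warning rather than an error).

This emulates the adaptive goal of dynamic branch cutting without
reimplementing any particular external package; exact agreement with such
packages is explicitly not promised.  Genes in no retained cluster carry
the reserved label `unassigned` — there is no re-attachment stage, so the
minimum-size filter is exact: members of an undersized cluster are always
unassigned.  min_size defaults to 50.  Modules are named m01, m02, … by
descending size with a condition suffix (`m01_20min`), a palette-free
version of the usual color naming; size ties break on the smallest member
label so naming is independent of gene order.

## Modular differential connectivity

For module M and transition earlier → later,
MDC = mean_{i<j∈M} TO_later / mean_{i<j∈M} TO_earlier (diagonal excluded).
The orientation is fixed later/earlier so MDC > 1 means gained
co-regulation across the transition, the only orientation consistent with
early post-stimulation gains accompanying documented up-regulation; the
orientation is stated in every output.  An earlier-time mean of 0 is a
hard error (undefined ratio).

Significance: the null redraws |M| genes uniformly from the shared universe
n_perm times (gene-label permutation; both matrices fixed) and the
two-sided empirical p on the log scale uses the +1 correction,
p = (1 + #{|log MDC_null| ≥ |log MDC_obs|}) / (n_perm + 1).  Testing on
log MDC makes gain and loss symmetric.  Permuting sample labels instead is
a known alternative but not the default, as label permutation is the direct
reading of the cited procedure.  Within each transition, Benjamini–Hochberg
FDR across modules; calls: gain (MDC > 1, FDR < α), loss (MDC < 1,
FDR < α), conserved otherwise, α = 0.10 by default with 0.01 exposed.

Exact invariants (tested): MDC(A,B,M) · MDC(B,A,M) = 1; scaling the later
matrix restricted to M by c scales MDC by c; identical matrices give
MDC = 1 and p = 1.  Under a 200-replicate global null (i.i.d. Gaussian
expression, fixed module definitions) the FDR-10% call rate measures
~0.02–0.03, within the α + 3·SE bound.

## Synthetic data generator

The generator defines the study conditions for every test.

*Topologies*: `uniform_random` (N, E uniform distinct edges, no
self-loops); `preferential_attachment` — a Barabási–Albert graph with each
edge oriented old → new node, giving heavy-tailed out-degree while keeping
in-degrees at the attachment count (so Boolean truth tables stay small);
`in_degree_sequence` — exact in-degree realization by uniform source
sampling without duplicates (used for the homogeneous-K oracle networks).

*Expression*: Gaussian latent-factor model.  For module m in condition c
with intra-correlation ρ_mc, each sample draws a factor f ~ N(0,1) and each
member gene takes μ_mc + √ρ_mc·f + √(1−ρ_mc)·ε, ε ~ N(0,1); background
genes are pure noise; everything is scaled by noise_sd (default 1) and
shifted by a baseline of 8 to sit on a log2-intensity-like scale.  The
expected intra-module Pearson correlation is exactly ρ_mc, giving
closed-form oracles for the recovery tests.  Gaussianity is a deliberate
simplification: the analysis layer is correlation-based and
distribution-robust.  Per-contrast p-value rankings come from plain
two-sample t-tests of each condition against the first; the moderated
paired test used on real microarrays is upstream of this package and only
the ranking interface matters.  What the generator does **not** emulate:
probe-level artifacts, batch effects, paired-hemisphere structure,
heavy-tailed noise — so passing tests demonstrate method correctness on
the stated statistical structure, not robustness to those real-data
features.

*Time-course scenario* (`paper_like_scenario`): 4 conditions (control,
20 min, 5 h, 24 h), 1200 genes, 20 samples per condition, 14 planted
60-gene modules.  Most modules follow a rise-then-fall correlation
schedule ρ ≈ (0.15, 0.55–0.65, 0.30, 0.18) with accompanying mean shifts
(0, 0.8, 0.4, 0.1); every sixth module is a stable background module at
ρ = 0.45.  Sizes were chosen once to keep the full four-condition run in
seconds while leaving each module comfortably above the 50-gene filter;
the rise-then-fall schedule encodes the qualitative hypothesis the
pipeline should recover (gains dominating the first transition, losses
accumulating later), not any particular numeric outcome.

## Pipeline and reproducibility

`RunConfig` gathers every knob (seed, τ list, sampling sizes, ensemble
size and swap budget, power p, min module size, n_perm, α) and round-trips
through YAML; a content digest is stamped into run manifests.  All
randomness flows through explicit seeds derived from the master seed via
`numpy.random.SeedSequence` (per-stage, per-network via a stable name
hash), so identical configs give bitwise-identical outputs.  The CLI is a
thin layer over `run_stability` / `run_coexpression`; all artifacts are
plain text (TSV/CSV/JSON, Newick for dendrograms).

## Problem sizes

Defaults used by the test suite and the acceptance script: Derrida oracle
networks N = 20 with 1000 rule sets × 100 initial conditions; ensemble
checks on 35-node graphs with 100 members; scale-free contrasts on
2000-node graphs; module recovery on 530 genes; null calibration with 200
replicates of 150 genes × 4 modules at 199 permutations; the time-course
scenario as above with 300 permutations.  These sizes keep every
computation deterministic-seeded and fast on a single CPU while leaving
Monte-Carlo errors small enough for 3-standard-error comparisons.

## Known limitations

* The Boolean layer ignores interaction signs and strengths (the input
  topologies carry none); regime calls characterize architecture, not
  kinetics.
* The dynamic cut is a deliberately simple stand-in for full adaptive
  branch decomposition; on dendrograms with nested module structure it
  will favor the partition level with the most ≥ min_size clusters.
* MDC compares means of TO; modules whose rewiring preserves the mean but
  permutes pair structure are invisible to it.
* The permutation null holds both TO matrices fixed and redraws gene sets,
  so it tests "is this set more rewired than a random same-size set",
  not sampling variability of TO itself.
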