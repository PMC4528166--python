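"""Track module rewiring across a four-condition time course with MDC.

Generates the packaged LTP-style synthetic scenario (control, 20 min,
5 h, 24 h: intra-module correlation rises sharply after stimulation and
then decays), runs the full co-expression track, and reports modular
differential connectivity per transition: MDC > 1 with FDR < 10% is a
significant gain of intramodular co-regulation, MDC < 1 a loss.
"""

from ltpnet import RunConfig, paper_like_scenario, run_coexpression

config = RunConfig(seed=1, n_perm=300, top_k_genes=400)
report = run_coexpression(config, paper_like_scenario(seed=1))

print(f"selected genes: {len(report.selected_genes)}")
for assign in report.assignments:
    print(f"  {assign.condition}: {len(assign.module_names)} modules, "
          f"{assign.n_unassigned} unassigned")

print("\ncalls per transition (gain / loss / conserved):")
print(report.transition_counts.to_string())

strongest = max(report.mdc_results, key=lambda r: abs(r.mdc - 1))
print(f"\nstrongest reconfiguration: {strongest.module} on {strongest.transition}: "
      f"MDC = {strongest.mdc:.2f}, FDR = {strongest.fdr:.3f} -> {strongest.call}")
print(
    "\nGains dominating the first transition and losses accumulating over the\n"
    "later ones reproduce the generator's planted rise-then-fall schedule of\n"
    "intramodular co-regulation."
)
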