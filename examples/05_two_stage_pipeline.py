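"""Full two-stage pipeline: screen on one replicate, test on its pair.

Generates paired replicates sharing one genotype panel, runs the
screening and testing stages with all five methods, and prints the
selection tally (how often each gene was selected at Holm-adjusted
p < 0.1 across pairs).
"""

from snpset import EffectSpec, SimConfig, generate_replicates, run_two_stage

cfg = SimConfig(
    n_samples=400, n_genes=12,
    effects=[EffectSpec("G0003", beta_rare=0.8, beta_common=0.25, gamma_ge=0.4)],
)
pairs = generate_replicates(cfg, n_pairs=4, seed=42)
tally = run_two_stage(pairs, B_screen=200, seed=7)

piv = tally.pivot(index="gene", columns="method", values="times_selected")
piv["screened_in"] = tally.groupby("gene")["times_screened_in"].first()
print(piv)

# The causal gene G0003 should be selected in (nearly) every pair by
# every method; null genes only sporadically. 'screened_in' counts how
# often the gene survived the screening stage (out of 4 pairs).
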