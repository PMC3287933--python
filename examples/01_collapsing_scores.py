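"""Collapse one gene's variants into burden and summary scores.

Builds a small synthetic cohort, picks one gene, and prints the
Madsen-Browning weighted sums (per functional class and combined) and the
common-variant summary score for the first few samples.
"""

import numpy as np

from snpset import SimConfig, collapse_gene
from snpset.simulate import simulate_replicate

rep = simulate_replicate(SimConfig(n_samples=300, n_genes=5), seed=7)
gene = rep.snp_sets[0]
affected = rep.samples["status"].to_numpy() == 1

scores = collapse_gene(rep.genotypes, rep.annotations, affected, gene)

print(f"gene {scores.gene}: {len(gene.variant_ids)} variants")
print(f"Madsen-Browning weights (nonsynonymous rare): "
      f"{np.round(scores.weights_rare.get('nonsynonymous', []), 3)}")
print("first five samples:")
print(f"  WS_syn      {np.round(scores.ws_syn[:5], 3)}")
print(f"  WS_nonsyn   {np.round(scores.ws_nonsyn[:5], 3)}")
print(f"  WS_combined {np.round(scores.ws_combined[:5], 3)}")
if scores.common_score is not None:
    print(f"  common score {np.round(scores.common_score[:5], 4)} "
          f"(coefficients = case/control frequency contrasts "
          f"{np.round(scores.coeffs_common, 4)})")

# WS_combined doubles the nonsynonymous contribution; a sample's common
# score is positive when it carries alleles that are enriched in cases.
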