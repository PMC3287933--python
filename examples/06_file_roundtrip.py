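"""Write a replicate to the on-disk formats and read it back.

Shows the tabular genotype dialect, the sample/annotation tables, and the
preparation steps (MAF, frequency classes, filters, PCs) applied to data
loaded from disk -- the same path the `snpset` CLI uses.
"""

import tempfile
from pathlib import Path

from snpset import (
    SimConfig,
    classify_variant_frequency,
    compute_maf,
    filter_low_burden_genes,
    filter_singleton_variants,
    read_annotations,
    read_genotypes,
    read_samples,
    write_genotypes,
)
from snpset.data_model import add_population_pcs
from snpset.simulate import simulate_replicate

rep = simulate_replicate(SimConfig(n_samples=300, n_genes=6), seed=23)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_genotypes(rep.genotypes, tmp / "geno.tsv")
    rep.samples.to_csv(tmp / "samples.tsv", sep="\t", index=False)
    rep.annotations[["variant_id", "gene", "functional_class", "chrom", "pos"]].to_csv(
        tmp / "ann.tsv", sep="\t", index=False
    )

    geno = read_genotypes(tmp / "geno.tsv")
    samples = read_samples(tmp / "samples.tsv")
    ann, snp_sets = read_annotations(tmp / "ann.tsv")

geno, removed = filter_singleton_variants(geno)
ann = ann[ann["variant_id"].isin(geno.variant_ids)]
ann = classify_variant_frequency(compute_maf(geno, ann))
snp_sets = [s for s in snp_sets]
snp_sets, dropped = filter_low_burden_genes(geno, snp_sets, ann)
samples = add_population_pcs(samples, geno, ann)

print(f"{geno.n_samples} samples x {geno.n_variants} variants "
      f"({len(removed)} singleton/monomorphic variants removed)")
print(f"{(ann['frequency_class'] == 'rare').mean():.0%} rare variants; "
      f"{len(snp_sets)} genes kept ({len(dropped)} below the 1% burden rule)")
print(samples[["sample_id", "status", "pc1", "pc2", "subpopulation"]].head(3))

# pc1/pc2 recover the continental structure of the simulated cohort and
# are the covariates the testing stage uses for stratification control.
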