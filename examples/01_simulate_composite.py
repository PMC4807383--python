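"""Found a second-generation composite and watch drift erode its diversity.

Two parental populations, each fixed for alternate alleles, are crossed; the
generation-2 composite has allele frequency ~0.5 everywhere (near-maximal
gene diversity) and LD only between linked loci.  Ten cycles of random
mating with equal parental contributions (Ne ~ 2N) then shave off a little
heterozygosity: He shrinks by roughly (1 - 1/(2*Ne))^10.
"""

from popdiseq import (
    SimConfig, allele_freqs, assign_effects, found_composite, gene_diversity,
    phenotypes, polymorphic_mask, random_mate,
)

cfg = SimConfig(pop_size=100, seed=42)
arch = assign_effects(cfg)
pop1 = phenotypes(found_composite(cfg, arch), arch)
pop2 = phenotypes(random_mate(pop1, 10), arch)

for name, pop in (("composite (gen 2)", pop1), ("after 10 random-mating cycles", pop2)):
    f = allele_freqs(pop.genotype_matrix("analysis"))
    he = gene_diversity(f)[1]
    print(f"{name}: {polymorphic_mask(f).sum()}/94 SNPs polymorphic, "
          f"mean He = {he:.4f}, expansion volume mean = {pop.y.mean():.1f} mL/g "
          f"(var {pop.y.var(ddof=1):.1f})")
print("He near 0.5 at founding is the maximum for biallelic SNPs; the small drop")
print(f"after 10 cycles matches the drift expectation (1 - 1/(2*{int(pop2.effective_size)}))^10.")
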