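"""Truncation selection leaves a footprint: response, F_ST, frequency shifts.

Four cycles of selecting the top 20% by phenotype raise the genotypic mean
and, through LD with the QTLs, drag SNP frequencies along (hitchhiking) —
visible as elevated F_ST against the base population and more significant
temporal changes than pure drift produces.
"""

from popdiseq import (
    SimConfig, assign_effects, found_composite, fst_pairwise, phenotypes,
    random_mate, select_truncation, temporal_scan,
)

cfg = SimConfig(pop_size=100, seed=42)
arch = assign_effects(cfg)
base = phenotypes(found_composite(cfg, arch), arch)
g0 = base.genotype_matrix("analysis")

sel = base
for cycle in range(4):
    parents = select_truncation(sel, 0.2, "high")
    sel = phenotypes(random_mate(parents, 1, n_offspring=100), arch)
    print(f"cycle {cycle + 1}: mean genotypic value {sel.g.mean():.2f} mL/g "
          f"(base {base.g.mean():.2f})")
drift = random_mate(base, 4)

for name, pop in (("selection", sel), ("drift only", drift)):
    g = pop.genotype_matrix("analysis")
    fst = fst_pairwise(g0, g).mean_fst
    nsig = temporal_scan(g0, g)[1].n_significant
    print(f"{name}: mean Fst vs base = {fst:.4f}, "
          f"SNPs with significant frequency change = {nsig}")
print("Selection shows both a larger Fst and more significant SNP changes than")
print("the drift-only control — the indirect footprint of selecting on the trait.")
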