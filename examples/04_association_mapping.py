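"""Single-marker GWAS on the simulated trait, least-squares and Bayesian.

Expansion volume is controlled by 19 QTLs (2.4% of phenotypic variance each)
plus 81 minor genes at h2 = 0.5.  The ANOVA route flags SNPs by
Benjamini-Hochberg FDR at 5%; the Bayesian route flags SNPs whose 95% HPD
interval for the dosage slope excludes zero (no multiplicity control, so a
few chance flags among 94 SNPs are expected).
"""

import dataclasses

from popdiseq import (
    MCMC_TEST_PROFILE, SimConfig, assign_effects, found_composite, phenotypes, run_gwas,
)

cfg = SimConfig(pop_size=300, seed=42)
arch = assign_effects(cfg)
pop = phenotypes(found_composite(cfg, arch), arch)
df = run_gwas(pop.genotype_matrix("analysis"), pop.phenotype_table(),
              method="both", cfg=dataclasses.replace(MCMC_TEST_PROFILE, seed=42))

hits = df[df["fdr_significant"] | df["hpd_significant"].fillna(False)]
qtl_chroms = sorted({int(c) for c in arch.chromosome[arch.is_qtl]})
print(f"{len(hits)} SNPs flagged out of {int(df['tested'].sum())} tested "
      f"(QTLs sit on chromosomes {qtl_chroms}):")
for _, r in hits.iterrows():
    fdr = f"p={r.p:.4f}" if r.fdr_significant else "ns"
    hpd = f"[{r.hpd_low:.2f}; {r.hpd_high:.2f}]" if r.hpd_significant else "ns"
    print(f"  SNP {r.snp_id:>3} chr{r.chrom} @ {r.position_bp/1e6:7.1f} Mb  FDR {fdr:>10}  HPD {hpd}")
print("Flags cluster on QTL-bearing chromosomes; founding LD reaches tens of Mb,")
print("so a flagged SNP can sit far from the QTL it tags.")
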