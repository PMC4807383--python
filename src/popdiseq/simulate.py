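"""Forward-in-time simulation of a composite maize breeding population.

The engine reproduces a classic quantitative-genetics study design: two
parental populations in linkage equilibrium, each fixed for alternate alleles,
are crossed; random union of F1 gametes yields a second-generation composite
that is in linkage disequilibrium only for linked loci (for a pair with
recombination fraction ``c`` and parental frequency differences ``dA, dB``
the expected gametic disequilibrium at founding is ``(1 - 2c)/4 * dA * dB``).
Further cycles of random mating with enforced equal parental contributions
(effective size roughly twice the census size) then erode that LD as
``D_t = D_0 (1 - c)^t`` while drift slowly removes heterozygosity.

A single trait (expansion volume, mL/g) is controlled by a set of QTLs plus
many minor genes with bidirectional dominance; additive effects are scaled so
each QTL explains a fixed fraction of the founding phenotypic variance and the
two extreme homozygotes span a user-set genotypic range.  The environmental
variance is derived from the broad-sense heritability at founding.

All randomness flows from one integer seed through named substreams
(effects, founding, meiosis, error, sampling), so each stage is reproducible
in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genodata import GenotypeMatrix, PhenotypeTable, SnpMap, load_snp_panel

logger = logging.getLogger(__name__)

#: Approximate physical lengths (bp) of maize chromosomes 1-9.
MAIZE_CHROM_LENGTHS_BP: tuple[int, ...] = (
    301_000_000, 237_000_000, 232_000_000, 242_000_000, 217_000_000,
    169_000_000, 176_000_000, 175_000_000, 157_000_000,
)

_SUBSTREAMS = {"effects": 0, "founding": 1, "meiosis": 2, "error": 3, "sampling": 4}


class SimulationError(ValueError):
    """Invalid simulation configuration or request."""


# ---------------------------------------------------------------------------
# Map function and expected-value propagation
# ---------------------------------------------------------------------------

def haldane_c(distance_bp: np.ndarray | float, cm_per_mb: float = 2.0) -> np.ndarray | float:
    """Recombination fraction from physical distance under the Haldane map.

    Physical distance is converted at a uniform ``cm_per_mb`` rate (default
    2 cM/Mb, a representative genome-wide figure for maize that also matches
    the decay profile this composite design is meant to exhibit: founding
    |D| above 0.10 for loci under 10 Mb apart and below 0.05 beyond 50 Mb).
    c = (1 - exp(-2 d_Morgans)) / 2; monotone in distance, capped at 0.5.
    """
    d_morgans = np.asarray(distance_bp, dtype=float) / 1e6 * cm_per_mb / 100.0
    c = 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
    return c if np.ndim(distance_bp) else float(c)


def expected_founding_d(c: float, delta_a: float = 1.0, delta_b: float = 1.0) -> float:
    """Expected gametic D in the generation-2 composite for one locus pair.

    ``delta_a``/``delta_b`` are the parental allele-frequency differences;
    with parents fixed for alternate alleles (|delta| = 1) unlinked pairs give
    D = 0 and fully linked pairs give D = 0.25.
    """
    return (1.0 - 2.0 * c) / 4.0 * delta_a * delta_b


def expected_d_decay(d0: float, c: float, t: int) -> float:
    """Infinite-population LD recursion: D_t = D_0 (1 - c)^t."""
    return d0 * (1.0 - c) ** t


# ---------------------------------------------------------------------------
# Configuration and architecture
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the composite-population simulation.

    Defaults reproduce the reference design: 1,170 SNPs on nine chromosomes of
    which the packaged 94-SNP simulated panel is analysed, 19 QTLs + 81 minor
    genes with bidirectional dominance (|d/a| <= 1.2), genotypic range 5-50
    mL/g, broad-sense heritability 0.5 with 2.4% of phenotypic variance per
    QTL, and a census size of 100.
    """

    n_chromosomes: int = 9
    chrom_lengths_bp: Sequence[int] = MAIZE_CHROM_LENGTHS_BP
    snp_positions: SnpMap | None = None  # default: packaged simulated panel
    n_snps_total: int = 1170
    analysis_snp_ids: Sequence[str] | None = None  # default: the panel's 94
    n_qtl: int = 19
    n_minor: int = 81
    g_min: float = 5.0
    g_max: float = 50.0
    dominance_range: tuple[float, float] = (-1.2, 1.2)
    h2: float = 0.5
    per_qtl_var_fraction: float = 0.024
    pop_size: int = 100
    n_generations_random_mating: int = 10
    cm_per_mb: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 <= 1.0):
            raise SimulationError("h2 must be in (0, 1]")
        if self.n_qtl * self.per_qtl_var_fraction > self.h2 + 1e-12:
            raise SimulationError("n_qtl * per_qtl_var_fraction exceeds h2")
        if not self.g_min < self.g_max:
            raise SimulationError("g_min must be < g_max")
        if self.pop_size < 2:
            raise SimulationError("pop_size must be >= 2")
        if len(self.chrom_lengths_bp) != self.n_chromosomes:
            raise SimulationError("chrom_lengths_bp length != n_chromosomes")

    def rng(self, substream: str, extra: int = 0) -> np.random.Generator:
        key = _SUBSTREAMS[substream]
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key, extra))
        )

    def panel(self) -> SnpMap:
        return self.snp_positions if self.snp_positions is not None else load_snp_panel("simulated")


@dataclass
class TraitArchitecture:
    """Causal loci (QTLs + minor genes) and their additive/dominance effects.

    ``a`` is half the difference between homozygotes, ``d`` the heterozygote
    deviation, both in trait units; genotype values at one locus are -a, d,
    +a for dosages 0, 1, 2.  ``mu`` centres the genotypic scale so the two
    extreme multilocus homozygotes sit at g_min and g_max.
    """

    chromosome: np.ndarray
    position_bp: np.ndarray
    a: np.ndarray
    d: np.ndarray
    is_qtl: np.ndarray
    mu: float
    ve: float
    vg_expected: float  # genotypic variance at p = 0.5, HWE, linkage equilibrium
    h2: float
    per_qtl_var_fraction: float
    locus_id: list[str] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.a)

    def qtl_variance_fractions(self) -> np.ndarray:
        """Per-QTL fraction of expected phenotypic variance at p = 0.5."""
        v = self.a**2 / 2.0 + self.d**2 / 4.0
        vp = self.vg_expected + self.ve
        return v[self.is_qtl] / vp

    def genotypic_values(self, dosages: np.ndarray) -> np.ndarray:
        """Map causal-locus dosages (n x n_loci) to genotypic values."""
        # per-locus value: dosage 0 -> -a, 1 -> d, 2 -> +a
        contrib = np.where(
            dosages == 1, self.d[None, :], (dosages.astype(float) - 1.0) * self.a[None, :]
        )
        return self.mu + contrib.sum(axis=1)


def assign_effects(config: SimConfig, rng_seed: int | None = None) -> TraitArchitecture:
    """Draw causal-locus positions and effects for the configured trait.

    Positions are uniform over the chromosomes (probability proportional to
    physical length), re-drawn on collision with an analysis SNP.  Dominance
    ratios d/a are uniform on ``dominance_range``.  QTL additive effects are
    scaled so each QTL explains ``per_qtl_var_fraction`` of the phenotypic
    variance expected at allele frequency 0.5 (Va = a^2/2, Vd = (d/2)^2);
    minor-gene effects are scaled jointly so total expected genotypic variance
    is ``h2 * Vp``; finally all effects are rescaled linearly (and the
    intercept set) so the extreme homozygotes hit g_min / g_max.  The linear
    rescale multiplies every variance component by the same factor, so the
    variance fractions and heritability are preserved exactly.
    """
    rng = config.rng("effects") if rng_seed is None else np.random.default_rng(rng_seed)
    n_loci = config.n_qtl + config.n_minor
    minor_total = config.h2 - config.n_qtl * config.per_qtl_var_fraction
    if minor_total < -1e-12:
        raise SimulationError("per-QTL variance fractions exceed h2")
    if config.n_minor == 0 and minor_total > 1e-9:
        raise SimulationError("no minor genes to absorb residual genetic variance")

    lengths = np.asarray(config.chrom_lengths_bp, dtype=float)
    probs = lengths / lengths.sum()
    panel = config.panel()
    taken = {(int(c), int(p)) for c, p in zip(panel.chromosome, panel.position_bp)}
    chroms = np.empty(n_loci, dtype=np.int64)
    positions = np.empty(n_loci, dtype=np.int64)
    for j in range(n_loci):
        while True:
            c = int(rng.choice(config.n_chromosomes, p=probs)) + 1
            pos = int(rng.integers(1, config.chrom_lengths_bp[c - 1] + 1))
            if (c, pos) not in taken:
                taken.add((c, pos))
                break
        chroms[j], positions[j] = c, pos

    lo, hi = config.dominance_range
    ratios = rng.uniform(lo, hi, size=n_loci)
    is_qtl = np.zeros(n_loci, dtype=bool)
    is_qtl[: config.n_qtl] = True

    # Work in units where Vp = 1, then rescale to the genotypic range.
    a = np.empty(n_loci)
    per_locus_var = lambda a_, r_: a_**2 * (0.5 + r_**2 / 4.0)
    a[is_qtl] = np.sqrt(config.per_qtl_var_fraction / (0.5 + ratios[is_qtl] ** 2 / 4.0))
    raw = rng.uniform(0.1, 1.0, size=config.n_minor)
    if config.n_minor:
        scale = np.sqrt(max(minor_total, 0.0) / per_locus_var(raw, ratios[~is_qtl]).sum())
        a[~is_qtl] = raw * scale
    d = ratios * a

    half_range = (config.g_max - config.g_min) / 2.0
    k = half_range / a.sum()
    a, d = a * k, d * k
    mu = (config.g_min + config.g_max) / 2.0
    vg = float((a**2 / 2.0 + d**2 / 4.0).sum())
    ve = vg * (1.0 - config.h2) / config.h2
    ids = [f"QTL{j + 1}" for j in range(config.n_qtl)] + [
        f"MG{j + 1}" for j in range(config.n_minor)
    ]
    logger.info(
        "architecture: %d loci, Vg(p=0.5)=%.3f, Ve=%.3f, per-QTL fraction=%.4f",
        n_loci, vg, ve, config.per_qtl_var_fraction,
    )
    return TraitArchitecture(
        chromosome=chroms, position_bp=positions, a=a, d=d, is_qtl=is_qtl,
        mu=mu, ve=ve, vg_expected=vg, h2=config.h2,
        per_qtl_var_fraction=config.per_qtl_var_fraction, locus_id=ids,
    )


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass
class _Genome:
    """Sorted layout of every simulated locus plus recombination fractions."""

    map: SnpMap                      # all loci, sorted by (chromosome, position)
    chrom_slices: list[slice]        # per-chromosome column ranges
    interval_c: list[np.ndarray]     # adjacent-locus recombination fractions
    analysis_idx: np.ndarray         # columns of the analysis SNPs
    snp_idx: np.ndarray              # columns of all grid SNPs
    causal_idx: np.ndarray           # columns of causal loci, in architecture order


def _build_genome(config: SimConfig, arch: TraitArchitecture | None) -> _Genome:
    panel = config.panel()
    per_chrom = np.full(config.n_chromosomes, config.n_snps_total // config.n_chromosomes)
    per_chrom[: config.n_snps_total % config.n_chromosomes] += 1

    ids: list[str] = []
    chroms: list[int] = []
    positions: list[int] = []
    kinds: list[str] = []
    for c in range(1, config.n_chromosomes + 1):
        on_c = [i for i, ch in enumerate(panel.chromosome) if int(ch) == c]
        pos_c = [int(panel.position_bp[i]) for i in on_c]
        used = set(pos_c)
        n_fill = max(0, per_chrom[c - 1] - len(on_c))
        fillers = []
        grid = np.linspace(1, config.chrom_lengths_bp[c - 1], num=n_fill + 2, dtype=np.int64)[1:-1]
        for p in grid:
            p = int(p)
            while p in used:
                p += 1
            used.add(p)
            fillers.append(p)
        for i in on_c:
            ids.append(panel.snp_id[i]); chroms.append(c)
            positions.append(int(panel.position_bp[i])); kinds.append("analysis")
        for k, p in enumerate(fillers):
            ids.append(f"chr{c}_grid{k + 1}"); chroms.append(c)
            positions.append(p); kinds.append("grid")
    if arch is not None:
        for j in range(arch.n_loci):
            ids.append(arch.locus_id[j]); chroms.append(int(arch.chromosome[j]))
            positions.append(int(arch.position_bp[j])); kinds.append("causal")

    order = np.lexsort((np.asarray(positions), np.asarray(chroms)))
    ids = [ids[i] for i in order]
    chroms_arr = np.asarray(chroms)[order]
    pos_arr = np.asarray(positions, dtype=np.int64)[order]
    kinds_arr = np.asarray(kinds)[order]
    full_map = SnpMap(ids, list(chroms_arr), pos_arr)
    full_map.metadata["kind"] = kinds_arr

    chrom_slices, interval_c = [], []
    start = 0
    for c in range(1, config.n_chromosomes + 1):
        n_c = int((chroms_arr == c).sum())
        sl = slice(start, start + n_c)
        chrom_slices.append(sl)
        gaps = np.diff(pos_arr[sl])
        interval_c.append(np.asarray(haldane_c(gaps, config.cm_per_mb), dtype=float))
        start += n_c

    analysis_ids = (
        list(config.analysis_snp_ids) if config.analysis_snp_ids is not None else panel.snp_id
    )
    analysis_idx = full_map.index_of(analysis_ids)
    snp_idx = np.flatnonzero(kinds_arr != "causal")
    causal_idx = (
        full_map.index_of(arch.locus_id) if arch is not None else np.empty(0, dtype=np.intp)
    )
    return _Genome(full_map, chrom_slices, interval_c, analysis_idx, snp_idx, causal_idx)


# ---------------------------------------------------------------------------
# Population container
# ---------------------------------------------------------------------------

@dataclass
class SimPopulation:
    """A diploid population: haplotypes over every simulated locus.

    ``haplotypes`` has shape (n, 2, n_loci) with 0/1 alternate-allele codes.
    Genotypic values ``g`` and phenotypes ``y`` are attached by
    :func:`phenotypes`.
    """

    haplotypes: np.ndarray
    genome: _Genome
    config: SimConfig
    generation: int = 2
    effective_size: float | None = None
    g: np.ndarray | None = None
    y: np.ndarray | None = None
    _meiosis_rng: np.random.Generator | None = None

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self, columns: np.ndarray | None = None) -> np.ndarray:
        d = self.haplotypes.sum(axis=1, dtype=np.int8)
        return d if columns is None else d[:, columns]

    def genotype_matrix(self, subset: str = "analysis") -> GenotypeMatrix:
        """Genotypes as a :class:`GenotypeMatrix` over ``analysis``/``snps``/``all`` loci."""
        cols = {
            "analysis": self.genome.analysis_idx,
            "snps": self.genome.snp_idx,
            "all": np.arange(self.haplotypes.shape[2]),
        }[subset]
        ids = [f"ind{i + 1}" for i in range(self.n_individuals)]
        return GenotypeMatrix(ids, self.dosages(cols), self.genome.map.subset(cols))

    def phenotype_table(self, trait: str = "expansion_volume") -> PhenotypeTable:
        if self.y is None:
            raise SimulationError("phenotypes not attached; call phenotypes() first")
        ids = [f"ind{i + 1}" for i in range(self.n_individuals)]
        return PhenotypeTable(ids, self.y, trait=trait)

    def gametic_d(self, col_i: int, col_j: int) -> float:
        """Realized gametic disequilibrium from the (known) haplotypes."""
        h = self.haplotypes.reshape(-1, self.haplotypes.shape[2])
        pa, pb = h[:, col_i].mean(), h[:, col_j].mean()
        pab = (h[:, col_i] * h[:, col_j]).mean()
        return float(pab - pa * pb)


def _strand_patterns(genome: _Genome, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """0/1 parental-strand indicator per gamete and locus (Haldane, Markov)."""
    n_loci = len(genome.map)
    s = np.empty((n_gametes, n_loci), dtype=np.int8)
    for sl, c in zip(genome.chrom_slices, genome.interval_c):
        n_c = sl.stop - sl.start
        start = rng.integers(0, 2, size=(n_gametes, 1), dtype=np.int8)
        if n_c > 1:
            switches = (rng.random((n_gametes, n_c - 1)) < c[None, :]).astype(np.int8)
            block = np.concatenate([start, switches], axis=1)
            s[:, sl] = np.cumsum(block, axis=1, dtype=np.int32) & 1
        else:
            s[:, sl] = start
    return s


def found_composite(config: SimConfig, arch: TraitArchitecture | None = None) -> SimPopulation:
    """Found the second-generation composite of two linkage-equilibrium parents.

    Each parental population is fixed for one allele per locus (which parent
    carries the alternate allele is random per locus), so the composite allele
    frequency is 0.5 in expectation at every locus and LD exists only between
    linked loci.  The F1 is heterozygous everywhere; random union of F1
    gametes with recombination produces ``pop_size`` generation-2 individuals.
    """
    genome = _build_genome(config, arch)
    rng_found = config.rng("founding")
    orientation = rng_found.integers(0, 2, size=len(genome.map), dtype=np.int8)
    rng_meiosis = config.rng("meiosis")
    n = config.pop_size
    strands = _strand_patterns(genome, 2 * n, rng_meiosis)
    gametes = orientation[None, :] ^ strands
    haps = gametes.reshape(n, 2, -1)
    logger.info("founded composite: N=%d, %d loci", n, len(genome.map))
    return SimPopulation(
        haplotypes=haps, genome=genome, config=config, generation=2,
        effective_size=float(n), _meiosis_rng=rng_meiosis,
    )


def random_mate(
    pop: SimPopulation,
    generations: int,
    equal_contributions: bool = True,
    n_offspring: int | None = None,
) -> SimPopulation:
    """Advance the population by cycles of random crosses.

    With ``equal_contributions`` every parent transmits (as nearly as
    possible) the same number of gametes — exactly two when the offspring
    count equals the parent count — which doubles the effective size relative
    to the census size (N = 100 -> Ne ~ 200; N = 300 -> Ne ~ 600).  When the
    gamete pool is not an exact multiple of the parent count, parents are
    cycled so contributions differ by at most one.  Without
    ``equal_contributions``, parents are drawn with replacement and Ne ~ N.
    ``n_offspring`` lets a reduced parent set (e.g. after truncation
    selection) regenerate a larger population.  ``generations=0`` returns an
    identical copy.
    """
    if generations < 0:
        raise SimulationError("generations must be >= 0")
    rng = pop._meiosis_rng if pop._meiosis_rng is not None else pop.config.rng("meiosis", 1)
    haps = pop.haplotypes
    for _ in range(generations):
        k = haps.shape[0]
        n = n_offspring if n_offspring is not None else k
        if n < 1 or k < 2:
            raise SimulationError("need >= 2 parents and >= 1 offspring")
        if equal_contributions:
            reps = -(-2 * n // k)  # ceil: contributions differ by at most one
            parents = np.tile(np.arange(k), reps)[: 2 * n]
            rng.shuffle(parents)
        else:
            parents = rng.integers(0, k, size=2 * n)
        strands = _strand_patterns(pop.genome, 2 * n, rng)
        rows = np.arange(2 * n)[:, None]
        gametes = haps[parents][rows, strands, np.arange(haps.shape[2])[None, :]]
        haps = gametes.reshape(n, 2, -1)
    final_n = haps.shape[0]
    ne = (2.0 * final_n if equal_contributions else float(final_n)) \
        if generations > 0 else pop.effective_size
    return SimPopulation(
        haplotypes=haps, genome=pop.genome, config=pop.config,
        generation=pop.generation + generations, effective_size=ne, _meiosis_rng=rng,
    )


def phenotypes(
    pop: SimPopulation,
    arch: TraitArchitecture,
    h2: float | None = None,
    rng_seed: int | None = None,
) -> SimPopulation:
    """Attach genotypic values and phenotypes: y = g + e, e ~ N(0, Ve).

    Ve = Vg (1 - h2) / h2 with Vg the genotypic variance expected at founding
    (all causal loci at frequency 0.5, Hardy-Weinberg, linkage equilibrium).
    ``h2=1`` gives y = g exactly; ``h2=0`` is an error.
    """
    h2 = arch.h2 if h2 is None else h2
    if h2 <= 0.0:
        raise SimulationError("h2 = 0 leaves the error variance undefined")
    if pop.genome.causal_idx.size == 0:
        raise SimulationError("population was founded without causal loci")
    rng = pop.config.rng("error") if rng_seed is None else np.random.default_rng(rng_seed)
    dos = pop.dosages(pop.genome.causal_idx)
    g = arch.genotypic_values(dos)
    ve = arch.vg_expected * (1.0 - h2) / h2
    e = rng.normal(0.0, np.sqrt(ve), size=g.shape) if ve > 0 else np.zeros_like(g)
    out = replace(pop, g=g, y=g + e)
    return out


def select_truncation(
    pop: SimPopulation, proportion: float, direction: str = "high"
) -> SimPopulation:
    """Keep the top (or bottom) phenotypic fraction as parents of the next cycle.

    A simplified stand-in for progeny-based recurrent selection schemes:
    truncation on the individual phenotype is enough to drive a response and
    the LD/allele-frequency side effects of selection.
    """
    if not (0.0 < proportion <= 1.0):
        raise SimulationError("proportion must be in (0, 1]")
    if pop.y is None:
        raise SimulationError("phenotypes required before selection")
    if direction not in ("high", "low"):
        raise SimulationError("direction must be 'high' or 'low'")
    k = int(round(proportion * pop.n_individuals))
    if k < 2:
        raise SimulationError("selected proportion yields fewer than 2 parents")
    order = np.argsort(pop.y)
    keep = order[-k:] if direction == "high" else order[:k]
    return replace(
        pop,
        haplotypes=pop.haplotypes[keep],
        g=None if pop.g is None else pop.g[keep],
        y=pop.y[keep],
    )


def sample_individuals(pop: SimPopulation, n: int, rng_seed: int | None = None) -> SimPopulation:
    """Uniform sample of ``n`` individuals without replacement."""
    if n > pop.n_individuals:
        raise SimulationError(f"cannot sample {n} from {pop.n_individuals} individuals")
    rng = pop.config.rng("sampling") if rng_seed is None else np.random.default_rng(rng_seed)
    keep = rng.choice(pop.n_individuals, size=n, replace=False)
    return replace(
        pop,
        haplotypes=pop.haplotypes[keep],
        g=None if pop.g is None else pop.g[keep],
        y=None if pop.y is None else pop.y[keep],
    )
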