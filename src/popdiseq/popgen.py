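"""Allele frequencies, diversity, Hardy-Weinberg tests, LD and F_ST.

The LD chain follows the classical two-locus treatment for unphased diploid
data: maximum-likelihood haplotype frequencies under random union of gametes
are obtained with the EM algorithm (the only phase ambiguity is the double
heterozygote), and the pairwise measures are

    D  = p_AB p_ab - p_Ab p_aB
    D' = |D| / D_max,  D_max = min(p_A p_b, p_a p_B) if D > 0
                              else min(p_A p_B, p_a p_b)
    r2 = D^2 / (p_A p_a p_B p_b)

Analyses gate SNPs on polymorphism (maf >= 1%) and Hardy-Weinberg
equilibrium (1-df chi-square, alpha = 0.05), under which the EM estimate is
the MLE.  F_ST is the Nei-style (H_T - H_S) / H_T with unweighted population
means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 1000


class PopgenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Single-locus statistics
# ---------------------------------------------------------------------------

@dataclass
class AlleleFreqs:
    snp_id: list[str]
    p: np.ndarray        # alternate-allele frequency
    maf: np.ndarray
    n_called: np.ndarray

    def __len__(self) -> int:
        return len(self.p)


def allele_freqs(g: GenotypeMatrix) -> AlleleFreqs:
    """Alternate-allele frequency per SNP, missing calls excluded."""
    called = g.dosages != MISSING
    n_called = called.sum(axis=0)
    if np.any(n_called == 0):
        j = int(np.argmin(n_called))
        raise PopgenError(f"SNP {g.map.snp_id[j]!r} has no called genotypes")
    dose = np.where(called, g.dosages, 0).astype(float)
    p = dose.sum(axis=0) / (2.0 * n_called)
    return AlleleFreqs(list(g.map.snp_id), p, np.minimum(p, 1.0 - p), n_called)


def polymorphic_mask(f: AlleleFreqs, threshold: float = 0.01) -> np.ndarray:
    """True where maf >= threshold (a SNP with maf < 1% counts as non-polymorphic;
    the boundary value is kept)."""
    return f.maf >= threshold


def gene_diversity(f: AlleleFreqs) -> tuple[np.ndarray, float]:
    """Expected heterozygosity He = 2p(1-p) per SNP and its mean."""
    he = 2.0 * f.p * (1.0 - f.p)
    return he, float(he.mean())


@dataclass
class HweResult:
    snp_id: list[str]
    n0: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    chi2: np.ndarray
    p_value: np.ndarray
    in_equilibrium: np.ndarray  # p >= alpha (untestable SNPs -> False)
    testable: np.ndarray
    alpha: float


def hwe_test(counts, alpha: float = 0.05) -> HweResult:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    ``counts`` is one (n0, n1, n2) triple or three parallel arrays.  Expected
    counts are (n q^2, 2 n p q, n p^2) with p estimated from the sample; no
    continuity correction.  Monomorphic SNPs are flagged untestable and take
    no part in HWE-gated analyses.
    """
    n0, n1, n2 = (np.atleast_1d(np.asarray(c, dtype=float)) for c in counts)
    n = n0 + n1 + n2
    if np.any(n < 1):
        raise PopgenError("HWE test requires at least one genotype")
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    testable = (p > 0) & (p < 1)
    exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(testable, ((obs - exp) ** 2 / np.where(exp > 0, exp, 1.0)).sum(axis=0), 0.0)
    pval = np.where(testable, stats.chi2.sf(chi2, df=1), 1.0)
    ids = [f"snp{i}" for i in range(len(p))]
    return HweResult(ids, n0, n1, n2, chi2, pval, testable & (pval >= alpha), testable, alpha)


def hwe_test_matrix(g: GenotypeMatrix, alpha: float = 0.05) -> HweResult:
    counts = [(g.dosages == k).sum(axis=0) for k in (0, 1, 2)]
    res = hwe_test(counts, alpha=alpha)
    res.snp_id = list(g.map.snp_id)
    return res


# ---------------------------------------------------------------------------
# Two-locus EM haplotype estimation
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeFreqs:
    """EM haplotype frequencies for one ordered SNP pair (A/a x B/b)."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    em_iterations: int
    em_loglik: float
    converged: bool = True
    phase_uninformative: bool = False

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB


def _em_batch(c: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """Vectorized two-locus EM.

    ``c`` holds the 3x3 genotype tables, shape (P, 3, 3): c[p, i, j] is the
    number of individuals with dosage i at the first SNP and j at the second.
    Returns haplotype frequencies (P, 4) ordered (AB, Ab, aB, ab), iteration
    counts, final log-likelihoods, convergence and ridge flags.
    """
    c = np.asarray(c, dtype=float)
    n = c.sum(axis=(1, 2))
    if np.any(n == 0):
        raise PopgenError("empty genotype table")
    # phase-known haplotype counts
    kAB = 2 * c[:, 2, 2] + c[:, 2, 1] + c[:, 1, 2]
    kAb = 2 * c[:, 2, 0] + c[:, 2, 1] + c[:, 1, 0]
    kaB = 2 * c[:, 0, 2] + c[:, 1, 2] + c[:, 0, 1]
    kab = 2 * c[:, 0, 0] + c[:, 1, 0] + c[:, 0, 1]
    ndh = c[:, 1, 1]  # double heterozygotes: AB/ab or Ab/aB
    h = np.full((len(n), 4), 0.25)
    iters = np.zeros(len(n), dtype=int)
    active = np.ones(len(n), dtype=bool)
    for it in range(1, max_iter + 1):
        prod_cis = h[:, 0] * h[:, 3]
        prod_trans = h[:, 1] * h[:, 2]
        denom = prod_cis + prod_trans
        t = np.where(denom > 0, prod_cis / np.where(denom > 0, denom, 1.0), 0.5)
        new = np.column_stack([
            kAB + t * ndh,
            kAb + (1 - t) * ndh,
            kaB + (1 - t) * ndh,
            kab + t * ndh,
        ]) / (2 * n)[:, None]
        delta = np.abs(new - h).max(axis=1)
        h = np.where(active[:, None], new, h)
        iters[active] = it
        active = active & (delta >= tol)
        if not active.any():
            break
    loglik = _loglik_batch(c, h)
    ridge = ndh == n  # every individual a double heterozygote: flat in phase
    return h, iters, loglik, ~active, ridge


def _loglik_batch(c: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood of 3x3 genotype tables given haplotype freqs."""
    pAB, pAb, paB, pab = h[:, 0], h[:, 1], h[:, 2], h[:, 3]
    probs = np.empty(c.shape)
    probs[:, 0, 0] = pab**2
    probs[:, 0, 1] = 2 * paB * pab
    probs[:, 0, 2] = paB**2
    probs[:, 1, 0] = 2 * pAb * pab
    probs[:, 1, 1] = 2 * (pAB * pab + pAb * paB)
    probs[:, 1, 2] = 2 * pAB * paB
    probs[:, 2, 0] = pAb**2
    probs[:, 2, 1] = 2 * pAB * pAb
    probs[:, 2, 2] = pAB**2
    with np.errstate(divide="ignore"):
        logp = np.where(c > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return (c * logp).sum(axis=(1, 2))


def genotype_loglik(table: np.ndarray, haps) -> float:
    """Log-likelihood of one 3x3 table at given (AB, Ab, aB, ab) frequencies."""
    return float(_loglik_batch(np.asarray(table, float)[None], np.asarray(haps, float)[None])[0])


def em_step(table: np.ndarray, haps) -> np.ndarray:
    """One EM update of (AB, Ab, aB, ab) frequencies for a single 3x3 table."""
    c = np.asarray(table, dtype=float)
    h = np.asarray(haps, dtype=float)
    n = c.sum()
    kAB = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    kAb = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    kaB = 2 * c[0, 2] + c[1, 2] + c[0, 1]
    kab = 2 * c[0, 0] + c[1, 0] + c[0, 1]
    ndh = c[1, 1]
    denom = h[0] * h[3] + h[1] * h[2]
    t = h[0] * h[3] / denom if denom > 0 else 0.5
    return np.array([kAB + t * ndh, kAb + (1 - t) * ndh,
                     kaB + (1 - t) * ndh, kab + t * ndh]) / (2 * n)


def em_haplotype_freqs(table: np.ndarray) -> HaplotypeFreqs:
    """ML haplotype frequencies for one unphased SNP pair (3x3 dosage table).

    Converges when the largest frequency change drops below 1e-8 (at most
    1,000 iterations; non-convergence is flagged, not raised).  The
    log-likelihood is non-decreasing across EM iterations.  When every
    individual is a double heterozygote the likelihood is flat in the phase
    split; the uninformative start then returns 0.25 everywhere and the
    ``phase_uninformative`` flag is set.
    """
    h, iters, ll, conv, ridge = _em_batch(np.asarray(table, dtype=float)[None])
    if not conv[0]:
        logger.warning("EM did not converge in %d iterations", EM_MAX_ITER)
    return HaplotypeFreqs(
        p_AB=float(h[0, 0]), p_Ab=float(h[0, 1]), p_aB=float(h[0, 2]), p_ab=float(h[0, 3]),
        em_iterations=int(iters[0]), em_loglik=float(ll[0]),
        converged=bool(conv[0]), phase_uninformative=bool(ridge[0]),
    )


# ---------------------------------------------------------------------------
# LD measures
# ---------------------------------------------------------------------------

@dataclass
class LDPair:
    snp_i: str
    snp_j: str
    D: float
    Dprime: float
    r2: float
    D_max: float
    distance_bp: float | None = None
    same_chromosome: bool = False


def _ld_from_freqs(pAB, pAb, paB, pab):
    """Vectorized D / D' / r2 from haplotype frequencies (arrays)."""
    pA = pAB + pAb
    pB = pAB + paB
    pa, pb = 1.0 - pA, 1.0 - pB
    D = pAB * pab - pAb * paB
    dmax_pos = np.minimum(pA * pb, pa * pB)
    dmax_neg = np.minimum(pA * pB, pa * pb)
    D_max = np.where(D > 0, dmax_pos, dmax_neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = np.where(D == 0, 0.0, np.abs(D) / D_max)
        r2 = np.where(D == 0, 0.0, D**2 / (pA * pa * pB * pb))
    return D, dprime, r2, D_max


def ld_from_haplotypes(h: HaplotypeFreqs) -> LDPair:
    """D, D' (reported unsigned, |D|/D_max) and r2 for one SNP pair."""
    for name, v in (("p_A", h.p_A), ("p_B", h.p_B)):
        if not (0.0 < v < 1.0):
            raise PopgenError(f"monomorphic locus in pair ({name} = {v})")
    D, dprime, r2, dmax = _ld_from_freqs(*(np.asarray([x]) for x in (h.p_AB, h.p_Ab, h.p_aB, h.p_ab)))
    return LDPair("A", "B", float(D[0]), float(dprime[0]), float(r2[0]), float(dmax[0]))


@dataclass
class GateReport:
    """Attrition bookkeeping for the maf/HWE gate (Ng / Np / Ne)."""

    n_individuals: int
    n_snps: int
    n_polymorphic: int
    n_hwe: int
    gated_snp_ids: list[str]


def snp_gate(
    g: GenotypeMatrix, maf_threshold: float = 0.01, hwe_alpha: float = 0.05
) -> tuple[np.ndarray, GateReport]:
    """Boolean mask of SNPs that are polymorphic and in Hardy-Weinberg equilibrium."""
    f = allele_freqs(g)
    poly = polymorphic_mask(f, maf_threshold)
    hwe = hwe_test_matrix(g, alpha=hwe_alpha)
    mask = poly & hwe.in_equilibrium
    report = GateReport(
        n_individuals=g.n_individuals,
        n_snps=g.n_snps,
        n_polymorphic=int(poly.sum()),
        n_hwe=int(mask.sum()),
        gated_snp_ids=[s for s, m in zip(g.map.snp_id, mask) if m],
    )
    logger.info(
        "gate: Ng=%d, SNPs=%d, Np=%d, Ne=%d",
        report.n_individuals, report.n_snps, report.n_polymorphic, report.n_hwe,
    )
    return mask, report


def _pair_tables(dosages: np.ndarray) -> np.ndarray:
    """3x3 genotype tables for every SNP pair via one-hot matrix products.

    Returns shape (m, m, 3, 3); entry [j, k, a, b] counts individuals with
    dosage a at SNP j and b at SNP k (missing at either excluded).
    """
    ind = [(dosages == a).astype(float) for a in (0, 1, 2)]
    m = dosages.shape[1]
    tables = np.empty((m, m, 3, 3))
    for a in range(3):
        for b in range(3):
            tables[:, :, a, b] = ind[a].T @ ind[b]
    return tables


def ld_all_pairs(
    g: GenotypeMatrix,
    maf_threshold: float = 0.01,
    hwe_alpha: float = 0.05,
    apply_gate: bool = True,
) -> tuple[pd.DataFrame, GateReport]:
    """EM-based D / D' / r2 for every unordered pair of gated SNPs.

    Individuals missing either genotype of a pair are dropped pairwise.
    Distances are attached for same-chromosome pairs only; SNPs without a
    mapped position (position 0 on an 'NA' chromosome) never receive one.
    """
    mask, report = snp_gate(g, maf_threshold, hwe_alpha)
    if not apply_gate:
        f = allele_freqs(g)
        mask = polymorphic_mask(f, 1e-12)  # LD undefined for fixed SNPs
    if mask.sum() < 2:
        raise PopgenError(
            f"fewer than 2 SNPs pass the gate (Ng={report.n_individuals}, "
            f"SNPs={report.n_snps}, Np={report.n_polymorphic}, Ne={report.n_hwe})"
        )
    keep = np.flatnonzero(mask)
    sub = g.dosages[:, keep]
    snp_ids = [g.map.snp_id[j] for j in keep]
    chroms = [g.map.chromosome[j] for j in keep]
    pos = g.map.position_bp[keep]

    tables = _pair_tables(sub)
    iu, ju = np.triu_indices(len(keep), k=1)
    h, iters, ll, conv, ridge = _em_batch(tables[iu, ju])
    D, dprime, r2, dmax = _ld_from_freqs(h[:, 0], h[:, 1], h[:, 2], h[:, 3])
    same = np.array([str(chroms[a]) == str(chroms[b]) for a, b in zip(iu, ju)])
    dist = np.where(same, np.abs(pos[iu] - pos[ju]).astype(float), np.nan)
    df = pd.DataFrame(
        {
            "snp_i": [snp_ids[a] for a in iu],
            "snp_j": [snp_ids[b] for b in ju],
            "chrom_i": [chroms[a] for a in iu],
            "chrom_j": [chroms[b] for b in ju],
            "same_chromosome": same,
            "distance_bp": dist,
            "D": D,
            "Dprime": dprime,
            "r2": r2,
            "D_max": dmax,
            "em_converged": conv,
        }
    )
    return df, report


def ld_summaries(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean |D|, D' and r2 per chromosome and pooled.

    Rows: one per chromosome (within-chromosome pairs), ``linked`` (all
    within-chromosome pairs pooled) and ``all`` (every pair, including
    inter-chromosome ones) — the two column groups reported side by side in
    the classic LD-by-chromosome table layout.
    """
    if pairs.empty:
        raise PopgenError("no LD pairs to summarise")
    rows = []

    def _row(label, sub):
        rows.append(
            {
                "group": label,
                "mean_absD": sub["D"].abs().mean(),
                "mean_Dprime": sub["Dprime"].mean(),
                "mean_r2": sub["r2"].mean(),
                "n_pairs": len(sub),
                "n_snps_used": len(set(sub["snp_i"]) | set(sub["snp_j"])),
            }
        )

    linked = pairs[pairs["same_chromosome"]]
    for chrom, sub in linked.groupby(linked["chrom_i"].astype(str), sort=True):
        _row(str(chrom), sub)
    if not linked.empty:
        _row("linked", linked)
    _row("all", pairs)
    return pd.DataFrame(rows).set_index("group")


def ld_decay_table(pairs: pd.DataFrame, bin_width_mb: float = 10.0) -> pd.DataFrame:
    """Mean |D| in physical-distance bins (same-chromosome pairs only)."""
    if bin_width_mb <= 0:
        raise PopgenError("bin width must be positive")
    linked = pairs[pairs["same_chromosome"] & pairs["distance_bp"].notna()]
    if linked.empty:
        raise PopgenError("no same-chromosome pairs for decay profile")
    dist_mb = linked["distance_bp"].to_numpy() / 1e6
    bins = np.floor(dist_mb / bin_width_mb).astype(int)
    out = []
    for b in sorted(set(bins)):
        sel = bins == b
        out.append(
            {
                "bin_mid_mb": (b + 0.5) * bin_width_mb,
                "mean_absD": float(np.abs(linked["D"].to_numpy()[sel]).mean()),
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    snp_id: list[str]
    h_t: np.ndarray
    h_s: np.ndarray
    fst: np.ndarray      # NaN where H_T = 0
    mean_fst: float      # over loci with H_T > 0


def fst_pairwise(a: GenotypeMatrix, b: GenotypeMatrix) -> FstResult:
    """Nei-style pairwise F_ST = (H_T - H_S) / H_T over shared SNPs.

    H_T uses unweighted pooled allele frequencies, H_S the unweighted mean of
    the two within-population expected heterozygosities.  Loci fixed for the
    same allele in both populations (H_T = 0) are excluded from the average.
    """
    if list(a.map.snp_id) != list(b.map.snp_id):
        raise PopgenError("populations are not aligned to the same SNPs")
    fa, fb = allele_freqs(a), allele_freqs(b)
    he_a = 2 * fa.p * (1 - fa.p)
    he_b = 2 * fb.p * (1 - fb.p)
    h_s = (he_a + he_b) / 2.0
    p_bar = (fa.p + fb.p) / 2.0
    h_t = 2 * p_bar * (1 - p_bar)
    usable = h_t > 0
    if not usable.any():
        raise PopgenError("no usable loci (all fixed for the same allele)")
    fst = np.full(len(h_t), np.nan)
    fst[usable] = (h_t[usable] - h_s[usable]) / h_t[usable]
    return FstResult(list(a.map.snp_id), h_t, h_s, fst, float(fst[usable].mean()))
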