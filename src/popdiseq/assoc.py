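"""Single-marker association mapping, two ways.

Least-squares route: per-SNP one-way analysis of variance across the observed
genotype classes (up to three; equivalent to a least-squares regression with
a class factor), with Benjamini-Hochberg step-up control of the false
discovery rate across SNPs.  A 1-df regression on allele dosage is available
as an option.

Bayesian route: per-SNP normal linear regression of the phenotype on allele
dosage with vague priors (flat on the coefficients, Jeffreys on the error
variance), sampled by Gibbs; a SNP is declared significant when the 95%
highest-posterior-density interval of the slope excludes zero.  No
multiplicity correction is applied to HPD decisions, so with ~100 SNPs a
handful of chance flags is expected under the null — a point worth
remembering when reading the output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genodata import MISSING, GenotypeMatrix, PhenotypeTable
from .popgen import allele_freqs, polymorphic_mask

logger = logging.getLogger(__name__)


class AssocError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Least squares
# ---------------------------------------------------------------------------

def ls_assoc_snp(dosages, phenotype, model: str = "anova") -> tuple[float, float]:
    """F statistic and p-value for one SNP.

    ``model="anova"`` treats the genotype classes present as factor levels
    (df1 = classes - 1, df2 = n - classes); ``model="dosage"`` fits the 1-df
    linear regression on allele dosage.  A phenotype with zero within-class
    variance gives p = 1 when it is constant overall (F = 0) and p = 0 when
    the classes separate it perfectly.
    """
    x = np.asarray(dosages)
    y = np.asarray(phenotype, dtype=float)
    if len(x) != len(y) or len(y) < 3:
        raise AssocError("need >= 3 individuals with genotype and phenotype")
    classes = np.unique(x)
    if len(classes) < 2:
        raise AssocError("single genotype class")
    if model == "dosage":
        df1, df2 = 1, len(y) - 2
        xc = x - x.mean()
        yc = y - y.mean()
        sxy, sxx, syy = xc @ yc, xc @ xc, yc @ yc
        ss_model = sxy**2 / sxx
        ss_resid = syy - ss_model
    elif model == "anova":
        df1, df2 = len(classes) - 1, len(y) - len(classes)
        grand = y.mean()
        ss_model = sum(((y[x == c].mean() - grand) ** 2) * (x == c).sum() for c in classes)
        ss_resid = sum(((y[x == c] - y[x == c].mean()) ** 2).sum() for c in classes)
    else:
        raise AssocError(f"unknown model {model!r}")
    if df2 < 1:
        raise AssocError("no residual degrees of freedom")
    if ss_resid <= 1e-300:
        if ss_model <= 1e-300:
            return 0.0, 1.0  # constant phenotype: nothing to test
        return math.inf, 0.0
    f = (ss_model / df1) / (ss_resid / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``.

    Sort p-values ascending, find the largest rank i with p(i) <= i q / m,
    and flag everything at or below that rank; tied p-values share their
    rank's decision.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise AssocError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise AssocError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# Bayesian regression
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Gibbs-sampler run lengths (defaults sized for production runs; use
    :data:`MCMC_TEST_PROFILE` for quick checks)."""

    burn_in: int = 50_000
    iterations: int = 100_000
    thinning: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.iterations:
            raise AssocError("burn_in must be < iterations")
        if self.thinning < 1:
            raise AssocError("thinning must be >= 1")


#: Scaled-down profile for fast exploratory runs and the test suite.
MCMC_TEST_PROFILE = MCMCConfig(burn_in=500, iterations=2_000, thinning=2)


@dataclass
class AssocResultBayes:
    beta_mean: float
    beta_sd: float
    hpd_low: float
    hpd_high: float
    significant: bool
    n_draws: int


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(level * n)`` sorted samples."""
    if not (0.0 < level < 1.0):
        raise AssocError("HPD level must be in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    if n < 100:
        raise AssocError("need >= 100 samples for an HPD interval")
    m = int(np.ceil(level * n))
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def bayes_assoc_snp(
    dosages, phenotype, cfg: MCMCConfig | None = None, level: float = 0.95
) -> AssocResultBayes:
    """Gibbs-sampled posterior of the dosage slope for one SNP.

    Model: y = intercept + slope * dosage + e, e ~ N(0, sigma^2); flat prior
    on the coefficients and p(sigma^2) proportional to 1/sigma^2.  The two
    Gibbs blocks are the conjugate conditionals: coefficients given sigma^2
    are bivariate normal around the least-squares solution; sigma^2 given the
    coefficients is inverse-gamma.  Burn-in, total iterations and thinning
    come from ``cfg``.
    """
    cfg = cfg if cfg is not None else MCMCConfig()
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(x) != len(y) or len(y) < 3:
        raise AssocError("need >= 3 individuals")
    if np.ptp(x) == 0:
        raise AssocError("constant dosage")
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ xty
    chol = np.linalg.cholesky(xtx_inv)
    sse = yty - beta_hat @ xty

    rng = np.random.default_rng(cfg.seed)
    n_iter = cfg.iterations
    z = rng.standard_normal((n_iter, 2))
    # sigma^2 | beta ~ InvGamma(n/2, SSR/2): draw via gamma deviates
    gam = rng.gamma(n / 2.0, 1.0, size=n_iter)
    sigma2 = sse / max(n - 2, 1)
    kept = []
    for it in range(n_iter):
        beta = beta_hat + math.sqrt(sigma2) * (chol @ z[it])
        diff = beta - beta_hat
        ssr = sse + diff @ xtx @ diff
        sigma2 = ssr / (2.0 * gam[it])
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            kept.append(beta[1])
    draws = np.asarray(kept)
    if not np.all(np.isfinite(draws)):
        raise AssocError("divergent chain: non-finite draws")
    lo, hi = hpd_interval(draws, level)
    return AssocResultBayes(
        beta_mean=float(draws.mean()), beta_sd=float(draws.std(ddof=1)),
        hpd_low=lo, hpd_high=hi, significant=not (lo <= 0.0 <= hi),
        n_draws=len(draws),
    )


# ---------------------------------------------------------------------------
# GWAS driver
# ---------------------------------------------------------------------------

def run_gwas(
    g: GenotypeMatrix,
    phen: PhenotypeTable,
    method: str = "ls",
    q: float = 0.05,
    cfg: MCMCConfig | None = None,
    maf_threshold: float = 0.01,
    model: str = "anova",
) -> pd.DataFrame:
    """Per-SNP association table for the requested method(s).

    ``method`` is ``"ls"``, ``"bayes"`` or ``"both"``.  SNPs are gated to
    polymorphic (maf >= ``maf_threshold``); monomorphic or single-class SNPs
    are skipped with a log entry.  The least-squares p-values are flagged by
    Benjamini-Hochberg at FDR ``q`` across the tested SNPs.
    """
    if method not in ("ls", "bayes", "both"):
        raise AssocError(f"unknown method {method!r}")
    y = phen.aligned_to(g)
    freqs = allele_freqs(g)
    poly = polymorphic_mask(freqs, maf_threshold)
    rows = []
    for j in range(g.n_snps):
        called = g.dosages[:, j] != MISSING
        x = g.dosages[called, j].astype(int)
        yy = y[called]
        row = {
            "snp_id": g.map.snp_id[j],
            "chrom": g.map.chromosome[j],
            "position_bp": int(g.map.position_bp[j]),
            "n": int(called.sum()),
            "tested": bool(poly[j]) and len(np.unique(x)) >= 2 and len(yy) >= 3,
        }
        if not row["tested"]:
            logger.info("skipping SNP %s (monomorphic or too few classes)", row["snp_id"])
        else:
            if method in ("ls", "both"):
                row["F"], row["p"] = ls_assoc_snp(x, yy, model=model)
            if method in ("bayes", "both"):
                b = bayes_assoc_snp(x, yy, cfg=cfg)
                row.update(
                    beta_mean=b.beta_mean, beta_sd=b.beta_sd,
                    hpd_low=b.hpd_low, hpd_high=b.hpd_high,
                    hpd_significant=b.significant,
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    if method in ("ls", "both"):
        df["fdr_significant"] = False
        tested = df["tested"] & df["p"].notna()
        if tested.any():
            df.loc[tested, "fdr_significant"] = bh_fdr(df.loc[tested, "p"].to_numpy(), q=q)
    return df
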