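"""Temporal test of allele-frequency change between two population samples.

The standardized change statistic for a biallelic locus sampled at
frequencies ``x`` (base) and ``y`` (derived) is

    Fc = (x - y)^2 / (z - x y),   z = (x + y) / 2,

whose null expectation under pure binomial sampling of S0 and St diploid
individuals is ``E[Fc] = 1/(2 S0) + 1/(2 St)`` (plus ``t / (2 Ne)`` when an
explicit drift term for ``t`` generations at effective size ``Ne`` is
requested).  ``Fc / E[Fc]`` is referred to a 1-df chi-square distribution;
the chi-square form is inherently two-sided.  The default null is
sampling-only (no drift term), with the drift correction available as an
option; the conventional significance level for declaring a non-random
change is 0.05%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import GenotypeMatrix
from .popgen import allele_freqs

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.0005  # the 0.05% level


class TemporalError(ValueError):
    pass


def waples_fc(x, y):
    """Standardized allele-frequency-change statistic Fc.

    Symmetric in (x, y) and invariant under joint allele relabeling
    (x, y) -> (1-x, 1-y).  Undefined when x = y is 0 or 1 (locus fixed for
    the same allele in both samples); such loci are excluded from scans.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = (x + y) / 2.0
    denom = z - x * y
    if np.any(denom <= 0):
        raise TemporalError("Fc undefined: locus fixed for the same allele in both samples")
    out = (x - y) ** 2 / denom
    return float(out) if out.ndim == 0 else out


@dataclass
class TemporalTestResult:
    x: np.ndarray
    y: np.ndarray
    s0: int
    st: int
    fc: np.ndarray
    expected_fc: float
    chi2: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    abs_dp: np.ndarray
    alpha: float
    snp_id: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.x, "y": self.y, "S0": self.s0, "St": self.st,
                "Fc": self.fc, "chi2": self.chi2, "p": self.p_value,
                "significant": self.significant, "abs_dp": self.abs_dp,
            }
        )
        if self.snp_id is not None:
            df.insert(0, "snp_id", self.snp_id)
        return df


def waples_test(
    x,
    y,
    s0: int,
    st: int,
    alpha: float = DEFAULT_ALPHA,
    t: int = 0,
    ne: int | None = None,
) -> TemporalTestResult:
    """Chi-square test of Fc against its sampling (optionally drift) expectation.

    Parameters
    ----------
    x, y : scalar or array of allele frequencies (base, derived sample).
    s0, st : diploid sample sizes of the two samples.
    t, ne : optional number of generations and effective size for the drift
        term ``t / (2 ne)``; by default the null is sampling-only, which is
        the calibration under which a change of about 0.10 is needed for
        significance at the 0.05% level with samples of 300, and about 0.17
        with samples of 100.
    """
    if s0 < 1 or st < 1:
        raise TemporalError("sample sizes must be >= 1")
    if ne is not None and t == 0:
        raise TemporalError("Ne given without a generation count t")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    fc = np.atleast_1d(waples_fc(x, y))
    expected = 1.0 / (2 * s0) + 1.0 / (2 * st) + (t / (2.0 * ne) if ne is not None else 0.0)
    chi2 = fc / expected
    p = stats.chi2.sf(chi2, df=1)
    return TemporalTestResult(
        x=x, y=y, s0=s0, st=st, fc=fc, expected_fc=expected, chi2=chi2,
        p_value=p, significant=p < alpha, abs_dp=np.abs(y - x), alpha=alpha,
    )


@dataclass
class TemporalSummary:
    n_tested: int
    n_excluded: int
    n_significant: int
    # |delta p| summaries over significant SNPs and over all tested SNPs;
    # both are reported because table captions and rows in the literature
    # do not always agree on which set the min/mean/max refer to.
    min_abs_dp_significant: float
    mean_abs_dp_significant: float
    max_abs_dp_significant: float
    min_abs_dp_all: float
    mean_abs_dp_all: float
    max_abs_dp_all: float


def temporal_scan(
    base: GenotypeMatrix,
    derived: GenotypeMatrix,
    alpha: float = DEFAULT_ALPHA,
    t: int = 0,
    ne: int | None = None,
) -> tuple[TemporalTestResult, TemporalSummary]:
    """Per-SNP temporal test between two aligned populations, plus summary.

    SNPs fixed for the same allele in both samples are excluded (they carry
    no information about change and the statistic is undefined there).
    """
    if list(base.map.snp_id) != list(derived.map.snp_id):
        raise TemporalError("populations are not aligned to the same SNPs")
    fb, fd = allele_freqs(base), allele_freqs(derived)
    z = (fb.p + fd.p) / 2.0
    testable = (z - fb.p * fd.p) > 0
    n_excluded = int((~testable).sum())
    if not testable.any():
        raise TemporalError("no testable SNPs (all fixed for the same allele)")
    if n_excluded:
        logger.info("temporal scan: excluding %d SNP(s) fixed in both samples", n_excluded)
    res = waples_test(
        fb.p[testable], fd.p[testable], s0=base.n_individuals, st=derived.n_individuals,
        alpha=alpha, t=t, ne=ne,
    )
    res.snp_id = [s for s, m in zip(base.map.snp_id, testable) if m]
    sig = res.abs_dp[res.significant]
    summary = TemporalSummary(
        n_tested=int(testable.sum()),
        n_excluded=n_excluded,
        n_significant=int(res.significant.sum()),
        min_abs_dp_significant=float(sig.min()) if sig.size else 0.0,
        mean_abs_dp_significant=float(sig.mean()) if sig.size else 0.0,
        max_abs_dp_significant=float(sig.max()) if sig.size else 0.0,
        min_abs_dp_all=float(res.abs_dp.min()),
        mean_abs_dp_all=float(res.abs_dp.mean()),
        max_abs_dp_all=float(res.abs_dp.max()),
    )
    return res, summary
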