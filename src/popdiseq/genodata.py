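"""Core genotype data structures and I/O.

The in-memory containers are deliberately small: a :class:`SnpMap` (marker
name, chromosome, 1-based bp position, optional maize bin label) and a
:class:`GenotypeMatrix` (individuals x SNPs dosage codes counting copies of
the designated alternate allele, with missing support).  Everything downstream
— diversity, LD, temporal tests, association mapping — consumes these two
types.

Dosage convention: codes 0/1/2 count the alternate allele fixed at load time
(VCF ALT, or the CSV convention "allele coded 1").  Whether that allele is the
minor allele is recomputed per population, never assumed from the coding.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class GenodataError(ValueError):
    """Raised for malformed genotype/map/phenotype inputs."""


@dataclass
class SnpMap:
    """Per-SNP chromosome, 1-based bp position and optional bin label.

    Parameters
    ----------
    snp_id, chromosome, position_bp, bin :
        Parallel sequences.  Chromosome labels may be integers or strings;
        bins are maize bin labels such as ``"1.04"`` (or None).
    ref_allele, alt_allele :
        Optional allele labels; only needed when aligning populations whose
        files may disagree on which allele is coded as the alternate.
    """

    snp_id: list[str]
    chromosome: list
    position_bp: np.ndarray
    bin: list | None = None
    ref_allele: list[str] | None = None
    alt_allele: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_id = list(map(str, self.snp_id))
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if len(set(self.snp_id)) != len(self.snp_id):
            raise GenodataError("duplicate snp_ids in map")
        if np.any(self.position_bp < 0):
            raise GenodataError("position_bp must be >= 0")
        if self.bin is None:
            self.bin = [None] * len(self.snp_id)

    def __len__(self) -> int:
        return len(self.snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "bin": self.bin,
            }
        )

    def index_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_id)}
        try:
            return np.array([lookup[str(s)] for s in snp_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message only
            raise GenodataError(f"snp_id not in map: {exc.args[0]}") from exc

    def subset(self, idx: np.ndarray) -> "SnpMap":
        idx = np.asarray(idx)
        return SnpMap(
            snp_id=[self.snp_id[i] for i in idx],
            chromosome=[self.chromosome[i] for i in idx],
            position_bp=self.position_bp[idx],
            bin=[self.bin[i] for i in idx],
            ref_allele=None if self.ref_allele is None else [self.ref_allele[i] for i in idx],
            alt_allele=None if self.alt_allele is None else [self.alt_allele[i] for i in idx],
            metadata=dict(self.metadata),
        )

    def sort_by_position(self) -> "SnpMap":
        """Return a copy sorted by (chromosome, position)."""
        order = np.lexsort((self.position_bp, np.asarray([str(c) for c in self.chromosome])))
        return self.subset(order)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele dosage codes tied to a SnpMap."""

    individuals: list[str]
    dosages: np.ndarray  # int8, values in {0, 1, 2, MISSING}
    map: SnpMap

    def __post_init__(self) -> None:
        self.individuals = list(map(str, self.individuals))
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise GenodataError("dosages must be 2-D (individuals x snps)")
        if self.dosages.shape[1] != len(self.map):
            raise GenodataError(
                f"dosage columns ({self.dosages.shape[1]}) != map length ({len(self.map)})"
            )
        if len(self.individuals) != self.dosages.shape[0]:
            raise GenodataError("individual id count != dosage rows")
        if len(set(self.individuals)) != len(self.individuals):
            raise GenodataError("duplicated individual id")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenodataError(
                f"invalid dosage {self.dosages[i, j]} at individual "
                f"{self.individuals[i]!r}, snp {self.map.snp_id[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = self.map.index_of(snp_ids)
        return GenotypeMatrix(self.individuals, self.dosages[:, idx], self.map.subset(idx))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.dosages.copy(), self.map)


@dataclass
class PhenotypeTable:
    """Per-individual trait values (continuous, e.g. expansion volume mL/g).

    Replicate measurements are supported; analyses use per-individual means.
    """

    individuals: list[str]
    values: np.ndarray  # per-individual mean trait value
    replicates: dict[str, list[float]] | None = None
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.individuals = list(map(str, self.individuals))
        self.values = np.asarray(self.values, dtype=float)
        if len(self.individuals) != len(self.values):
            raise GenodataError("phenotype id/value length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise GenodataError("non-finite phenotype value")

    @classmethod
    def from_replicates(cls, measurements: dict[str, Sequence[float]], trait: str = "trait"):
        ids = list(measurements)
        means = np.array([np.mean(measurements[i]) for i in ids], dtype=float)
        return cls(ids, means, {k: list(v) for k, v in measurements.items()}, trait)

    def aligned_to(self, g: GenotypeMatrix) -> np.ndarray:
        """Values ordered as g.individuals; error if any individual lacks one."""
        lookup = dict(zip(self.individuals, self.values))
        missing = [i for i in g.individuals if i not in lookup]
        if missing:
            raise GenodataError(f"phenotype missing for individuals: {missing[:5]}")
        return np.array([lookup[i] for i in g.individuals], dtype=float)


# ---------------------------------------------------------------------------
# CSV / TSV I/O
# ---------------------------------------------------------------------------

def read_genotypes_csv(path: str | Path, snp_map: SnpMap | None = None) -> GenotypeMatrix:
    """Read a genotype dosage CSV (header ``id,<snp_id>,...``; NA = missing).

    When ``snp_map`` is omitted a positionless map is synthesised from the
    header so the matrix can still feed map-free statistics.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[0] == 0:
        raise GenodataError(f"{path}: no individuals")
    if df.shape[1] < 2:
        raise GenodataError(f"{path}: no SNP columns")
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise GenodataError(f"{path}: duplicated individual id {dup!r}")
    snp_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy()
    dosages = np.empty(raw.shape, dtype=np.int8)
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            cell = raw[i, j]
            if isinstance(cell, float) and np.isnan(cell) or str(cell).strip() in ("NA", "", "nan"):
                dosages[i, j] = MISSING
            elif str(cell).strip() in ("0", "1", "2"):
                dosages[i, j] = int(str(cell).strip())
            else:
                raise GenodataError(
                    f"{path}: malformed cell {cell!r} at row {ids[i]!r}, column {snp_ids[j]!r}"
                )
    if snp_map is None:
        snp_map = SnpMap(snp_ids, ["NA"] * len(snp_ids), np.zeros(len(snp_ids), dtype=np.int64))
    else:
        if list(snp_map.snp_id) != snp_ids:
            raise GenodataError(f"{path}: header SNPs do not match supplied map")
    return GenotypeMatrix(ids, dosages, snp_map)


def write_genotypes_csv(g: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id," + ",".join(g.map.snp_id) + "\n")
        for ind, row in zip(g.individuals, g.dosages):
            cells = ["NA" if v == MISSING else str(int(v)) for v in row]
            fh.write(ind + "," + ",".join(cells) + "\n")


def read_snp_map_tsv(path: str | Path) -> SnpMap:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "bin": str}, comment="#")
    required = {"snp_id", "chromosome", "position_bp"}
    if not required.issubset(df.columns):
        raise GenodataError(f"{path}: SNP map needs columns {sorted(required)}")
    bins = df["bin"].where(df["bin"].notna(), None).tolist() if "bin" in df else None
    return SnpMap(
        snp_id=df["snp_id"].tolist(),
        chromosome=df["chromosome"].tolist(),
        position_bp=df["position_bp"].to_numpy(dtype=np.int64),
        bin=bins,
    )


def write_snp_map_tsv(m: SnpMap, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes_csv(path: str | Path, trait: str | None = None) -> PhenotypeTable:
    """Read ``id,value`` (or ``id,<trait>``) CSV; repeated ids become replicates."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise GenodataError(f"{path}: phenotype file needs id + value columns")
    col = trait if trait is not None else df.columns[1]
    measurements: dict[str, list[float]] = {}
    for ind, val in zip(df.iloc[:, 0].astype(str), df[col].astype(float)):
        measurements.setdefault(ind, []).append(val)
    return PhenotypeTable.from_replicates(measurements, trait=str(col))


def write_phenotypes_csv(p: PhenotypeTable, path: str | Path) -> None:
    pd.DataFrame({"id": p.individuals, p.trait: p.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Minimal VCF
# ---------------------------------------------------------------------------

def read_vcf_minimal(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into alternate-allele dosages.

    GT ``0/0``→0, ``0/1``/``1/0``→1, ``1/1``→2, ``./.``→missing; phase is
    ignored.  Multi-allelic records are skipped with a warning; non-diploid
    calls are an error.  Only CHROM/POS/ID/REF/ALT/GT are consumed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = [str(s) for s in vcf.samples]
    snp_ids, chroms, positions, refs, alts, columns = [], [], [], [], [], []
    for n_rec, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            warnings.warn(
                f"{path}: skipping multi-allelic record {variant.CHROM}:{variant.POS}"
            )
            logger.warning("skipping multi-allelic record %s:%s", variant.CHROM, variant.POS)
            continue
        col = np.empty(len(ids), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if len(alleles) != 2:
                raise GenodataError(
                    f"{path}: non-diploid GT at {variant.CHROM}:{variant.POS} sample {ids[i]}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING
            else:
                col[i] = alleles[0] + alleles[1]
        snp_ids.append(variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}")
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        columns.append(col)
    if not columns:
        raise GenodataError(f"{path}: no usable biallelic records")
    snp_map = SnpMap(snp_ids, chroms, np.array(positions, dtype=np.int64),
                     ref_allele=refs, alt_allele=alts)
    return GenotypeMatrix(ids, np.column_stack(columns), snp_map)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf_minimal(g: GenotypeMatrix, path: str | Path) -> None:
    m = g.map
    refs = m.ref_allele if m.ref_allele is not None else ["A"] * len(m)
    alts = m.alt_allele if m.alt_allele is not None else ["T"] * len(m)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(str(c) for c in m.chromosome):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individuals) + "\n")
        for j in range(g.n_snps):
            gts = "\t".join(_GT_STRINGS[int(v)] for v in g.dosages[:, j])
            fh.write(
                f"{m.chromosome[j]}\t{int(m.position_bp[j])}\t{m.snp_id[j]}\t"
                f"{refs[j]}\t{alts[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Packaged SNP panel
# ---------------------------------------------------------------------------

def load_snp_panel(which: str = "true") -> SnpMap:
    """Load the packaged 96-SNP popcorn quality panel or its simulated twin.

    ``which="true"`` returns the 94 mapped SNPs of the real panel (the two
    SNPs that did not map to any assembly are excluded and listed under
    ``map.metadata["unmapped"]``); ``which="simulated"`` returns the 94
    numbered simulated SNPs on chromosomes 1-9.
    """
    if which not in ("true", "simulated"):
        raise GenodataError(f"unknown panel selector {which!r}")
    ref = importlib.resources.files("popdiseq.data") / f"snp_panel_{which}.tsv"
    df = pd.read_csv(ref, sep="\t", dtype={"snp_id": str, "bin": str})
    unmapped = df.loc[df["chromosome"].isna() | (df["chromosome"] == "NA"), "snp_id"].tolist()
    df = df[~df["snp_id"].isin(unmapped)]
    snp_map = SnpMap(
        snp_id=df["snp_id"].tolist(),
        chromosome=[int(c) for c in df["chromosome"]],
        position_bp=df["position_bp"].to_numpy(dtype=np.int64),
        bin=df["bin"].where(df["bin"].notna(), None).tolist(),
    )
    snp_map.metadata["unmapped"] = unmapped
    snp_map.metadata["panel"] = which
    return snp_map


# ---------------------------------------------------------------------------
# Data hygiene
# ---------------------------------------------------------------------------

def impute_missing_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by that SNP's modal dosage.

    Ties between equally frequent dosage codes break toward the lower code.
    This is a deliberately simple stand-in for haplotype-aware imputation:
    downstream analyses can also skip imputation entirely and drop missing
    calls pairwise.
    """
    out = g.dosages.copy()
    for j in range(g.n_snps):
        col = out[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        called = col[~miss]
        if called.size == 0:
            raise GenodataError(f"SNP {g.map.snp_id[j]!r} entirely missing")
        counts = np.bincount(called, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the lowest code on ties
        col[miss] = mode
    return GenotypeMatrix(list(g.individuals), out, g.map)


def align_populations(pops: Sequence[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Restrict matrices to their common SNPs, same column order/orientation.

    If maps carry allele labels and two populations disagree on which allele
    is the alternate, the discordant columns are recoded ``2 - x`` (missing
    preserved) so dosages count the same allele everywhere.
    """
    if not pops:
        raise GenodataError("no populations to align")
    common = set(pops[0].map.snp_id)
    for p in pops[1:]:
        common &= set(p.map.snp_id)
    if not common:
        raise GenodataError("empty SNP intersection across populations")
    # Keep the first population's ordering.
    order = [s for s in pops[0].map.snp_id if s in common]
    ref = pops[0].subset_snps(order)
    out = [ref]
    for p in pops[1:]:
        sub = p.subset_snps(order)
        if ref.map.alt_allele is not None and sub.map.alt_allele is not None:
            for j in range(len(order)):
                if sub.map.alt_allele[j] != ref.map.alt_allele[j]:
                    if (sub.map.alt_allele[j] == ref.map.ref_allele[j]
                            and sub.map.ref_allele[j] == ref.map.alt_allele[j]):
                        col = sub.dosages[:, j]
                        called = col != MISSING
                        col[called] = 2 - col[called]
                        sub.map.alt_allele[j] = ref.map.alt_allele[j]
                        sub.map.ref_allele[j] = ref.map.ref_allele[j]
                    else:
                        raise GenodataError(
                            f"allele mismatch at {order[j]}: "
                            f"{ref.map.ref_allele[j]}/{ref.map.alt_allele[j]} vs "
                            f"{sub.map.ref_allele[j]}/{sub.map.alt_allele[j]}"
                        )
        out.append(sub)
    return out
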