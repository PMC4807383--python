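"""Configuration-driven orchestration of the full analysis chain.

A single :class:`RunConfig` (usually loaded from YAML) drives: simulate the
composite (Pop1) and random-mated (Pop2) populations at each requested sample
size, then run LD, temporal, F_ST and GWAS analyses and render compact
summary reports.  Every output file carries the config hash and seed in a
comment header, so reruns with an identical config are reproducible
bit-for-bit (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, popgen, temporal as temporal_mod
from .genodata import (
    GenotypeMatrix,
    read_genotypes_csv,
    read_phenotypes_csv,
    read_snp_map_tsv,
    write_genotypes_csv,
    write_phenotypes_csv,
    write_snp_map_tsv,
)
from .simulate import SimConfig, assign_effects, found_composite, phenotypes, random_mate

logger = logging.getLogger(__name__)

DATASETS = ("pop1", "pop2")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline settings: simulation block, gates, analyses, output control."""

    simulation: dict = field(default_factory=dict)  # SimConfig field overrides
    sample_sizes: tuple[int, ...] = (100, 300)
    generations: int = 10
    maf: float = 0.01
    hwe_alpha: float = 0.05
    temporal_alpha: float = 0.0005
    fdr_q: float = 0.05
    gwas_method: str = "both"
    mcmc_profile: str = "test"  # "test" (fast) or "full" (production run lengths)
    analyses: tuple[str, ...] = ("ld", "temporal", "fst", "gwas")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.analyses:
            raise PipelineError("at least one analysis must be requested")
        unknown = set(self.analyses) - {"ld", "temporal", "fst", "gwas"}
        if unknown:
            raise PipelineError(f"unknown analyses: {sorted(unknown)}")
        if self.mcmc_profile not in ("test", "full"):
            raise PipelineError("mcmc_profile must be 'test' or 'full'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        for key in ("sample_sizes", "analyses"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def sim_config(self, pop_size: int) -> SimConfig:
        overrides = dict(self.simulation)
        overrides.pop("pop_size", None)
        overrides.pop("seed", None)
        return SimConfig(pop_size=pop_size, seed=self.seed, **overrides)

    def mcmc_config(self) -> assoc.MCMCConfig:
        base = assoc.MCMC_TEST_PROFILE if self.mcmc_profile == "test" else assoc.MCMCConfig()
        return dataclasses.replace(base, seed=self.seed)


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def _dataset_dir(outdir: Path, pop: str, n: int) -> Path:
    return outdir / f"{pop}_n{n}"


def cmd_simulate(cfg: RunConfig, outdir: str | Path) -> dict:
    """Simulate Pop1/Pop2 at every sample size; emit genotypes, phenotypes, maps."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "datasets": {}}
    for n in cfg.sample_sizes:
        sim = cfg.sim_config(pop_size=n)
        arch = assign_effects(sim)
        pop1 = phenotypes(found_composite(sim, arch), arch)
        pop2 = phenotypes(random_mate(pop1, cfg.generations), arch)
        for pop_name, pop in (("pop1", pop1), ("pop2", pop2)):
            ddir = _dataset_dir(outdir, pop_name, n)
            ddir.mkdir(parents=True, exist_ok=True)
            g = pop.genotype_matrix("analysis")
            write_genotypes_csv(g, ddir / "genotypes.csv")
            write_snp_map_tsv(g.map, ddir / "snp_map.tsv")
            write_phenotypes_csv(pop.phenotype_table(), ddir / "phenotypes.csv")
            freqs = popgen.allele_freqs(g)
            _, he_mean = popgen.gene_diversity(freqs)
            manifest["datasets"][f"{pop_name}_n{n}"] = {
                "n_individuals": g.n_individuals,
                "generation": pop.generation,
                "effective_size": pop.effective_size,
                "mean_he": round(he_mean, 4),
                "n_polymorphic": int(popgen.polymorphic_mask(freqs, cfg.maf).sum()),
                "phenotype_mean": round(float(pop.y.mean()), 3),
                "phenotype_var": round(float(pop.y.var(ddof=1)), 3),
            }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("simulated %d datasets into %s", len(manifest["datasets"]), outdir)
    return manifest


def _load_dataset(ddir: Path) -> GenotypeMatrix:
    if not (ddir / "genotypes.csv").exists():
        raise PipelineError(f"missing {ddir}/genotypes.csv — rerun the simulate stage")
    snp_map = read_snp_map_tsv(ddir / "snp_map.tsv")
    return read_genotypes_csv(ddir / "genotypes.csv", snp_map=snp_map)


def cmd_ld(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    for n in cfg.sample_sizes:
        for pop in DATASETS:
            ddir = _dataset_dir(outdir, pop, n)
            g = _load_dataset(ddir)
            pairs, report = popgen.ld_all_pairs(g, cfg.maf, cfg.hwe_alpha)
            _write_tsv(pairs, ddir / "ld_pairs.tsv", cfg)
            _write_tsv(popgen.ld_summaries(pairs), ddir / "ld_summary.tsv", cfg, index=True)
            _write_tsv(popgen.ld_decay_table(pairs), ddir / "ld_decay.tsv", cfg)
            logger.info("%s: Ng=%d Np=%d Ne=%d", ddir.name, report.n_individuals,
                        report.n_polymorphic, report.n_hwe)


def cmd_temporal(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    for n in cfg.sample_sizes:
        base = _load_dataset(_dataset_dir(outdir, "pop1", n))
        derived = _load_dataset(_dataset_dir(outdir, "pop2", n))
        res, summary = temporal_mod.temporal_scan(base, derived, alpha=cfg.temporal_alpha)
        ddir = _dataset_dir(outdir, "pop2", n)
        _write_tsv(res.to_frame(), ddir / "temporal.tsv", cfg)
        _write_tsv(pd.DataFrame([dataclasses.asdict(summary)]), ddir / "temporal_summary.tsv", cfg)


def cmd_fst(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    for n in cfg.sample_sizes:
        a = _load_dataset(_dataset_dir(outdir, "pop1", n))
        b = _load_dataset(_dataset_dir(outdir, "pop2", n))
        res = popgen.fst_pairwise(a, b)
        df = pd.DataFrame({"snp_id": res.snp_id, "H_T": res.h_t, "H_S": res.h_s, "Fst": res.fst})
        df.loc[len(df)] = ["MEAN", np.nan, np.nan, res.mean_fst]
        _write_tsv(df, _dataset_dir(outdir, "pop2", n) / "fst.tsv", cfg)


def cmd_gwas(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    for n in cfg.sample_sizes:
        for pop in DATASETS:
            ddir = _dataset_dir(outdir, pop, n)
            g = _load_dataset(ddir)
            phen = read_phenotypes_csv(ddir / "phenotypes.csv")
            df = assoc.run_gwas(
                g, phen, method=cfg.gwas_method, q=cfg.fdr_q,
                cfg=cfg.mcmc_config(), maf_threshold=cfg.maf,
            )
            _write_tsv(df, ddir / "gwas.tsv", cfg)


def cmd_report(cfg: RunConfig, outdir: str | Path) -> str:
    """Render phenotype / LD / temporal / association summary tables.

    Regeneration is idempotent: the report is a pure function of the stage
    outputs on disk.
    """
    outdir = Path(outdir)
    lines: list[str] = [f"# popdiseq report  config_hash={cfg.config_hash()} seed={cfg.seed}", ""]

    lines.append("== Phenotype summary (min / mean / max / variance) ==")
    for n in cfg.sample_sizes:
        for pop in DATASETS:
            ddir = _dataset_dir(outdir, pop, n)
            if not (ddir / "phenotypes.csv").exists():
                raise PipelineError(f"missing {ddir}/phenotypes.csv — rerun the simulate stage")
            y = read_phenotypes_csv(ddir / "phenotypes.csv").values
            lines.append(
                f"{pop}\tn={n}\t{y.min():.1f}\t{y.mean():.1f}\t{y.max():.1f}\t{y.var(ddof=1):.2f}"
            )
    lines.append("")

    lines.append("== LD summary (mean |D| / D' / r2, linked and all pairs) ==")
    for n in cfg.sample_sizes:
        for pop in DATASETS:
            path = _dataset_dir(outdir, pop, n) / "ld_summary.tsv"
            if not path.exists():
                raise PipelineError(f"missing {path} — rerun the ld stage")
            summ = pd.read_csv(path, sep="\t", comment="#", index_col=0)
            for group in ("linked", "all"):
                r = summ.loc[group]
                lines.append(
                    f"{pop}\tn={n}\t{group}\t{r.mean_absD:.4f}\t{r.mean_Dprime:.4f}"
                    f"\t{r.mean_r2:.4f}\t({int(r.n_pairs)} pairs)"
                )
    lines.append("")

    lines.append("== Temporal test (pop1 -> pop2, alpha = "
                 f"{cfg.temporal_alpha:g}) ==")
    for n in cfg.sample_sizes:
        path = _dataset_dir(outdir, "pop2", n) / "temporal_summary.tsv"
        if not path.exists():
            raise PipelineError(f"missing {path} — rerun the temporal stage")
        s = pd.read_csv(path, sep="\t", comment="#").iloc[0]
        lines.append(
            f"n={n}\tN_significant={int(s.n_significant)}"
            f"\t|dp| significant: {s.min_abs_dp_significant:.4f}/"
            f"{s.mean_abs_dp_significant:.4f}/{s.max_abs_dp_significant:.4f}"
            f"\t|dp| all: {s.min_abs_dp_all:.4f}/{s.mean_abs_dp_all:.4f}/{s.max_abs_dp_all:.4f}"
        )
    lines.append("")

    lines.append("== Association mapping ==")
    for n in cfg.sample_sizes:
        for pop in DATASETS:
            path = _dataset_dir(outdir, pop, n) / "gwas.tsv"
            if not path.exists():
                raise PipelineError(f"missing {path} — rerun the gwas stage")
            df = pd.read_csv(path, sep="\t", comment="#")
            flags = df.get("fdr_significant", pd.Series(dtype=bool)).fillna(False)
            hpd = df.get("hpd_significant", pd.Series(dtype=bool)).fillna(False)
            sig = df[flags | hpd]
            if sig.empty:
                lines.append(f"{pop}\tn={n}\tzero significant associations")
            else:
                for _, r in sig.iterrows():
                    hpd_str = (
                        f"{r.hpd_low:.2f}; {r.hpd_high:.2f}"
                        if bool(r.get("hpd_significant", False)) else "ns"
                    )
                    fdr_str = f"{r.p:.4f}" if bool(r.get("fdr_significant", False)) else "ns"
                    lines.append(
                        f"{pop}\tn={n}\tchr{r.chrom}\t{int(r.position_bp)}\t{r.snp_id}"
                        f"\tFDR {fdr_str}\tHPD {hpd_str}"
                    )
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text


def cmd_all(cfg: RunConfig, outdir: str | Path) -> str:
    cmd_simulate(cfg, outdir)
    if "ld" in cfg.analyses:
        cmd_ld(cfg, outdir)
    if "temporal" in cfg.analyses:
        cmd_temporal(cfg, outdir)
    if "fst" in cfg.analyses:
        cmd_fst(cfg, outdir)
    if "gwas" in cfg.analyses:
        cmd_gwas(cfg, outdir)
    return cmd_report(cfg, outdir)
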