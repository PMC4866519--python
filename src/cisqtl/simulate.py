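"""Synthetic genotype/phenotype/covariate data with known ground truth.

Genotypes are drawn from a Gaussian-copula model: each of the two
haplotypes per sample is a latent AR(1) Gaussian process across variant
index (parameter ``ld_rho``), thresholded per variant at the quantile
implied by its sampled minor-allele frequency. Summing the two allele
indicators yields Hardy-Weinberg dosages in {0, 1, 2} whose
adjacent-variant correlation grows with ``ld_rho`` — a cheap but
controllable stand-in for linkage disequilibrium.

Phenotypes follow the additive model
``y = slope * dosage + covariate effects + Gaussian noise``; phenotypes
absent from the effect table are pure noise. Anchors are placed on the
planted variant's position so it always sits inside the default window.

Writers emit spec-conformant plain-text VCF / BED / covariate files and
can bgzip + Tabix-index them for region-query tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .io_formats import CovariateMatrix, DosageMatrix, PhenotypeSet

__all__ = ["SimConfig", "simulate_genotypes", "simulate_phenotypes",
           "simulate_covariates", "write_fixture"]


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic fixture.

    Defaults describe a small but realistic eQTL panel: a few hundred
    samples, common variants (MAF 0.05-0.5), moderate LD, unit-variance
    residual noise.
    """

    n_samples: int = 300
    n_variants: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    n_phenotypes: int = 20
    # phenotype index -> (variant index, slope); phenotypes not listed are null
    effects: dict[int, tuple[int, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    n_covariates: int = 0
    covariate_sd: float = 0.0  # per-covariate effect size on every phenotype
    missing_rate: float = 0.0
    chrom: str = "1"
    start_pos: int = 10_000
    spacing: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ld_rho < 1:
            raise ValueError("need 0 <= ld_rho < 1")
        for pi, (vi, _) in self.effects.items():
            if not 0 <= vi < self.n_variants:
                raise ValueError(f"effect for phenotype {pi} references variant {vi}")
            if not 0 <= pi < self.n_phenotypes:
                raise ValueError(f"effect references phenotype {pi}")


def _ar1_latent(rng, n_series: int, length: int, rho: float) -> np.ndarray:
    z = np.empty((n_series, length))
    z[:, 0] = rng.standard_normal(n_series)
    innov = rng.standard_normal((n_series, length - 1)) if length > 1 else None
    s = np.sqrt(1.0 - rho**2)
    for j in range(1, length):
        z[:, j] = rho * z[:, j - 1] + s * innov[:, j - 1]
    return z


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> DosageMatrix:
    """Dosage matrix with AR(1)-copula LD and evenly spaced positions."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    from scipy.special import ndtri

    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_variants)
    thresholds = ndtri(mafs)  # allele carried when latent < threshold
    # two haplotypes per sample, each an AR(1) chain over variants
    h1 = _ar1_latent(rng, cfg.n_samples, cfg.n_variants, cfg.ld_rho)
    h2 = _ar1_latent(rng, cfg.n_samples, cfg.n_variants, cfg.ld_rho)
    dosages = ((h1 < thresholds).astype(float) + (h2 < thresholds).astype(float)).T
    positions = cfg.start_pos + cfg.spacing * np.arange(cfg.n_variants)
    ids = [f"var{j + 1}" for j in range(cfg.n_variants)]
    samples = [f"S{i + 1}" for i in range(cfg.n_samples)]
    return DosageMatrix(
        chrom=cfg.chrom,
        variant_ids=ids,
        positions=positions,
        dosages=dosages,
        sample_ids=samples,
    )


def simulate_covariates(cfg: SimConfig, rng: np.random.Generator | None = None) -> CovariateMatrix | None:
    if cfg.n_covariates == 0:
        return None
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    vals = rng.standard_normal((cfg.n_covariates, cfg.n_samples))
    return CovariateMatrix(
        covariate_ids=[f"cov{c + 1}" for c in range(cfg.n_covariates)],
        values=vals,
        sample_ids=[f"S{i + 1}" for i in range(cfg.n_samples)],
    )


def simulate_phenotypes(
    g: DosageMatrix,
    cfg: SimConfig,
    cov: CovariateMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> PhenotypeSet:
    """Additive-model phenotypes; anchor = planted variant's position for
    phenotypes with effects, evenly spread across the variant span for
    null phenotypes."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n, m = g.n_samples, cfg.n_phenotypes
    values = rng.normal(0.0, cfg.noise_sd, size=(m, n))
    if cov is not None and cfg.covariate_sd > 0:
        effects = rng.normal(0.0, cfg.covariate_sd, size=(m, cov.n_covariates))
        values += effects @ cov.values
    anchors = np.empty(m, dtype=int)
    span_anchor = np.linspace(g.positions[0], g.positions[-1], num=max(m, 2)).astype(int)
    for i in range(m):
        if i in cfg.effects:
            vi, slope = cfg.effects[i]
            values[i] += slope * g.dosages[vi]
            anchors[i] = g.positions[vi]
        else:
            anchors[i] = span_anchor[i % len(span_anchor)]
    # coordinate-sorted so written BED files are Tabix-indexable
    order = np.argsort(anchors, kind="stable")
    return PhenotypeSet(
        phenotype_ids=[f"pheno{i + 1}" for i in order],
        chroms=[cfg.chrom] * m,
        starts=(anchors - 1)[order],
        ends=anchors[order],
        values=values[order],
        sample_ids=list(g.sample_ids),
    )


def _write_vcf(g: DosageMatrix, path: Path, missing_rate: float, rng) -> None:
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={g.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(g.n_variants):
            miss = (
                rng.random(g.n_samples) < missing_rate
                if missing_rate > 0
                else np.zeros(g.n_samples, dtype=bool)
            )
            calls = []
            for i in range(g.n_samples):
                if miss[i]:
                    calls.append("./.:.")
                else:
                    d = g.dosages[j, i]
                    calls.append(f"{gts[int(round(d))]}:{d:g}")
            fh.write(
                f"{g.chrom}\t{g.positions[j]}\t{g.variant_ids[j]}\tA\tG\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(calls) + "\n"
            )


def _write_bed(p: PhenotypeSet, path: Path) -> None:
    with open(path, "wt") as fh:
        fh.write("#chr\tstart\tend\tid\t" + "\t".join(p.sample_ids) + "\n")
        for i in range(p.n_phenotypes):
            row = "\t".join(repr(float(v)) for v in p.values[i])
            fh.write(
                f"{p.chroms[i]}\t{p.starts[i]}\t{p.ends[i]}\t{p.phenotype_ids[i]}\t{row}\n"
            )


def _write_cov(c: CovariateMatrix, path: Path) -> None:
    with open(path, "wt") as fh:
        fh.write("id " + " ".join(c.sample_ids) + "\n")
        for i, cid in enumerate(c.covariate_ids):
            fh.write(cid + " " + " ".join(repr(float(v)) for v in c.values[i]) + "\n")


def write_fixture(
    g: DosageMatrix,
    p: PhenotypeSet,
    cov: CovariateMatrix | None,
    out_dir: str | Path,
    missing_rate: float = 0.0,
    bgzip: bool = False,
    seed: int = 0,
) -> dict[str, Path]:
    """Write VCF/BED(/covariate) files; with ``bgzip=True`` the VCF and
    BED are bgzip-compressed and Tabix-indexed for region queries."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    vcf = out_dir / "genotypes.vcf"
    bed = out_dir / "phenotypes.bed"
    _write_vcf(g, vcf, missing_rate, rng)
    _write_bed(p, bed)
    if bgzip:
        for key, plain, preset in (("vcf", vcf, "vcf"), ("bed", bed, "bed")):
            gz = Path(str(plain) + ".gz")
            pysam.tabix_compress(str(plain), str(gz), force=True)
            pysam.tabix_index(str(gz), preset=preset, force=True)
            plain.unlink()
            paths[key] = gz
    else:
        paths["vcf"], paths["bed"] = vcf, bed
    if cov is not None:
        covp = out_dir / "covariates.txt"
        _write_cov(cov, covp)
        paths["cov"] = covp
    return paths
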