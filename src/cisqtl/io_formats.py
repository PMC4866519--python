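"""Genomic file I/O for cis-QTL mapping.

Reads genotype dosages from VCF (plain or bgzipped + Tabix-indexed),
molecular phenotype quantifications from UCSC BED (4 annotation columns
followed by one column per sample), and covariate tables; aligns samples
across the three; writes the per-phenotype results table.

Coordinate conventions: VCF positions are 1-based; BED intervals are
0-based half-open. The cis-window anchor of a phenotype is its BED start
interpreted as a 1-based position (``anchor = start + 1``), i.e. a
TSS-style single-coordinate anchor. Signed distances are
``variant POS - anchor``.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "DosageMatrix",
    "PhenotypeSet",
    "CovariateMatrix",
    "read_genotype_region",
    "read_phenotype_bed",
    "read_covariates",
    "intersect_samples",
    "write_results",
    "parse_region",
]

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) into its parts."""
    m = _REGION_RE.match(region)
    if m is None:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise ValueError(f"malformed region {region!r}: need 1 <= start <= end")
    return chrom, start, end


@dataclass
class DosageMatrix:
    """Genotype dosages at L variant sites for N samples.

    ``dosages`` is an L x N real matrix with values in [0, 2] (expected
    alternate-allele counts). Variants are sorted by position and carry
    no zero-variance rows after filtering.
    """

    chrom: str
    variant_ids: list[str]
    positions: np.ndarray  # 1-based, ascending
    dosages: np.ndarray  # L x N
    sample_ids: list[str]
    n_monomorphic_dropped: int = 0

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def window(self, anchor: int, window: int) -> "DosageMatrix":
        """Subset to variants with POS in [anchor - window, anchor + window]."""
        lo = np.searchsorted(self.positions, anchor - window, side="left")
        hi = np.searchsorted(self.positions, anchor + window, side="right")
        return DosageMatrix(
            chrom=self.chrom,
            variant_ids=self.variant_ids[lo:hi],
            positions=self.positions[lo:hi],
            dosages=self.dosages[lo:hi],
            sample_ids=self.sample_ids,
        )


@dataclass
class PhenotypeSet:
    """Molecular phenotype quantifications with genomic anchors.

    ``values`` is a phenotypes x N matrix. BED coordinates are kept
    0-based half-open; ``anchors`` holds the derived 1-based cis-window
    centers (start + 1).
    """

    phenotype_ids: list[str]
    chroms: list[str]
    starts: np.ndarray  # 0-based
    ends: np.ndarray
    values: np.ndarray
    sample_ids: list[str]

    @property
    def anchors(self) -> np.ndarray:
        return self.starts + 1

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_ids)

    def subset(self, idx) -> "PhenotypeSet":
        idx = np.asarray(idx, dtype=int)
        return PhenotypeSet(
            phenotype_ids=[self.phenotype_ids[i] for i in idx],
            chroms=[self.chroms[i] for i in idx],
            starts=self.starts[idx],
            ends=self.ends[idx],
            values=self.values[idx],
            sample_ids=self.sample_ids,
        )


@dataclass
class CovariateMatrix:
    """C covariates x N samples; qualitative covariates pre-encoded numerically."""

    covariate_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_ids)


def _is_gzipped(path: str | Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _dosage_from_record(rec, n_samples: int) -> np.ndarray:
    """Per-sample dosage: DS field when present, else alternate-allele count
    from GT. Missing calls become NaN."""
    out = np.full(n_samples, np.nan)
    has_ds = "DS" in rec.format
    for i, (_, call) in enumerate(rec.samples.items()):
        if has_ds:
            ds = call.get("DS")
            if isinstance(ds, tuple):
                ds = ds[0] if ds else None
            if ds is not None:
                out[i] = float(ds)
                continue
        gt = call.get("GT")
        if gt is None or any(a is None for a in gt):
            continue
        out[i] = float(sum(1 for a in gt if a != 0))
    return out


def read_genotype_region(
    vcf_path: str | Path,
    region: str | None = None,
    maf_min: float = 0.0,
    missing_policy: str = "mean",
) -> DosageMatrix:
    """Read a dosage matrix from a VCF, optionally restricted to a region.

    Parameters
    ----------
    vcf_path
        Plain-text or bgzipped VCF. A Tabix/CSI index is required only
        when a region query is made on a compressed file; plain files are
        scanned in full and filtered in memory.
    region
        ``chrom:start-end`` with 1-based inclusive coordinates, or None
        for the whole file (single-chromosome files expected).
    maf_min
        Minor-allele-frequency threshold computed from the mean dosage;
        variants below it are dropped. Zero-variance (monomorphic)
        variants are always dropped and counted.
    missing_policy
        ``"mean"`` imputes missing calls to the per-variant mean dosage;
        ``"drop"`` removes samples carrying any missing call.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)
    if missing_policy not in ("mean", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    reg = parse_region(region) if region is not None else None
    compressed = _is_gzipped(vcf_path)

    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    n = len(samples)

    if reg is not None and compressed:
        tbi = Path(str(vcf_path) + ".tbi")
        csi = Path(str(vcf_path) + ".csi")
        if not tbi.exists() and not csi.exists():
            raise FileNotFoundError(
                f"region query on compressed VCF {vcf_path} requires a "
                "Tabix (.tbi) or CSI (.csi) index"
            )
        chrom, start, end = reg
        records = vf.fetch(chrom, start - 1, end)
    else:
        records = iter(vf)

    ids: list[str] = []
    pos: list[int] = []
    rows: list[np.ndarray] = []
    chrom_seen: str | None = None
    i_rec = 0
    try:
        for rec in records:
            i_rec += 1
            if reg is not None:
                chrom, start, end = reg
                if rec.chrom != chrom or not (start <= rec.pos <= end):
                    continue
            if chrom_seen is None:
                chrom_seen = rec.chrom
            elif rec.chrom != chrom_seen and reg is None:
                raise ValueError(
                    f"multiple chromosomes in {vcf_path} without a region; "
                    "query one chromosome at a time"
                )
            vid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
            ids.append(vid)
            pos.append(rec.pos)
            rows.append(_dosage_from_record(rec, n))
    except Exception as exc:  # pragma: no cover - depends on malformed input
        if isinstance(exc, ValueError):
            raise
        raise ValueError(f"malformed VCF record near record {i_rec} of {vcf_path}: {exc}")
    finally:
        vf.close()

    if not rows:
        return DosageMatrix(
            chrom=chrom_seen or (reg[0] if reg else ""),
            variant_ids=[],
            positions=np.empty(0, dtype=int),
            dosages=np.empty((0, n)),
            sample_ids=samples,
        )

    dos = np.vstack(rows)
    positions = np.asarray(pos, dtype=int)
    order = np.argsort(positions, kind="stable")
    positions, dos = positions[order], dos[order]
    ids = [ids[i] for i in order]

    if missing_policy == "drop":
        keep = ~np.isnan(dos).any(axis=0)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d samples with missing genotypes", n_dropped)
        dos = dos[:, keep]
        samples = [s for s, k in zip(samples, keep) if k]
    else:
        miss = np.isnan(dos)
        if miss.any():
            row_mean = np.nanmean(np.where(miss, np.nan, dos), axis=1)
            row_mean = np.where(np.isnan(row_mean), 0.0, row_mean)
            dos = np.where(miss, row_mean[:, None], dos)

    af = dos.mean(axis=1) / 2.0
    maf = np.minimum(af, 1.0 - af)
    variance = dos.var(axis=1)
    mono = variance == 0.0
    n_mono = int(mono.sum())
    keep = (~mono) & (maf >= maf_min)
    if n_mono:
        logger.info("dropped %d monomorphic variants", n_mono)
    return DosageMatrix(
        chrom=chrom_seen or "",
        variant_ids=[v for v, k in zip(ids, keep) if k],
        positions=positions[keep],
        dosages=dos[keep],
        sample_ids=samples,
        n_monomorphic_dropped=n_mono,
    )


def read_phenotype_bed(bed_path: str | Path, region: str | None = None) -> PhenotypeSet:
    """Read a phenotype BED: ``#chr start end id sample1 sample2 ...``.

    When ``region`` is given, phenotypes whose anchor (start + 1) falls
    inside it are returned; an empty intersection yields an empty set.
    """
    bed_path = Path(bed_path)
    opener = gzip.open if _is_gzipped(bed_path) else open
    with opener(bed_path, "rt") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{bed_path}: BED header line must start with '#'")
        cols = header.lstrip("#").split("\t")
        if len(cols) < 5:
            raise ValueError(f"{bed_path}: expected >=5 columns (chr start end id samples...)")
        sample_ids = cols[4:]
        df = pd.read_csv(
            io.StringIO(fh.read()), sep="\t", header=None, names=cols,
            dtype={cols[0]: str}, float_precision="round_trip",
        )
    if df.shape[1] != len(cols):
        raise ValueError(f"{bed_path}: column count mismatch between header and rows")
    if df.iloc[:, 4:].isna().any().any():
        # NaN where the source had no field means a ragged row
        raise ValueError(f"{bed_path}: sample-count mismatch between header and rows")
    values = df.iloc[:, 4:].to_numpy(dtype=float)
    ids = df.iloc[:, 3].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"{bed_path}: duplicated phenotype ids {dupes}")
    chroms = df.iloc[:, 0].astype(str).tolist()
    starts = df.iloc[:, 1].to_numpy(dtype=int)
    ends = df.iloc[:, 2].to_numpy(dtype=int)

    pset = PhenotypeSet(
        phenotype_ids=ids,
        chroms=chroms,
        starts=starts,
        ends=ends,
        values=values,
        sample_ids=sample_ids,
    )
    if region is None:
        return pset
    chrom, start, end = parse_region(region)
    anchors = pset.anchors
    keep = [
        i
        for i in range(pset.n_phenotypes)
        if chroms[i] == chrom and start <= anchors[i] <= end
    ]
    return pset.subset(keep)


def read_covariates(cov_path: str | Path) -> CovariateMatrix:
    """Read a whitespace-separated covariate table: ids in column 1,
    sample ids in the header row."""
    df = pd.read_csv(cov_path, sep=r"\s+", index_col=0, float_precision="round_trip")
    return CovariateMatrix(
        covariate_ids=[str(x) for x in df.index],
        values=df.to_numpy(dtype=float),
        sample_ids=[str(c) for c in df.columns],
    )


def intersect_samples(
    g: DosageMatrix,
    p: PhenotypeSet,
    c: CovariateMatrix | None = None,
) -> tuple[DosageMatrix, PhenotypeSet, CovariateMatrix | None]:
    """Align genotype, phenotype and covariate columns to the shared
    samples, in the genotype file's order. Covariates that become
    constant after intersection are dropped."""
    shared = set(g.sample_ids) & set(p.sample_ids)
    if c is not None:
        shared &= set(c.sample_ids)
    ordered = [s for s in g.sample_ids if s in shared]
    if len(ordered) < 3:
        raise ValueError(f"only {len(ordered)} shared samples; need at least 3")
    n_dropped = (
        len(set(g.sample_ids) | set(p.sample_ids) | (set(c.sample_ids) if c else set()))
        - len(ordered)
    )
    if n_dropped:
        logger.info("sample intersection dropped %d samples", n_dropped)

    gi = [g.sample_ids.index(s) for s in ordered]
    pi = [p.sample_ids.index(s) for s in ordered]
    g2 = DosageMatrix(
        chrom=g.chrom,
        variant_ids=g.variant_ids,
        positions=g.positions,
        dosages=g.dosages[:, gi],
        sample_ids=ordered,
        n_monomorphic_dropped=g.n_monomorphic_dropped,
    )
    p2 = PhenotypeSet(
        phenotype_ids=p.phenotype_ids,
        chroms=p.chroms,
        starts=p.starts,
        ends=p.ends,
        values=p.values[:, pi],
        sample_ids=ordered,
    )
    c2 = None
    if c is not None:
        ci = [c.sample_ids.index(s) for s in ordered]
        vals = c.values[:, ci]
        keep = vals.std(axis=1) > 0
        if not keep.all():
            logger.warning(
                "dropped %d covariates constant after sample intersection",
                int((~keep).sum()),
            )
        c2 = CovariateMatrix(
            covariate_ids=[cid for cid, k in zip(c.covariate_ids, keep) if k],
            values=vals[keep],
            sample_ids=ordered,
        )
    return g2, p2, c2


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.6g}"


def write_results(records, out_path: str | Path) -> None:
    """Write one space-separated row per phenotype, no header:

    phenotype_id n_variants_tested k_hat n_hat best_variant_id
    distance_to_anchor nominal_p slope direct_perm_p beta_perm_p

    Missing scheme outputs are written as NA. Output is gzipped when the
    path ends in ``.gz``; concatenating per-chunk files therefore equals
    a single whole-run file.
    """
    out_path = Path(out_path)
    opener = gzip.open if str(out_path).endswith(".gz") else open
    with opener(out_path, "wt") as fh:
        for r in records:
            fields = [
                r.phenotype_id,
                str(int(r.n_tested)),
                _fmt(r.k_hat),
                _fmt(r.n_hat),
                r.best_variant_id if r.best_variant_id is not None else "NA",
                _fmt(r.distance),
                _fmt(r.nominal_p),
                _fmt(r.slope),
                _fmt(r.perm_p),
                _fmt(r.beta_p),
            ]
            fh.write(" ".join(fields) + "\n")
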