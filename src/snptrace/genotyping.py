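"""Allele counting at panel loci from aligned reads, and genotype calling.

Per sample and per panel SNP, reads passing mapping- and base-quality
filters are split into reference-, alternative- and other-base support;
VAF = alt / (ref + alt) and a discrete genotype (hom-ref / het / hom-alt)
is called from VAF once depth is sufficient. Duplicate, secondary,
supplementary, unmapped and QC-fail reads are excluded; overlapping mate
pairs are counted once per fragment (pysam's overlap detection).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SnpLocus, SnpPanel

logger = logging.getLogger(__name__)

# excluded alignment flags: UNMAP | SECONDARY | QCFAIL | DUP | SUPPLEMENTARY
_FLAG_FILTER = 0x4 | 0x100 | 0x200 | 0x400 | 0x800


class GenotypeCall(IntEnum):
    """Discrete diploid genotype at a biallelic SNP."""

    NO_CALL = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


@dataclass(frozen=True, slots=True)
class QualityConfig:
    """Read-filtering and genotype-discretisation thresholds.

    min_depth: informative reads (ref+alt) required for a call.
    min_mapq / min_baseq: per-read and per-base quality floors.
    het_low / het_high: VAF window called heterozygous; below is hom-ref,
    above is hom-alt. The window mirrors the panel's population-AF window
    and the canonical germline VAF anchors {0, 0.5, 1}.
    """

    min_depth: int = 30
    min_mapq: int = 10
    min_baseq: int = 20
    het_low: float = 0.1
    het_high: float = 0.9

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.het_low < self.het_high < 1.0:
            raise ValueError("need 0 < het_low < het_high < 1")


@dataclass(frozen=True, slots=True)
class SnpReadcount:
    """Filtered read support at one panel locus."""

    locus: SnpLocus
    ref_count: int
    alt_count: int
    other_count: int = 0

    @property
    def depth(self) -> int:
        """Informative depth: ref + alt reads (other bases excluded)."""
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float | None:
        """Alternative allele fraction; None at zero informative depth."""
        if self.depth == 0:
            return None
        return self.alt_count / self.depth


def call_genotype(ref_count: int, alt_count: int, quality: QualityConfig | None = None) -> GenotypeCall:
    """Call a discrete genotype from ref/alt read counts.

    Depth below ``min_depth`` gives NO_CALL; otherwise the VAF is binned at
    het_low/het_high. Monotone in VAF at fixed depth.
    """
    quality = quality or QualityConfig()
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_count + alt_count
    if depth < quality.min_depth:
        return GenotypeCall.NO_CALL
    vaf = alt_count / depth
    if vaf < quality.het_low:
        return GenotypeCall.HOM_REF
    if vaf > quality.het_high:
        return GenotypeCall.HOM_ALT
    return GenotypeCall.HET


def call_genotypes_array(
    ref_counts: np.ndarray, alt_counts: np.ndarray, quality: QualityConfig | None = None
) -> np.ndarray:
    """Vectorised :func:`call_genotype` over per-locus count arrays (int8)."""
    quality = quality or QualityConfig()
    ref = np.asarray(ref_counts, dtype=np.int64)
    alt = np.asarray(alt_counts, dtype=np.int64)
    depth = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    out = np.full(ref.shape, int(GenotypeCall.HET), dtype=np.int8)
    out[vaf < quality.het_low] = int(GenotypeCall.HOM_REF)
    out[vaf > quality.het_high] = int(GenotypeCall.HOM_ALT)
    out[depth < quality.min_depth] = int(GenotypeCall.NO_CALL)
    return out


@dataclass(frozen=True)
class SampleProfile:
    """Per-sample read counts, VAFs and genotype calls across a panel.

    Arrays align with ``panel.loci``. ``vafs`` holds NaN where informative
    depth is zero.
    """

    sample_id: str
    panel: SnpPanel
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    other_counts: np.ndarray
    genotypes: np.ndarray  # int8 of GenotypeCall values

    def __post_init__(self) -> None:
        n = len(self.panel)
        for arr in (self.ref_counts, self.alt_counts, self.other_counts, self.genotypes):
            if len(arr) != n:
                raise ValueError("per-locus arrays must match panel size")

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        panel: SnpPanel,
        ref_counts,
        alt_counts,
        other_counts=None,
        quality: QualityConfig | None = None,
    ) -> "SampleProfile":
        ref = np.asarray(ref_counts, dtype=np.int64)
        alt = np.asarray(alt_counts, dtype=np.int64)
        other = (
            np.zeros(len(panel), dtype=np.int64)
            if other_counts is None
            else np.asarray(other_counts, dtype=np.int64)
        )
        return cls(
            sample_id=sample_id,
            panel=panel,
            ref_counts=ref,
            alt_counts=alt,
            other_counts=other,
            genotypes=call_genotypes_array(ref, alt, quality),
        )

    @property
    def depths(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    @property
    def vafs(self) -> np.ndarray:
        depth = self.depths
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(depth > 0, self.alt_counts / np.maximum(depth, 1), np.nan)

    @property
    def readcounts(self) -> list[SnpReadcount]:
        return [
            SnpReadcount(
                locus=locus,
                ref_count=int(self.ref_counts[i]),
                alt_count=int(self.alt_counts[i]),
                other_count=int(self.other_counts[i]),
            )
            for i, locus in enumerate(self.panel)
        ]

    def subset(self, indices, quality: QualityConfig | None = None) -> "SampleProfile":
        """Profile restricted to the given locus indices (same sample).

        Genotypes are carried over, not re-called, so subsetting commutes
        with calling.
        """
        idx = np.asarray(sorted(indices), dtype=np.int64)
        return SampleProfile(
            sample_id=self.sample_id,
            panel=self.panel.subset(idx),
            ref_counts=self.ref_counts[idx],
            alt_counts=self.alt_counts[idx],
            other_counts=self.other_counts[idx],
            genotypes=self.genotypes[idx],
        )

    def rename(self, sample_id: str) -> "SampleProfile":
        return SampleProfile(
            sample_id=sample_id,
            panel=self.panel,
            ref_counts=self.ref_counts,
            alt_counts=self.alt_counts,
            other_counts=self.other_counts,
            genotypes=self.genotypes,
        )


def extract_readcounts(
    alignment_path: str | Path,
    panel: SnpPanel,
    quality: QualityConfig | None = None,
    sample_id: str | None = None,
) -> SampleProfile:
    """Count ref/alt/other bases at every panel locus of one BAM file.

    The BAM must be coordinate-sorted and indexed. Reads flagged duplicate,
    secondary, supplementary, unmapped or QC-fail are skipped, as are reads
    below ``min_mapq`` and bases below ``min_baseq``; overlapping mates
    contribute once. Panel chromosomes absent from the BAM header yield
    depth 0 / NO_CALL with a warning; if *no* panel chromosome is present
    the chromosome naming is considered incompatible and an error is raised.
    """
    import pysam

    quality = quality or QualityConfig()
    path = Path(alignment_path)
    sample_id = sample_id or path.stem

    with pysam.AlignmentFile(str(path), "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(f"{path}: BAM index (.bai) not found")
        references = set(bam.references)
        panel_chroms = set(panel.chromosomes())
        if panel_chroms and not panel_chroms & references:
            raise ValueError(
                f"{path}: chromosome naming mismatch — none of the panel "
                f"chromosomes {sorted(panel_chroms)} occur in the BAM header"
            )
        missing = panel_chroms - references
        for chrom in sorted(missing):
            logger.warning(
                "%s: chromosome %s not in BAM; its loci get zero depth", path.name, chrom
            )

        n = len(panel)
        ref_counts = np.zeros(n, dtype=np.int64)
        alt_counts = np.zeros(n, dtype=np.int64)
        other_counts = np.zeros(n, dtype=np.int64)
        for i, locus in enumerate(panel):
            if locus.chrom in missing:
                continue
            for column in bam.pileup(
                locus.chrom,
                locus.pos - 1,
                locus.pos,
                truncate=True,
                stepper="samtools",
                min_base_quality=quality.min_baseq,
                min_mapping_quality=quality.min_mapq,
                flag_filter=_FLAG_FILTER,
                ignore_overlaps=True,
                max_depth=1_000_000,
            ):
                for pread in column.pileups:
                    if pread.is_del or pread.is_refskip or pread.query_position is None:
                        continue
                    base = pread.alignment.query_sequence[pread.query_position].upper()
                    if base == locus.ref_allele:
                        ref_counts[i] += 1
                    elif base == locus.alt_allele:
                        alt_counts[i] += 1
                    else:
                        other_counts[i] += 1

    return SampleProfile.from_counts(
        sample_id, panel, ref_counts, alt_counts, other_counts, quality=quality
    )


def write_readcounts_table(
    profiles: list[SampleProfile],
    suffix: str,
    timestamp: str,
    outdir: str | Path = ".",
) -> Path:
    """Write the per-sample, per-SNP readcount CSV.

    File name: ``SNP_readcounts_[suffix]_[timestamp].csv``. One row per
    (sample, locus) with counts, VAF (3 decimals, empty when undefined) and
    the discrete genotype.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"SNP_readcounts_{suffix}_{timestamp}.csv"
    if profiles:
        ref_panel = profiles[0].panel
        for p in profiles[1:]:
            if p.panel.site_keys != ref_panel.site_keys:
                raise ValueError("all profiles must share one panel")
    else:
        logger.warning("no profiles given; writing header-only readcounts table")
    rows = []
    for profile in profiles:
        vafs = profile.vafs
        for i, locus in enumerate(profile.panel):
            vaf = vafs[i]
            rows.append(
                {
                    "sample_id": profile.sample_id,
                    "rsid": locus.rsid,
                    "chrom": locus.chrom,
                    "pos": locus.pos,
                    "ref": locus.ref_allele,
                    "alt": locus.alt_allele,
                    "ref_count": int(profile.ref_counts[i]),
                    "alt_count": int(profile.alt_counts[i]),
                    "other_count": int(profile.other_counts[i]),
                    "vaf": "" if math.isnan(vaf) else f"{vaf:.3f}",
                    "genotype": GenotypeCall(int(profile.genotypes[i])).name,
                }
            )
    columns = [
        "sample_id", "rsid", "chrom", "pos", "ref", "alt",
        "ref_count", "alt_count", "other_count", "vaf", "genotype",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


def read_readcounts_table(path: str | Path, panel: SnpPanel,
                          quality: QualityConfig | None = None) -> list[SampleProfile]:
    """Rebuild sample profiles from a ``SNP_readcounts_*.csv`` file.

    Genotypes are re-called from the stored counts under ``quality`` so a
    table produced with one threshold set can be re-analysed under another.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "rsid": str})
    key_to_idx = {(l.chrom, int(l.pos)): i for i, l in enumerate(panel)}
    profiles: list[SampleProfile] = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        ref = np.zeros(len(panel), dtype=np.int64)
        alt = np.zeros(len(panel), dtype=np.int64)
        other = np.zeros(len(panel), dtype=np.int64)
        for row in sub.itertuples():
            try:
                i = key_to_idx[(row.chrom, int(row.pos))]
            except KeyError as exc:
                raise ValueError(
                    f"{path}: locus {row.chrom}:{row.pos} not in panel"
                ) from exc
            ref[i] = int(row.ref_count)
            alt[i] = int(row.alt_count)
            other[i] = int(getattr(row, "other_count", 0) or 0)
        profiles.append(
            SampleProfile.from_counts(str(sample_id), panel, ref, alt, other, quality=quality)
        )
    return profiles
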