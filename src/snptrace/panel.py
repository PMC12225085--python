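"""SNP fingerprint panels and the selection pipeline that builds them.

A fingerprint panel is a small set of common germline SNPs that together
identify the donor of a sequenced sample. Because targeted NGS covers only a
few hundred kilobases, generic genome-wide SNP lists barely intersect a given
gene panel, so the panel has to be derived from the cohort's own data: start
from the single-nucleotide variants an analysis pipeline would normally
discard (intronic, synonymous, known benign), keep the ones that are common
in the population (AF window), drop recurrent technical artefacts and
near-private SNPs, and finally prune linkage-disequilibrium groups down to
one maximally informative representative each.

Coordinates are 1-based internally; panel files on disk are BED-like
(0-based, half-open), columns chrom / start / end / rsid / ref / alt with
optional genome- and exome-AF columns.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: name of the bundled default 28-SNP panel (synthetic coordinates)
DEFAULT_PANEL_RESOURCE = "panel28.synthetic.bed"


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


@dataclass(frozen=True, slots=True)
class SnpLocus:
    """One biallelic fingerprint SNP.

    ``pop_af`` / ``pop_af_exome`` are the population alternative-allele
    frequencies from a genome- and an exome-derived database respectively;
    either may be absent.
    """

    rsid: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    pop_af: float | None = None
    pop_af_exome: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"{self.rsid}: alleles must be single uppercase bases, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        for af in (self.pop_af, self.pop_af_exome):
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"{self.rsid}: allele frequency {af} outside [0, 1]")

    @property
    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos)

    @property
    def afs(self) -> tuple[float, ...]:
        """The available population AF annotations (0, 1 or 2 values)."""
        return tuple(a for a in (self.pop_af, self.pop_af_exome) if a is not None)


@dataclass(frozen=True)
class SnpPanel:
    """An ordered, duplicate-free set of fingerprint loci.

    Loci are kept in canonical genomic order (chromosome, then position)
    regardless of input order, so panel files and per-locus vectors are
    always comparable across samples.
    """

    loci: tuple[SnpLocus, ...]
    name: str = "panel"

    def __init__(self, loci: Iterable[SnpLocus], name: str = "panel") -> None:
        ordered = tuple(sorted(loci, key=lambda l: l.sort_key))
        seen: set[tuple[str, int]] = set()
        for locus in ordered:
            key = (locus.chrom, locus.pos)
            if key in seen:
                raise ValueError(f"duplicate panel locus at {locus.chrom}:{locus.pos}")
            seen.add(key)
        object.__setattr__(self, "loci", ordered)
        object.__setattr__(self, "name", name)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, i: int) -> SnpLocus:
        return self.loci[i]

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(l.rsid for l in self.loci)

    @property
    def site_keys(self) -> tuple[tuple[str, int, str, str], ...]:
        """(chrom, pos, ref, alt) per locus — the identity used to compare panels."""
        return tuple((l.chrom, l.pos, l.ref_allele, l.alt_allele) for l in self.loci)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "SnpPanel":
        """Panel restricted to the given locus indices (order re-canonicalised)."""
        return SnpPanel(
            (self.loci[i] for i in indices),
            name=name or f"{self.name}[{len(indices)}]",
        )

    def chromosomes(self) -> tuple[str, ...]:
        out: list[str] = []
        for locus in self.loci:
            if locus.chrom not in out:
                out.append(locus.chrom)
        return tuple(out)


def _parse_af(token: str) -> float | None:
    token = token.strip()
    if token in ("", ".", "NA", "nan"):
        return None
    return float(token)


def load_panel(path: str | Path, name: str | None = None) -> SnpPanel:
    """Read a SNP panel from a BED-like TSV file.

    Expected columns: chrom, start (0-based), end, rsid, ref, alt, with
    optional 7th/8th columns holding genome/exome population AFs. Lines
    starting with ``#`` are comments. Each record must describe a single
    base (end == start + 1); internal positions are 1-based (pos = start + 1).
    """
    path = Path(path)
    loci: list[SnpLocus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}, line {lineno}: expected >= 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, rsid, ref, alt = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-integer coordinates") from exc
            if end != start + 1:
                raise ValueError(
                    f"{path}, line {lineno}: not a single-base locus "
                    f"(end {end} != start {start} + 1)"
                )
            af = _parse_af(fields[6]) if len(fields) > 6 else None
            af_ex = _parse_af(fields[7]) if len(fields) > 7 else None
            try:
                loci.append(
                    SnpLocus(
                        rsid=rsid,
                        chrom=chrom,
                        pos=start + 1,
                        ref_allele=ref.upper(),
                        alt_allele=alt.upper(),
                        pop_af=af,
                        pop_af_exome=af_ex,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    if not loci:
        logger.warning("panel file %s contains no loci", path)
    return SnpPanel(loci, name=name or path.stem)


def write_panel(panel: SnpPanel, path: str | Path) -> Path:
    """Write a panel as a BED-like TSV (0-based half-open coordinates).

    Round-trips through :func:`load_panel` to an equal panel.
    """
    path = Path(path)
    has_af = any(l.pop_af is not None or l.pop_af_exome is not None for l in panel)
    with open(path, "w") as fh:
        fh.write("# SNP fingerprint panel: chrom\tstart(0-based)\tend\trsid\tref\talt")
        fh.write("\taf_genome\taf_exome\n" if has_af else "\n")
        for l in panel:
            row = [l.chrom, str(l.pos - 1), str(l.pos), l.rsid, l.ref_allele, l.alt_allele]
            if has_af:
                row.append("." if l.pop_af is None else f"{l.pop_af:g}")
                row.append("." if l.pop_af_exome is None else f"{l.pop_af_exome:g}")
            fh.write("\t".join(row) + "\n")
    return path


def default_panel() -> SnpPanel:
    """The bundled 28-SNP demonstration panel.

    The rsIDs are a published CLL targeted-panel fingerprint set; the
    coordinates, alleles and allele frequencies in the bundled file are
    synthetic stand-ins (small per-chromosome coordinates so miniature
    alignment fixtures stay tiny).
    """
    from importlib.resources import as_file, files

    resource = files("snptrace.data").joinpath(DEFAULT_PANEL_RESOURCE)
    with as_file(resource) as p:
        return load_panel(p, name="panel28")


# ---------------------------------------------------------------------------
# Cohort variant matrix and the selection pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortVariantMatrix:
    """Candidate variants x samples VAF table driving panel selection.

    ``vaf`` rows align with ``variants``; NaN marks a variant not detected in
    a sample.
    """

    variants: tuple[SnpLocus, ...]
    vaf: pd.DataFrame  # index: rsid, columns: sample ids, values in [0,1] or NaN

    def __post_init__(self) -> None:
        if len(self.variants) != len(self.vaf):
            raise ValueError("variant list and VAF table have different lengths")
        values = self.vaf.to_numpy(dtype=float)
        present = ~np.isnan(values)
        if present.any() and ((values[present] < 0) | (values[present] > 1)).any():
            raise ValueError("VAF values outside [0, 1]")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.vaf.columns)

    @property
    def n_samples(self) -> int:
        return self.vaf.shape[1]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortVariantMatrix":
        """Read the TSV interchange format.

        Leading columns chrom, pos, ref, alt, rsid, af_genome, af_exome;
        every remaining column is one sample's VAF ('.' = not detected).
        """
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        meta_cols = ["chrom", "pos", "ref", "alt", "rsid", "af_genome", "af_exome"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        sample_cols = [c for c in df.columns if c not in meta_cols]
        variants = tuple(
            SnpLocus(
                rsid=row.rsid,
                chrom=row.chrom,
                pos=int(row.pos),
                ref_allele=row.ref,
                alt_allele=row.alt,
                pop_af=_parse_af(row.af_genome) if isinstance(row.af_genome, str) else None,
                pop_af_exome=_parse_af(row.af_exome) if isinstance(row.af_exome, str) else None,
            )
            for row in df.itertuples()
        )
        vaf = (
            df[sample_cols]
            .replace(".", np.nan)
            .astype(float)
            .set_axis(df["rsid"], axis=0)
        )
        return cls(variants=variants, vaf=vaf)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        meta = pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref_allele for v in self.variants],
                "alt": [v.alt_allele for v in self.variants],
                "rsid": [v.rsid for v in self.variants],
                "af_genome": ["." if v.pop_af is None else f"{v.pop_af:g}" for v in self.variants],
                "af_exome": [
                    "." if v.pop_af_exome is None else f"{v.pop_af_exome:g}"
                    for v in self.variants
                ],
            }
        )
        body = self.vaf.reset_index(drop=True).copy()
        out = pd.concat([meta, body], axis=1)
        out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.4f")
        return path

    def variant_by_rsid(self, rsid: str) -> SnpLocus:
        for v in self.variants:
            if v.rsid == rsid:
                return v
        raise KeyError(rsid)


@dataclass(frozen=True)
class LinkageGroups:
    """Partition of correlated (linkage-disequilibrium) candidate SNPs.

    Only grouped rsids are listed; any candidate not mentioned is implicitly
    its own singleton group. Groups come precomputed (e.g. from pairwise r²
    against a reference population) — this package does not estimate LD.
    """

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.groups:
            for rsid in group:
                if rsid in seen:
                    raise ValueError(f"rsid {rsid} appears in more than one linkage group")
                seen.add(rsid)

    @property
    def grouped_rsids(self) -> frozenset[str]:
        return frozenset(r for g in self.groups for r in g)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LinkageGroups":
        """Read TSV with columns group_id, rsid."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if not {"group_id", "rsid"}.issubset(df.columns):
            raise ValueError(f"{path}: need columns group_id and rsid")
        groups = [
            tuple(sub["rsid"]) for _, sub in df.groupby("group_id", sort=True)
        ]
        return cls(groups=tuple(groups))


def filter_by_population_af(
    candidates: Sequence[SnpLocus],
    af_min: float = 0.1,
    af_max: float = 0.9,
) -> list[SnpLocus]:
    """Keep candidates common enough to discriminate between individuals.

    A candidate passes if at least one of its population AF annotations lies
    in the inclusive window [af_min, af_max]; rare and near-fixed SNPs carry
    little identity information. Candidates without any AF annotation cannot
    be assessed and are dropped with a warning.
    """
    if not 0.0 <= af_min < af_max <= 1.0:
        raise ValueError(f"invalid AF window [{af_min}, {af_max}]")
    kept: list[SnpLocus] = []
    for cand in candidates:
        afs = cand.afs
        if not afs:
            logger.warning("%s has no population AF annotation; excluded", cand.rsid)
            continue
        if any(af_min <= a <= af_max for a in afs):
            kept.append(cand)
    return kept


def flag_artefacts(
    matrix: CohortVariantMatrix,
    vaf_sd_max: float = 0.05,
    carrier_frac_min: float = 0.9,
) -> set[str]:
    """Flag recurrent technical artefacts.

    A real germline SNP segregates: its per-sample VAFs cluster around 0,
    0.5 and 1 across carriers. A "variant" observed in nearly every sample
    at nearly the same VAF is a systematic artefact of the assay. Flagged:
    present in >= carrier_frac_min of samples AND sd of the present VAFs
    <= vaf_sd_max.
    """
    if len(matrix.variants) == 0:
        return set()
    if matrix.n_samples < 2:
        raise ValueError("artefact detection needs at least 2 samples")
    values = matrix.vaf.to_numpy(dtype=float)
    present = ~np.isnan(values)
    carrier_frac = present.mean(axis=1)
    sds = pd.DataFrame(values).std(axis=1, ddof=1).to_numpy()  # NaN-skipping
    with np.errstate(invalid="ignore"):
        flagged = (carrier_frac >= carrier_frac_min) & (sds <= vaf_sd_max)
    return {v.rsid for v, f in zip(matrix.variants, flagged) if f}


def filter_low_prevalence(
    matrix: CohortVariantMatrix,
    min_carrier_frac: float = 0.05,
    het_low: float = 0.1,
) -> list[SnpLocus]:
    """Drop true SNPs carried by too few cohort samples.

    A SNP observed in a handful of samples contributes almost no pairwise
    discrimination. Carrier = sample with recorded VAF >= het_low (the
    lower heterozygous bound). Keeps variants with carrier fraction >=
    min_carrier_frac, input order preserved.
    """
    if len(matrix.variants) == 0:
        return []
    values = matrix.vaf.to_numpy(dtype=float)
    carriers = np.nan_to_num(values, nan=-1.0) >= het_low
    frac = carriers.mean(axis=1)
    return [v for v, f in zip(matrix.variants, frac) if f >= min_carrier_frac]


def mean_cohort_vaf(matrix: CohortVariantMatrix) -> dict[str, float]:
    """Mean of the present (non-NaN) VAFs per variant, keyed by rsid."""
    means = matrix.vaf.mean(axis=1, skipna=True)
    return {v.rsid: float(means.iloc[i]) for i, v in enumerate(matrix.variants)}


def prune_linkage_groups(
    candidates: Sequence[SnpLocus],
    groups: LinkageGroups,
    cohort_vaf: Mapping[str, float],
) -> SnpPanel:
    """Collapse each linkage group to its most informative member.

    Correlated SNPs carry redundant identity information; from each group the
    SNP whose mean cohort VAF is closest to 0.5 (maximal heterozygosity,
    hence maximal information) is retained. Ties break to the lowest genomic
    coordinate so the result is reproducible. Ungrouped candidates are all
    retained.
    """
    by_rsid = {c.rsid: c for c in candidates}
    missing = sorted(groups.grouped_rsids - by_rsid.keys())
    if missing:
        raise ValueError(f"linkage groups reference rsids absent from candidates: {missing}")
    grouped = groups.grouped_rsids
    kept: list[SnpLocus] = [c for c in candidates if c.rsid not in grouped]
    for group in groups.groups:
        members = [by_rsid[r] for r in group]
        best = min(
            members,
            key=lambda m: (abs(cohort_vaf.get(m.rsid, 0.0) - 0.5), m.sort_key),
        )
        kept.append(best)
    return SnpPanel(kept, name="pruned")


@dataclass(frozen=True)
class PanelSelectionReport:
    """Final panel plus per-stage candidate counts (for the run log)."""

    panel: SnpPanel
    stages: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def format_log(self) -> str:
        lines = [f"{stage}: {count} candidates" for stage, count in self.stages]
        lines.append(f"final panel: {len(self.panel)} SNPs")
        return "\n".join(lines)


def select_panel(
    matrix: CohortVariantMatrix,
    groups: LinkageGroups,
    af_min: float = 0.1,
    af_max: float = 0.9,
    artefact_sd: float = 0.05,
    artefact_carrier: float = 0.9,
    min_carrier: float = 0.05,
    het_low: float = 0.1,
    name: str = "selected",
) -> PanelSelectionReport:
    """Run the full selection pipeline from cohort matrix to pruned panel.

    Stages: population-AF window -> artefact removal -> prevalence filter ->
    linkage-group pruning. Pure function of its inputs: identical inputs and
    thresholds give the identical panel.
    """
    stages: list[tuple[str, int]] = [("input candidates", len(matrix.variants))]

    by_af = filter_by_population_af(matrix.variants, af_min=af_min, af_max=af_max)
    stages.append(("after population-AF filter", len(by_af)))

    artefacts = flag_artefacts(matrix, vaf_sd_max=artefact_sd, carrier_frac_min=artefact_carrier)
    no_artefacts = [v for v in by_af if v.rsid not in artefacts]
    stages.append(("after artefact removal", len(no_artefacts)))

    keep_rsids = {v.rsid for v in no_artefacts}
    prevalent_all = filter_low_prevalence(matrix, min_carrier_frac=min_carrier, het_low=het_low)
    survivors = [v for v in prevalent_all if v.rsid in keep_rsids]
    stages.append(("after prevalence filter", len(survivors)))

    surv_rsids = {v.rsid for v in survivors}
    effective_groups = LinkageGroups(
        groups=tuple(
            g for g in (tuple(r for r in grp if r in surv_rsids) for grp in groups.groups)
            if len(g) >= 1
        )
    )
    panel = prune_linkage_groups(survivors, effective_groups, mean_cohort_vaf(matrix))
    panel = SnpPanel(panel.loci, name=name)
    return PanelSelectionReport(panel=panel, stages=tuple(stages))
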