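"""Synthetic cohorts with planted sample-handling errors.

Generates the inputs the rest of the package consumes without any patient
data: diploid genotypes drawn per SNP under Hardy–Weinberg equilibrium from
the panel's population allele frequencies, read counts drawn per locus with
negative-binomial depth and binomial allele sampling, and a configurable set
of planted handling errors — label swaps, mislabels, cross-sample
contamination and copy-number-like VAF shifts — together with a truth
ledger of the sample pairs those errors imply.

Sample names follow ``CLL-<patientid>-<runid>-TP<k>`` so the default
patient-id extraction (first run of digits) works out of the box.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cohort import DEFAULT_ID_PATTERN, PlantedTruth
from .genotyping import GenotypeCall, QualityConfig, SampleProfile
from .panel import SnpPanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Planted-error specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Swap:
    """Exchange the labels of two samples (the classic sample swap)."""

    sample_a: str
    sample_b: str


@dataclass(frozen=True, slots=True)
class Mislabel:
    """Rewrite one sample's patient label (keeps run-id and timepoint parts)."""

    sample: str
    new_patient_label: str


@dataclass(frozen=True, slots=True)
class Contaminate:
    """Mix a fraction of another sample's DNA into one sample's reads."""

    sample: str
    donor: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 0.5:
            raise ValueError("contamination fraction must be in (0, 0.5]")


@dataclass(frozen=True, slots=True)
class CnaShift:
    """Shift heterozygous VAFs on one chromosome, emulating a copy-number
    aberration that changes clone size between timepoints."""

    sample: str
    chrom: str
    vaf_delta: float


ErrorSpec = Swap | Mislabel | Contaminate | CnaShift


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic cohort.

    mean_depth / depth_dispersion parametrise a negative-binomial depth per
    locus (variance = m + m^2/k; the default k is effectively Poisson);
    base_error_rate is the per-read probability of reading the wrong allele.
    """

    panel: SnpPanel
    n_patients: int
    timepoints: int = 2
    mean_depth: float = 100.0
    depth_dispersion: float = 1000.0
    base_error_rate: float = 0.001
    seed: int = 1
    planted_errors: tuple[ErrorSpec, ...] = ()
    quality: QualityConfig = field(default_factory=QualityConfig)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in [0, 0.5)")


def patient_label(index: int) -> str:
    """Deterministic 8-digit patient identifier for patient ``index``."""
    return f"{10000000 + index:08d}"


def sample_name(patient_index: int, timepoint: int) -> str:
    """Canonical sample name for (patient, timepoint), both 0-based."""
    return (
        f"CLL-{patient_label(patient_index)}-"
        f"{timepoint + 1:02d}S{patient_index:05d}-TP{timepoint + 1}"
    )


# ---------------------------------------------------------------------------
# Genotype and readcount simulation
# ---------------------------------------------------------------------------


def simulate_genotypes(panel: SnpPanel, n_patients: int, seed: int) -> np.ndarray:
    """Draw diploid genotypes under Hardy–Weinberg equilibrium.

    Per patient and locus the genotype is HOM_REF / HET / HOM_ALT with
    probabilities (1-p)^2, 2p(1-p), p^2 for p = the locus population AF.
    Returns an (n_patients, n_loci) int8 matrix of GenotypeCall values.
    """
    p = []
    for locus in panel:
        if locus.pop_af is None:
            raise ValueError(f"{locus.rsid}: pop_af required for genotype simulation")
        p.append(locus.pop_af)
    p = np.asarray(p, dtype=float)
    rng = np.random.default_rng(seed)
    u = rng.random((n_patients, len(panel)))
    hom_ref = (1.0 - p) ** 2
    het = 2.0 * p * (1.0 - p)
    g = (u >= hom_ref).astype(np.int8) + (u >= hom_ref + het).astype(np.int8)
    return g


#: expected alternative-allele fraction per genotype, given error rate e
def _expected_alt_fraction(genotypes: np.ndarray, error_rate: float) -> np.ndarray:
    mu = np.empty(genotypes.shape, dtype=float)
    mu[genotypes == int(GenotypeCall.HOM_REF)] = error_rate
    mu[genotypes == int(GenotypeCall.HET)] = 0.5
    mu[genotypes == int(GenotypeCall.HOM_ALT)] = 1.0 - error_rate
    return mu


def _draw_depths(rng: np.random.Generator, shape, mean: float, dispersion: float) -> np.ndarray:
    # NB with mean m, size k: p = k/(k+m); variance m + m^2/k
    k = float(dispersion)
    return rng.negative_binomial(k, k / (k + mean), size=shape)


def simulate_readcounts(
    genotypes: np.ndarray, config: SimConfig
) -> list[SampleProfile]:
    """Simulate one profile per (patient, timepoint) from true genotypes.

    Timepoints of one patient share the genotype row but get independent
    depth and allele-sampling noise. Depth ~ NegBin(mean_depth,
    depth_dispersion); alt reads ~ Binomial(depth, mu) with mu = e, 0.5,
    1-e for hom-ref / het / hom-alt and e = base_error_rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    n_patients, n_loci = genotypes.shape
    mu = _expected_alt_fraction(genotypes, config.base_error_rate)
    profiles: list[SampleProfile] = []
    for pidx in range(n_patients):
        for t in range(config.timepoints):
            depth = _draw_depths(rng, n_loci, config.mean_depth, config.depth_dispersion)
            alt = rng.binomial(depth, mu[pidx])
            ref = depth - alt
            profiles.append(
                SampleProfile.from_counts(
                    sample_name(pidx, t), config.panel, ref, alt, quality=config.quality
                )
            )
    return profiles


# ---------------------------------------------------------------------------
# Cohort container and error planting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohort:
    """Profiles plus ground truth of a simulated cohort.

    ``donors[i]`` is the patient index whose DNA profile ``profiles[i]``
    actually contains — label-level planted errors change sample names but
    never this assignment (contamination/CNA shifts perturb counts, not the
    donor). The truth ledger of implied pairs is derived from (donor,
    labelled patient id) for every profile pair.
    """

    config: SimConfig
    genotypes: np.ndarray  # patients x loci, true genotypes
    profiles: tuple[SampleProfile, ...]
    donors: tuple[int, ...]
    planted: tuple[ErrorSpec, ...] = ()
    id_pattern: str = DEFAULT_ID_PATTERN

    def __post_init__(self) -> None:
        if len(self.profiles) != len(self.donors):
            raise ValueError("profiles and donors must align")
        names = [p.sample_id for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")

    def profile_index(self, sample_id: str) -> int:
        for i, p in enumerate(self.profiles):
            if p.sample_id == sample_id:
                return i
        raise KeyError(f"no sample named {sample_id}")

    def _labelled_pid(self, sample_id: str) -> str | None:
        m = re.search(self.id_pattern, sample_id)
        return m.group(1) if m else None

    @property
    def truth(self) -> PlantedTruth:
        """Implied unexpected pairs and broken (discordant) expected pairs."""
        unexpected: set[frozenset[str]] = set()
        discordant: set[frozenset[str]] = set()
        n = len(self.profiles)
        for i in range(n):
            for j in range(i + 1, n):
                pid_i = self._labelled_pid(self.profiles[i].sample_id)
                pid_j = self._labelled_pid(self.profiles[j].sample_id)
                same_label = pid_i is not None and pid_i == pid_j
                same_donor = self.donors[i] == self.donors[j]
                pair = frozenset((self.profiles[i].sample_id, self.profiles[j].sample_id))
                if same_donor and not same_label:
                    unexpected.add(pair)
                elif same_label and not same_donor:
                    discordant.add(pair)
        return PlantedTruth(
            unexpected_pairs=frozenset(unexpected),
            discordant_expected_pairs=frozenset(discordant),
        )


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Full generator: genotypes -> readcounts -> planted errors."""
    genotypes = simulate_genotypes(config.panel, config.n_patients, config.seed)
    profiles = simulate_readcounts(genotypes, config)
    donors = tuple(
        pidx for pidx in range(config.n_patients) for _ in range(config.timepoints)
    )
    cohort = SyntheticCohort(
        config=config,
        genotypes=genotypes,
        profiles=tuple(profiles),
        donors=donors,
    )
    if config.planted_errors:
        cohort = plant_errors(cohort, config.planted_errors)
    return cohort


def _rewrite_patient_label(sample_id: str, new_label: str, pattern: str) -> str:
    m = re.search(pattern, sample_id)
    if not m:
        raise ValueError(f"cannot locate patient label in {sample_id!r}")
    return sample_id[: m.start(1)] + new_label + sample_id[m.end(1):]


def plant_errors(cohort: SyntheticCohort, specs) -> SyntheticCohort:
    """Apply handling-error specs to a cohort, returning a new cohort.

    Swaps exchange sample labels (data stays put); mislabels rewrite the
    patient-id portion of one name; contamination replaces a sample's
    counts with a resampled (1-f)/f mixture of its own and the donor's
    expected allele fractions at unchanged depths; CNA shifts move the
    expected het VAF on one chromosome. The true genotype matrix is never
    modified. A sample may appear in at most one swap.
    """
    specs = tuple(specs)
    if not specs:
        return cohort
    swapped: set[str] = set()
    for spec in specs:
        if isinstance(spec, Swap):
            for s in (spec.sample_a, spec.sample_b):
                if s in swapped:
                    raise ValueError(f"sample {s} appears in more than one swap")
                swapped.add(s)

    profiles = list(cohort.profiles)
    donors = list(cohort.donors)
    rng = np.random.default_rng(
        np.random.SeedSequence(cohort.config.seed, spawn_key=(2,))
    )

    def idx(sample_id: str) -> int:
        for i, p in enumerate(profiles):
            if p.sample_id == sample_id:
                return i
        raise KeyError(f"no sample named {sample_id}")

    e = cohort.config.base_error_rate
    for spec in specs:
        if isinstance(spec, Swap):
            ia, ib = idx(spec.sample_a), idx(spec.sample_b)
            name_a, name_b = profiles[ia].sample_id, profiles[ib].sample_id
            # labels move, DNA (and the aligned donor entry) stays put
            profiles[ia] = profiles[ia].rename(name_b)
            profiles[ib] = profiles[ib].rename(name_a)
        elif isinstance(spec, Mislabel):
            i = idx(spec.sample)
            new_name = _rewrite_patient_label(
                profiles[i].sample_id, spec.new_patient_label, cohort.id_pattern
            )
            profiles[i] = profiles[i].rename(new_name)
        elif isinstance(spec, Contaminate):
            i, j = idx(spec.sample), idx(spec.donor)
            mu_self = _expected_alt_fraction(cohort.genotypes[donors[i]], e)
            mu_donor = _expected_alt_fraction(cohort.genotypes[donors[j]], e)
            mu = (1.0 - spec.fraction) * mu_self + spec.fraction * mu_donor
            depth = profiles[i].depths
            alt = rng.binomial(depth, mu)
            profiles[i] = SampleProfile.from_counts(
                profiles[i].sample_id, profiles[i].panel, depth - alt, alt,
                quality=cohort.config.quality,
            )
        elif isinstance(spec, CnaShift):
            i = idx(spec.sample)
            true_g = cohort.genotypes[donors[i]]
            on_chrom = np.array(
                [l.chrom == spec.chrom for l in profiles[i].panel], dtype=bool
            )
            affected = on_chrom & (true_g == int(GenotypeCall.HET))
            mu = _expected_alt_fraction(true_g, e)
            mu[affected] = np.clip(0.5 + spec.vaf_delta, 0.0, 1.0)
            depth = profiles[i].depths
            alt = np.asarray(profiles[i].alt_counts).copy()
            alt[affected] = rng.binomial(depth[affected], mu[affected])
            profiles[i] = SampleProfile.from_counts(
                profiles[i].sample_id, profiles[i].panel, depth - alt, alt,
                quality=cohort.config.quality,
            )
        else:
            raise TypeError(f"unknown error spec: {spec!r}")

    return replace(
        cohort,
        profiles=tuple(profiles),
        donors=tuple(donors),
        planted=cohort.planted + specs,
    )


def validation_cohort_config(
    seed: int,
    n_patients: int = 200,
    panel: SnpPanel | None = None,
    mean_depth: float = 100.0,
    base_error_rate: float = 0.001,
) -> SimConfig:
    """Standard validation scenario: 2 timepoints per patient, 3 swaps of
    TP2 samples between patient pairs (0,1), (2,3), (4,5) and one mislabel
    of patient 0's TP1 to a fresh patient label.

    The planted errors imply exactly 6 unexpected same-donor pairs and 5
    broken expected pairs (the mislabel renames one swap-implied unexpected
    pair and removes one broken expected pair).
    """
    if panel is None:
        from .panel import default_panel

        panel = default_panel()
    planted: tuple[ErrorSpec, ...] = (
        Swap(sample_name(0, 1), sample_name(1, 1)),
        Swap(sample_name(2, 1), sample_name(3, 1)),
        Swap(sample_name(4, 1), sample_name(5, 1)),
        Mislabel(sample_name(0, 0), "99999999"),
    )
    return SimConfig(
        panel=panel,
        n_patients=n_patients,
        timepoints=2,
        mean_depth=mean_depth,
        base_error_rate=base_error_rate,
        seed=seed,
        planted_errors=planted,
    )


# ---------------------------------------------------------------------------
# Miniature BAM fixtures
# ---------------------------------------------------------------------------


def _build_reference(panel: SnpPanel, read_length: int, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    bases = np.frombuffer(b"ACGT", dtype="S1")
    ref: dict[str, np.ndarray] = {}
    for chrom in panel.chromosomes():
        loci = [l for l in panel if l.chrom == chrom]
        length = max(l.pos for l in loci) + read_length + 10
        seq = bases[rng.integers(0, 4, size=length)].copy()
        for l in loci:
            seq[l.pos - 1] = l.ref_allele.encode()
        ref[chrom] = seq
    return ref


def write_fixture_bams(
    cohort: SyntheticCohort,
    outdir: str | Path,
    read_length: int = 100,
    decoy_duplicates: int = 0,
) -> tuple[list[Path], Path]:
    """Materialise each profile as a coordinate-sorted, indexed miniature BAM.

    A synthetic reference (one small contig per panel chromosome) is written
    alongside as FASTA. Each read covers exactly one locus and carries the
    ref or alt base there, so a pileup reproduces the simulated ref/alt
    counts exactly. ``decoy_duplicates`` extra duplicate-flagged alt-carrying
    reads per locus exercise duplicate filtering. Panel loci closer together
    than ``read_length`` would let one locus's reads overlap another and
    distort its counts, so that spacing is rejected.
    """
    import pysam

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = cohort.config.panel
    for chrom in panel.chromosomes():
        positions = sorted(l.pos for l in panel if l.chrom == chrom)
        for a, b in zip(positions, positions[1:]):
            if b - a < read_length:
                raise ValueError(
                    f"panel loci {chrom}:{a} and {chrom}:{b} are closer than the "
                    f"read length ({read_length}); use a more widely spaced panel "
                    "or shorter reads"
                )

    reference = _build_reference(panel, read_length, cohort.config.seed)
    fasta_path = outdir / "reference.synthetic.fa"
    with open(fasta_path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            s = seq.tobytes().decode()
            for k in range(0, len(s), 60):
                fh.write(s[k : k + 60] + "\n")

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": int(len(seq))} for chrom, seq in reference.items()
        ],
    }
    tid = {chrom: i for i, chrom in enumerate(reference)}

    bam_paths: list[Path] = []
    for profile in cohort.profiles:
        bam_path = outdir / f"{profile.sample_id}.bam"
        tmp_path = outdir / f"{profile.sample_id}.unsorted.bam"
        with pysam.AlignmentFile(str(tmp_path), "wb", header=header) as bam:
            serial = 0
            for i, locus in enumerate(panel):
                seq = reference[locus.chrom]
                start0 = min(max(locus.pos - 1 - read_length // 2, 0),
                             len(seq) - read_length)
                offset = locus.pos - 1 - start0
                template = bytearray(seq[start0 : start0 + read_length].tobytes())
                counts = (
                    (locus.ref_allele, int(profile.ref_counts[i]), 0),
                    (locus.alt_allele, int(profile.alt_counts[i]), 0),
                    (locus.alt_allele, decoy_duplicates, 0x400),
                )
                for base, count, extra_flag in counts:
                    template[offset] = ord(base)
                    read_seq = template.decode()
                    for _ in range(count):
                        a = pysam.AlignedSegment()
                        a.query_name = f"{profile.sample_id}.{serial}"
                        serial += 1
                        a.query_sequence = read_seq
                        a.flag = extra_flag
                        a.reference_id = tid[locus.chrom]
                        a.reference_start = start0
                        a.mapping_quality = 60
                        a.cigarstring = f"{read_length}M"
                        a.query_qualities = pysam.qualitystring_to_array(
                            "I" * read_length
                        )
                        bam.write(a)
        pysam.sort("-o", str(bam_path), str(tmp_path))
        tmp_path.unlink()
        pysam.index(str(bam_path))
        bam_paths.append(bam_path)
    return bam_paths, fasta_path
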