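"""Cohort-level swap screening: all-vs-all scan, expected-pair checks,
report files, heatmap, panel-size sensitivity and contamination QC.

The scan compares every unordered pair of samples in a batch. Matching
pairs with *different* patient labels indicate a swap or mislabel;
*expected* pairs (same patient label, e.g. sequential timepoints) that fail
to match indicate the complementary half of the same mistakes. Outputs
mirror the three CSV reports and the correlation heatmap of the underlying
command-line workflow, with deterministic, injectable timestamps.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import (
    MatchStatus,
    MatchThresholds,
    PairComparison,
    classify_pair,
    vaf_correlation,
)
from .genotyping import GenotypeCall, SampleProfile

logger = logging.getLogger(__name__)

#: default patient-id extractor: first maximal run of digits in the name
DEFAULT_ID_PATTERN = r"(\d+)"

#: pairwise scans are quadratic; warn beyond this cohort size
MAX_SAMPLES_SOFT_LIMIT = 5000


class PairVerdict(str, Enum):
    CONCORDANT = "CONCORDANT"
    REVIEW = "REVIEW"
    DISCORDANT = "DISCORDANT"


@dataclass(frozen=True, slots=True)
class ExpectedPair:
    """An expected same-patient pair with its observed comparison."""

    x_id: str
    y_id: str
    patient_id: str
    observed: PairComparison
    verdict: PairVerdict


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of planted handling errors, as implied sample pairs."""

    unexpected_pairs: frozenset[frozenset[str]]
    discordant_expected_pairs: frozenset[frozenset[str]]


@dataclass(frozen=True)
class CohortScanResult:
    """All pairwise comparisons of one batch plus derived bookkeeping."""

    comparisons: tuple[PairComparison, ...]
    matches: tuple[PairComparison, ...]
    expected: tuple[ExpectedPair, ...]
    unexpected_matches: tuple[PairComparison, ...]
    sample_ids: tuple[str, ...]
    thresholds: MatchThresholds

    def comparison_for(self, x_id: str, y_id: str) -> PairComparison:
        key = frozenset((x_id, y_id))
        for c in self.comparisons:
            if c.sample_pair == key:
                return c
        raise KeyError(f"pair ({x_id}, {y_id}) was not scanned")

    @property
    def match_pairs(self) -> frozenset[frozenset[str]]:
        return frozenset(c.sample_pair for c in self.matches)


def extract_patient_id(sample_id: str, id_pattern: str = DEFAULT_ID_PATTERN) -> str | None:
    """Patient identifier captured by ``id_pattern``, or None."""
    m = re.search(id_pattern, sample_id)
    return m.group(1) if m else None


def derive_expected_pairs(
    sample_ids, id_pattern: str = DEFAULT_ID_PATTERN
) -> list[tuple[str, str, str]]:
    """All unordered sample pairs sharing a captured patient id.

    ``id_pattern`` must contain exactly one capturing group; by default the
    first maximal digit run in the name is the patient id. Samples whose
    name does not match are excluded with a warning.
    """
    if re.compile(id_pattern).groups < 1:
        raise ValueError(f"id pattern {id_pattern!r} has no capturing group")
    by_patient: dict[str, list[str]] = {}
    for sid in sample_ids:
        pid = extract_patient_id(sid, id_pattern)
        if pid is None:
            logger.warning("sample %s does not match id pattern %r; excluded", sid, id_pattern)
            continue
        by_patient.setdefault(pid, []).append(sid)
    pairs: list[tuple[str, str, str]] = []
    for pid, members in by_patient.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j], pid))
    return pairs


# ---------------------------------------------------------------------------
# The all-vs-all scan (vectorised)
# ---------------------------------------------------------------------------


def _pairwise_arrays(profiles: list[SampleProfile]):
    no_call = int(GenotypeCall.NO_CALL)
    G = np.stack([np.asarray(p.genotypes, dtype=np.int8) for p in profiles])
    V = G != no_call
    vaf = np.stack([p.vafs for p in profiles])
    X = np.where(V, np.nan_to_num(vaf), 0.0)
    return G, V, X


def _pairwise_statistics(G, V, X):
    """Evaluable counts, concordant counts and VAF Pearson correlation for
    every sample pair, via masked-sum matrix products.

    Pairs whose joint VAF vector is (near-)constant in either sample are
    recomputed through :func:`vaf_correlation` so the degenerate rule is
    authoritative.
    """
    Vf = V.astype(np.float64)
    n_eval = Vf @ Vf.T
    conc = np.zeros_like(n_eval)
    for g in (0, 1, 2):
        A = ((G == g) & V).astype(np.float64)
        conc += A @ A.T

    Sx = X @ Vf.T          # Sx[i,j] = sum of x_i over the joint mask
    Sxy = X @ X.T
    Sxx = (X * X) @ Vf.T   # Sxx[i,j] = sum of x_i^2 over the joint mask
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n_eval * Sxy - Sx * Sx.T
        var_x = n_eval * Sxx - Sx**2
        var_y = var_x.T
        corr = cov / np.sqrt(var_x * var_y)

    scale = n_eval * np.maximum(Sxx, Sxx.T) + 1.0
    degenerate = (var_x <= 1e-9 * scale) | (var_y <= 1e-9 * scale) | (n_eval < 2)
    return (
        np.rint(n_eval).astype(np.int64),
        np.rint(conc).astype(np.int64),
        corr,
        degenerate,
    )


def scan_cohort(
    profiles,
    thresholds: MatchThresholds | None = None,
    id_pattern: str = DEFAULT_ID_PATTERN,
    expected_pairs: list[tuple[str, str, str]] | None = None,
) -> CohortScanResult:
    """Compare every unordered pair of samples in a batch.

    Equivalent to calling :func:`snptrace.concordance.compare_pair` on all
    n(n-1)/2 pairs (a vectorised formulation keeps large batches fast).
    Expected same-patient pairs are derived from ``id_pattern`` unless an
    explicit list of (x_id, y_id, patient_id) is supplied; each gets a
    verdict via :func:`check_expected_pairs`.
    """
    profiles = list(profiles)
    t = thresholds or MatchThresholds()
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to scan")
    ids = [p.sample_id for p in profiles]
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise ValueError(f"duplicate sample ids: {sorted(dup)}")
    ref_sites = profiles[0].panel.site_keys
    for p in profiles[1:]:
        if p.panel.site_keys != ref_sites:
            raise ValueError("all profiles must be genotyped on the same panel")
    if len(profiles) > MAX_SAMPLES_SOFT_LIMIT:
        logger.warning(
            "scanning %d samples: the all-vs-all comparison is quadratic and "
            "may take very long", len(profiles),
        )

    G, V, X = _pairwise_arrays(profiles)
    n_eval, conc, corr, degenerate = _pairwise_statistics(G, V, X)
    panel = profiles[0].panel
    pos_tuples = tuple((l.chrom, l.pos, l.rsid) for l in panel)
    vafs = np.stack([p.vafs for p in profiles])
    n = len(profiles)

    # the degenerate rule is authoritative: recompute those few pairs exactly
    for i, j in zip(*np.nonzero(np.triu(degenerate, k=1))):
        both = V[i] & V[j]
        corr[i, j] = corr[j, i] = vaf_correlation(vafs[i][both], vafs[j][both])

    comparisons: list[PairComparison] = []
    for i in range(n - 1):
        block = slice(i + 1, n)
        both_block = V[i] & V[block]
        rows, cols = np.nonzero(both_block & (G[i] != G[block]))
        counts = np.bincount(rows, minlength=n - i - 1)
        disc_per_j = np.split(cols, np.cumsum(counts)[:-1])
        ne_row = n_eval[i, block]
        nc_row = conc[i, block]
        corr_row = corr[i, block]
        for k in range(n - i - 1):
            ne = int(ne_row[k])
            nc = int(nc_row[k])
            c = float(corr_row[k])
            if ne < t.min_evaluable:
                status = MatchStatus.UNEVALUABLE
            else:
                status = classify_pair(nc / ne, c, t)
            comparisons.append(
                PairComparison(
                    x_id=ids[i],
                    y_id=ids[i + 1 + k],
                    n_evaluable=ne,
                    n_concordant=nc,
                    correlation=c,
                    status=status,
                    discordant_positions=tuple(
                        pos_tuples[m] for m in disc_per_j[k].tolist()
                    ),
                )
            )

    matches = tuple(
        c for c in comparisons
        if c.status in (MatchStatus.MATCH, MatchStatus.BORDERLINE_MATCH)
    )
    pid = {s: extract_patient_id(s, id_pattern) for s in ids}
    unexpected = tuple(
        c for c in matches
        if pid[c.x_id] is None or pid[c.y_id] is None or pid[c.x_id] != pid[c.y_id]
    )
    if expected_pairs is None:
        expected_pairs = derive_expected_pairs(ids, id_pattern)
    result = CohortScanResult(
        comparisons=tuple(comparisons),
        matches=matches,
        expected=(),
        unexpected_matches=unexpected,
        sample_ids=tuple(ids),
        thresholds=t,
    )
    expected = check_expected_pairs(expected_pairs, result)
    return CohortScanResult(
        comparisons=result.comparisons,
        matches=result.matches,
        expected=tuple(expected),
        unexpected_matches=result.unexpected_matches,
        sample_ids=result.sample_ids,
        thresholds=t,
    )


def check_expected_pairs(
    expected: list[tuple[str, str, str]], scan: CohortScanResult
) -> list[ExpectedPair]:
    """Assign a verdict to each expected same-patient pair.

    CONCORDANT for a confident MATCH; REVIEW for a BORDERLINE_MATCH (high
    correlation, concordance in the borderline band — typically CNA or
    coverage effects, worth manual inspection); DISCORDANT otherwise.
    """
    out: list[ExpectedPair] = []
    scanned = set(scan.sample_ids)
    by_pair = {c.sample_pair: c for c in scan.comparisons}
    for x_id, y_id, patient_id in expected:
        missing = {x_id, y_id} - scanned
        if missing:
            raise ValueError(f"expected pair references unscanned samples: {sorted(missing)}")
        obs = by_pair[frozenset((x_id, y_id))]
        if obs.status is MatchStatus.MATCH:
            verdict = PairVerdict.CONCORDANT
        elif obs.status is MatchStatus.BORDERLINE_MATCH:
            verdict = PairVerdict.REVIEW
        else:
            verdict = PairVerdict.DISCORDANT
        out.append(ExpectedPair(x_id=x_id, y_id=y_id, patient_id=patient_id,
                                observed=obs, verdict=verdict))
    return out


# ---------------------------------------------------------------------------
# Report files
# ---------------------------------------------------------------------------


def default_timestamp() -> str:
    return datetime.now().strftime("%Y%m%d-%H%M%S")


def _fmt(value: float) -> str:
    return "" if np.isnan(value) else f"{value:.3f}"


def write_pairwise_csv(
    result: CohortScanResult,
    suffix: str,
    timestamp: str | None = None,
    outdir: str | Path = ".",
) -> Path:
    """Write ``Pairwise_concordance_[suffix]_[timestamp].csv``.

    Matching (and borderline) pairs come first, then all remaining pairs by
    descending correlation. Discordant locus positions are semicolon-joined
    ``chrom:pos:rsid`` so flagged pairs can be inspected per SNP.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timestamp = timestamp or default_timestamp()
    path = outdir / f"Pairwise_concordance_{suffix}_{timestamp}.csv"

    def sort_key(c: PairComparison):
        is_match = c.status in (MatchStatus.MATCH, MatchStatus.BORDERLINE_MATCH)
        corr = -np.inf if np.isnan(c.correlation) else c.correlation
        return (0 if is_match else 1, -corr, c.x_id, c.y_id)

    rows = [
        {
            "x_sample": c.x_id,
            "y_sample": c.y_id,
            "n_evaluable": c.n_evaluable,
            "fraction_concordant": _fmt(c.fraction_concordant),
            "correlation": _fmt(c.correlation),
            "status": c.status.value,
            "discordant_positions": ";".join(
                f"{chrom}:{pos}:{rsid}" for chrom, pos, rsid in c.discordant_positions
            ),
        }
        for c in sorted(result.comparisons, key=sort_key)
    ]
    columns = ["x_sample", "y_sample", "n_evaluable", "fraction_concordant",
               "correlation", "status", "discordant_positions"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


def write_expected_csv(
    expected,
    suffix: str,
    timestamp: str | None = None,
    outdir: str | Path = ".",
) -> Path:
    """Write ``Expected_concordant_pairs_[suffix]_[timestamp].csv``, all
    expected pairs in order of descending correlation (broken pairs sink to
    the bottom)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timestamp = timestamp or default_timestamp()
    path = outdir / f"Expected_concordant_pairs_{suffix}_{timestamp}.csv"

    def sort_key(e: ExpectedPair):
        corr = -np.inf if np.isnan(e.observed.correlation) else e.observed.correlation
        return (-corr, e.x_id, e.y_id)

    rows = [
        {
            "x_sample": e.x_id,
            "y_sample": e.y_id,
            "patient_id": e.patient_id,
            "fraction_concordant": _fmt(e.observed.fraction_concordant),
            "correlation": _fmt(e.observed.correlation),
            "verdict": e.verdict.value,
        }
        for e in sorted(expected, key=sort_key)
    ]
    columns = ["x_sample", "y_sample", "patient_id", "fraction_concordant",
               "correlation", "verdict"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


def correlation_matrix(result: CohortScanResult) -> tuple[tuple[str, ...], np.ndarray]:
    """Symmetric n x n matrix of pairwise VAF correlations, diagonal 1."""
    ids = result.sample_ids
    index = {s: i for i, s in enumerate(ids)}
    m = np.full((len(ids), len(ids)), np.nan)
    np.fill_diagonal(m, 1.0)
    for c in result.comparisons:
        i, j = index[c.x_id], index[c.y_id]
        m[i, j] = m[j, i] = c.correlation
    return ids, m


def render_heatmap(
    result: CohortScanResult,
    suffix: str,
    timestamp: str | None = None,
    outdir: str | Path = ".",
) -> Path:
    """Render ``Pairwise_concordance_[suffix]_[timestamp].png``: the
    correlation matrix on a fixed [-1, 1] colour scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timestamp = timestamp or default_timestamp()
    path = outdir / f"Pairwise_concordance_{suffix}_{timestamp}.png"
    ids, m = correlation_matrix(result)
    n = len(ids)
    fig, ax = plt.subplots(figsize=(max(4.0, n * 0.12), max(3.2, n * 0.12)))
    im = ax.imshow(m, vmin=-1.0, vmax=1.0, cmap="RdBu_r", interpolation="nearest")
    ax.set_title("Pairwise VAF correlation")
    if n <= 40:
        ax.set_xticks(range(n), ids, rotation=90, fontsize=5)
        ax.set_yticks(range(n), ids, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Subset sensitivity and contamination QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class SubsetPowerResult:
    """Detection bookkeeping for one random panel subset."""

    subset_size: int
    iteration: int
    seed: int
    detected_unexpected: int
    detected_discordant: int
    false_positives: int


def count_false_positives(
    scan: CohortScanResult,
    truth: PlantedTruth,
    id_pattern: str = DEFAULT_ID_PATTERN,
) -> int:
    """Confident MATCH pairs that are neither expected (same patient label)
    nor planted same-donor pairs."""
    planted = truth.unexpected_pairs
    n = 0
    for c in scan.comparisons:
        if c.status is not MatchStatus.MATCH:
            continue
        px = extract_patient_id(c.x_id, id_pattern)
        py = extract_patient_id(c.y_id, id_pattern)
        if px is not None and px == py:
            continue
        if c.sample_pair in planted:
            continue
        n += 1
    return n


def evaluate_scan_against_truth(
    scan: CohortScanResult, truth: PlantedTruth, id_pattern: str = DEFAULT_ID_PATTERN
) -> tuple[int, int, int]:
    """(detected planted unexpected pairs, detected discordant expected
    pairs, false positives) of one scan."""
    match_pairs = scan.match_pairs
    detected_unexpected = sum(1 for p in truth.unexpected_pairs if p in match_pairs)
    discordant_observed = {
        frozenset((e.x_id, e.y_id))
        for e in scan.expected
        if e.verdict is PairVerdict.DISCORDANT
    }
    detected_discordant = sum(
        1 for p in truth.discordant_expected_pairs if p in discordant_observed
    )
    fp = count_false_positives(scan, truth, id_pattern)
    return detected_unexpected, detected_discordant, fp


def subset_sensitivity(
    profiles,
    truth: PlantedTruth,
    sizes,
    iterations: int = 10,
    seed: int = 0,
    thresholds: MatchThresholds | None = None,
    id_pattern: str = DEFAULT_ID_PATTERN,
) -> list[SubsetPowerResult]:
    """Re-run the scan on random panel subsets to probe panel-size power.

    For each (size, iteration) a uniform subset of loci is drawn with a
    deterministic seed derived from (seed, size, iteration), the scan is
    repeated on the restricted profiles, and detections of the planted
    truth plus false positives are recorded. Fewer SNPs keep sensitivity
    for a while but false positives grow quickly.
    """
    profiles = list(profiles)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    panel_size = len(profiles[0].panel)
    results: list[SubsetPowerResult] = []
    for size in sizes:
        if size > panel_size:
            raise ValueError(f"subset size {size} exceeds panel size {panel_size}")
        for it in range(iterations):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(size, it))
            )
            idx = np.sort(rng.choice(panel_size, size=size, replace=False))
            sub = [p.subset(idx) for p in profiles]
            scan = scan_cohort(sub, thresholds=thresholds, id_pattern=id_pattern)
            du, dd, fp = evaluate_scan_against_truth(scan, truth, id_pattern)
            results.append(
                SubsetPowerResult(
                    subset_size=int(size),
                    iteration=it,
                    seed=seed,
                    detected_unexpected=du,
                    detected_discordant=dd,
                    false_positives=fp,
                )
            )
    return results


@dataclass(frozen=True)
class ContaminationReport:
    """Per-sample deviation of VAFs from the germline anchors {0, 0.5, 1}."""

    sample_id: str
    score: float  # NaN when no evaluable locus
    flagged: bool
    deviant_loci: tuple[tuple[str, int, str, float, float], ...]
    # (chrom, pos, rsid, vaf, deviation)


def contamination_score(
    profile: SampleProfile,
    deviation_max: float = 0.1,
    score_max: float = 0.05,
) -> ContaminationReport:
    """Score cross-sample contamination from VAF anchor deviations.

    Germline SNP VAFs in a pure sample sit near 0, 0.5 or 1; admixed DNA
    pulls loci where the two individuals differ away from those anchors.
    Score = mean over evaluable loci of the distance to the nearest anchor;
    loci deviating by more than ``deviation_max`` are listed and the sample
    is flagged when the score exceeds ``score_max``.
    """
    no_call = int(GenotypeCall.NO_CALL)
    evaluable = np.asarray(profile.genotypes) != no_call
    if not evaluable.any():
        logger.warning("%s: no evaluable locus; contamination score undefined",
                       profile.sample_id)
        return ContaminationReport(
            sample_id=profile.sample_id, score=float("nan"), flagged=False,
            deviant_loci=(),
        )
    vafs = profile.vafs
    anchors = np.array([0.0, 0.5, 1.0])
    deviations = np.min(
        np.abs(vafs[:, None] - anchors[None, :]), axis=1
    )
    score = float(np.mean(deviations[evaluable]))
    deviant = tuple(
        (l.chrom, l.pos, l.rsid, float(vafs[i]), float(deviations[i]))
        for i, l in enumerate(profile.panel)
        if evaluable[i] and deviations[i] > deviation_max
    )
    return ContaminationReport(
        sample_id=profile.sample_id,
        score=score,
        flagged=score > score_max,
        deviant_loci=deviant,
    )
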