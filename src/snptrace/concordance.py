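"""Pairwise sample-identity comparison.

Two samples from the same donor agree at (nearly) every fingerprint SNP;
two unrelated samples agree only by chance. A pair is summarised by the
fraction of concordant genotype calls over jointly callable loci and by the
Pearson correlation of the two VAF vectors, and classified against two
thresholds: correlation >= 0.9 and concordance >= 0.8 flag a confident
match, while concordance in [0.7, 0.8) with high correlation is a
borderline match earmarked for manual review (copy-number aberrations and
low coverage push genuine same-donor pairs into this band).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .genotyping import GenotypeCall, SampleProfile

logger = logging.getLogger(__name__)

#: max absolute elementwise VAF difference treated as "same" when Pearson
#: correlation is undefined because one vector has zero variance
DEGENERATE_VAF_TOL = 0.1


class MatchStatus(str, Enum):
    MATCH = "MATCH"
    BORDERLINE_MATCH = "BORDERLINE_MATCH"
    NO_MATCH = "NO_MATCH"
    UNEVALUABLE = "UNEVALUABLE"


@dataclass(frozen=True, slots=True)
class MatchThresholds:
    """Classification thresholds for a sample pair.

    ``concordance_match`` (0.8) and ``correlation_min`` (0.9) define a
    confident match; ``concordance_floor`` (0.7) opens the borderline band
    below the match threshold. Setting concordance_match == concordance_floor
    collapses the borderline band and reproduces a single-threshold matcher.
    ``min_evaluable`` guards against classifying pairs that share almost no
    callable loci.
    """

    concordance_match: float = 0.8
    concordance_floor: float = 0.7
    correlation_min: float = 0.9
    min_evaluable: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.concordance_floor <= self.concordance_match <= 1.0:
            raise ValueError("need 0 < concordance_floor <= concordance_match <= 1")


@dataclass(frozen=True, slots=True)
class PairComparison:
    """Result of comparing one unordered sample pair."""

    x_id: str
    y_id: str
    n_evaluable: int
    n_concordant: int
    correlation: float  # NaN when undefined
    status: MatchStatus
    discordant_positions: tuple[tuple[str, int, str], ...]  # (chrom, pos, rsid)

    @property
    def fraction_concordant(self) -> float:
        if self.n_evaluable == 0:
            return float("nan")
        return self.n_concordant / self.n_evaluable

    @property
    def sample_pair(self) -> frozenset[str]:
        return frozenset((self.x_id, self.y_id))


def vaf_correlation(vx, vy) -> float:
    """Pearson correlation of two VAF vectors over jointly callable loci.

    When either vector is constant, Pearson correlation is undefined; a
    same-donor pair of e.g. all-hom-ref profiles would otherwise be
    uncomparable. The degenerate rule returns 1.0 if the vectors are
    elementwise within DEGENERATE_VAF_TOL and 0.0 otherwise. Vectors
    shorter than 2 give NaN.
    """
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if vx.shape != vy.shape:
        raise ValueError("VAF vectors must have equal length")
    if vx.size < 2:
        return float("nan")
    if np.std(vx) == 0.0 or np.std(vy) == 0.0:
        return 1.0 if float(np.max(np.abs(vx - vy))) <= DEGENERATE_VAF_TOL else 0.0
    return float(np.corrcoef(vx, vy)[0, 1])


def classify_pair(
    fraction: float, correlation: float, thresholds: MatchThresholds | None = None
) -> MatchStatus:
    """Classify a pair from its concordance fraction and VAF correlation.

    Both criteria must hold for a (borderline) match: correlation >=
    correlation_min and fraction >= concordance_match (MATCH) or >=
    concordance_floor (BORDERLINE_MATCH). An undefined (NaN) correlation
    never matches.
    """
    t = thresholds or MatchThresholds()
    if np.isnan(correlation) or np.isnan(fraction) or correlation < t.correlation_min:
        return MatchStatus.NO_MATCH
    if fraction >= t.concordance_match:
        return MatchStatus.MATCH
    if fraction >= t.concordance_floor:
        return MatchStatus.BORDERLINE_MATCH
    return MatchStatus.NO_MATCH


def compare_pair(
    x: SampleProfile, y: SampleProfile, thresholds: MatchThresholds | None = None
) -> PairComparison:
    """Compare two sample profiles genotyped on the same panel.

    Loci with NO_CALL in either sample are excluded from both the
    concordance fraction and the correlation. Pairs with fewer than
    ``min_evaluable`` joint calls are reported but flagged UNEVALUABLE.
    A pair with zero discordant loci is a normal, valid result (fraction 1,
    empty discordant list).
    """
    t = thresholds or MatchThresholds()
    if x.panel.site_keys != y.panel.site_keys:
        raise ValueError(
            f"profiles {x.sample_id} and {y.sample_id} were genotyped on different panels"
        )
    no_call = int(GenotypeCall.NO_CALL)
    gx = np.asarray(x.genotypes)
    gy = np.asarray(y.genotypes)
    evaluable = (gx != no_call) & (gy != no_call)
    n_evaluable = int(evaluable.sum())
    concordant = evaluable & (gx == gy)
    n_concordant = int(concordant.sum())
    discordant_idx = np.nonzero(evaluable & (gx != gy))[0]
    discordant = tuple(
        (x.panel[i].chrom, x.panel[i].pos, x.panel[i].rsid) for i in discordant_idx
    )
    correlation = vaf_correlation(x.vafs[evaluable], y.vafs[evaluable])
    if n_evaluable < t.min_evaluable:
        logger.warning(
            "pair (%s, %s): only %d jointly callable loci (< %d); unevaluable",
            x.sample_id, y.sample_id, n_evaluable, t.min_evaluable,
        )
        status = MatchStatus.UNEVALUABLE
    else:
        status = classify_pair(n_concordant / n_evaluable, correlation, t)
    return PairComparison(
        x_id=x.sample_id,
        y_id=y.sample_id,
        n_evaluable=n_evaluable,
        n_concordant=n_concordant,
        correlation=correlation,
        status=status,
        discordant_positions=discordant,
    )
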