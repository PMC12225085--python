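import numpy as np
import pytest

from snptrace import GenotypeCall, QualityConfig, SampleProfile, SnpLocus, SnpPanel, default_panel


@pytest.fixture(scope="session")
def panel28() -> SnpPanel:
    return default_panel()


@pytest.fixture(scope="session")
def quality() -> QualityConfig:
    return QualityConfig()


def make_profile(panel: SnpPanel, genotypes, sample_id="S", depth=100) -> SampleProfile:
    """Deterministic noise-free profile: counts exactly reflect genotypes.

    ``genotypes`` is a sequence of GenotypeCall values (NO_CALL gives zero
    coverage at that locus).
    """
    ref = np.zeros(len(panel), dtype=np.int64)
    alt = np.zeros(len(panel), dtype=np.int64)
    for i, g in enumerate(genotypes):
        g = GenotypeCall(int(g))
        if g is GenotypeCall.HOM_REF:
            ref[i] = depth
        elif g is GenotypeCall.HET:
            ref[i] = depth // 2
            alt[i] = depth - depth // 2
        elif g is GenotypeCall.HOM_ALT:
            alt[i] = depth
    return SampleProfile.from_counts(sample_id, panel, ref, alt)


@pytest.fixture(scope="session")
def tiny_panel() -> SnpPanel:
    return SnpPanel(
        [
            SnpLocus("rsA", "chr1", 600, "A", "G", pop_af=0.5),
            SnpLocus("rsB", "chr1", 1800, "C", "T", pop_af=0.3),
            SnpLocus("rsC", "chr2", 600, "G", "A", pop_af=0.7),
            SnpLocus("rsD", "chr2", 1800, "T", "C", pop_af=0.5),
        ],
        name="tiny",
    )
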