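"""Genotype miniature BAM files at the bundled 28-SNP panel.

Simulates two patients (two timepoints each), materialises their reads as
coordinate-sorted indexed BAMs on a synthetic reference, then runs the
pileup-based extraction and prints the first sample's readcounts.
"""

import tempfile

from snptrace import SimConfig, default_panel, extract_readcounts, simulate_cohort, write_fixture_bams

panel = default_panel()
cohort = simulate_cohort(SimConfig(panel=panel, n_patients=2, mean_depth=60.0, seed=5))

with tempfile.TemporaryDirectory() as workdir:
    bams, fasta = write_fixture_bams(cohort, workdir)
    print(f"wrote {len(bams)} BAMs and reference {fasta.name}")
    profile = extract_readcounts(bams[0], panel)
    print(f"sample {profile.sample_id}:")
    print(f"{'rsid':<12}{'ref':>5}{'alt':>5}{'vaf':>8}  genotype")
    for rc, g in zip(profile.readcounts[:8], profile.genotypes[:8]):
        vaf = "" if rc.vaf is None else f"{rc.vaf:.3f}"
        print(f"{rc.locus.rsid:<12}{rc.ref_count:>5}{rc.alt_count:>5}{vaf:>8}  {int(g)}")
# VAFs cluster at 0 / 0.5 / 1 (hom-ref, het, hom-alt): the germline
# fingerprint pattern the pair comparison relies on. Genotype codes:
# 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = no call.
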