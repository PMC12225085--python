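"""Flag cross-sample contamination from VAF anchor deviations.

In a pure sample, germline SNP VAFs sit near 0, 0.5 or 1. Admixed DNA from
another individual pulls loci where the two genomes differ away from those
anchors; the contamination score is the mean deviation over callable loci.
"""

from snptrace import Contaminate, SimConfig, contamination_score, default_panel, simulate_cohort
from snptrace.synthetic import sample_name

for fraction in (0.0, 0.05, 0.10, 0.20):
    planted = (
        (Contaminate(sample_name(0, 0), sample_name(1, 0), fraction),)
        if fraction else ()
    )
    cohort = simulate_cohort(
        SimConfig(panel=default_panel(), n_patients=2, timepoints=1,
                  mean_depth=500.0, seed=23, planted_errors=planted)
    )
    report = contamination_score(cohort.profiles[0])
    print(f"admixture {fraction:4.0%}: score={report.score:.4f} "
          f"deviant_loci={len(report.deviant_loci):2d} flagged={report.flagged}")
# The score scales with the admixed fraction; individual deviant loci point
# at the SNPs where the contaminating individual's genotype differs.
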