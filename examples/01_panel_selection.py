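"""Select a fingerprint panel from a cohort variant matrix.

Builds a small synthetic cohort matrix with known nuisance variants (a
technical artefact, a population-rare SNP, a near-private SNP, one linked
pair) and runs the four-stage selection pipeline: population-AF window,
artefact removal, prevalence filter, linkage pruning.
"""

import numpy as np
import pandas as pd

from snptrace import CohortVariantMatrix, LinkageGroups, SnpLocus, select_panel

rng = np.random.default_rng(11)
n_samples = 80

variants, rows = [], []
for i in range(12):  # informative, segregating SNPs
    variants.append(SnpLocus(f"rs_good{i}", "chr1", 1000 + 400 * i, "A", "G",
                             pop_af=0.15 + 0.05 * i))
    rows.append(rng.choice([0.0, 0.5, 1.0], n_samples, p=[0.35, 0.45, 0.2]))
variants.append(SnpLocus("rs_artefact", "chr2", 500, "C", "T", pop_af=0.5))
rows.append(0.12 + rng.normal(0, 0.004, n_samples))        # same VAF everywhere
variants.append(SnpLocus("rs_rare", "chr2", 900, "G", "A", pop_af=0.02))
rows.append(rng.choice([0.0, 0.5], n_samples))             # rare in population
private = np.full(n_samples, np.nan)
private[5] = 0.5
variants.append(SnpLocus("rs_private", "chr2", 1300, "T", "C", pop_af=0.3))
rows.append(private)                                       # one carrier only

matrix = CohortVariantMatrix(
    variants=tuple(variants),
    vaf=pd.DataFrame(rows, index=[v.rsid for v in variants],
                     columns=[f"S{i:02d}" for i in range(n_samples)]),
)
groups = LinkageGroups(groups=(("rs_good0", "rs_good1"),))  # one LD pair

report = select_panel(matrix, groups)
print(report.format_log())
print("selected:", ", ".join(report.panel.rsids))
# The log shows how many candidates each stage removed; the final panel
# keeps only common, segregating, independent SNPs (one per LD group).
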