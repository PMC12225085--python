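"""Detect a planted sample swap in an all-vs-all cohort scan.

Simulates 20 patients with two timepoints each, swaps the TP2 samples of
two patients, scans every pair, and writes the pairwise and expected-pair
CSV reports plus the correlation heatmap.
"""

import tempfile

from snptrace import (
    PairVerdict, SimConfig, Swap, default_panel, render_heatmap, scan_cohort,
    simulate_cohort, write_expected_csv, write_pairwise_csv,
)
from snptrace.synthetic import sample_name

config = SimConfig(
    panel=default_panel(), n_patients=20, mean_depth=100.0, seed=42,
    planted_errors=(Swap(sample_name(3, 1), sample_name(7, 1)),),
)
cohort = simulate_cohort(config)
result = scan_cohort(cohort.profiles)

print(f"{len(result.comparisons)} pairs compared, "
      f"{len(result.matches)} tentative matches")
print("unexpected matches (differing patient ids -> swap or mislabel):")
for c in result.unexpected_matches:
    print(f"  {c.x_id} ~ {c.y_id}  fraction={c.fraction_concordant:.3f} "
          f"r={c.correlation:.3f}")
print("expected pairs that fail to match (the swap's other half):")
for e in result.expected:
    if e.verdict is PairVerdict.DISCORDANT:
        print(f"  {e.x_id} ~ {e.y_id}  fraction={e.observed.fraction_concordant:.3f} "
              f"r={e.observed.correlation:.3f}")

with tempfile.TemporaryDirectory() as outdir:
    ts = "20250101-120000"
    for path in (write_pairwise_csv(result, "demo", ts, outdir),
                 write_expected_csv(result.expected, "demo", ts, outdir),
                 render_heatmap(result, "demo", ts, outdir)):
        print("wrote", path.name)
# One swap surfaces twice: two unexpected cross-patient matches (each TP1
# matches the other patient's mislabelled TP2) and two broken expected pairs.
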