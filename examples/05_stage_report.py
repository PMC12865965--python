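"""Stage-accounting report and QA sampling — the audit face of the pipeline.

Feeds a set of stage counts through the report builder (the conservation
law is checked row by row, percentages rounded half-up to one decimal)
and draws a seeded QA worksheet from a toy classification table.
"""

import pandas as pd

from medharmonize import StageCounts, build_report, qa_sample

P1 = "Phase 1: Drug Name Standardization"
P2 = "Phase 2: Therapeutic Class Mapping"

counts = [
    StageCounts(P1, "1. Absolute Match", 14273, 276, 2353, 16902, 16902),
    StageCounts(P1, "2. Fuzzy Match", 5, 100, 2248, 2353, 16902),
    StageCounts(P1, "3. Dictionary Match", 846, 0, 1402, 2248, 16902),
    StageCounts(P1, "5. Expert Review", 1778, 0, 0, 1778, 16902),
    StageCounts(P2, "1. Direct Matching to Generic Names", 389, 0, 88, 477, 477),
    StageCounts(P2, "2. Matching Trade Names", 31, 0, 57, 88, 477),
    StageCounts(P2, "3. Fuzzy Match to Drug-Form Strings", 19, 0, 38, 57, 477),
]
report = build_report(counts)
print(report.to_string(index=False))

print()
population = pd.DataFrame(
    {
        "canonical_name": [f"drug{i:03d}" for i in range(444)],
        "method": ["generic_exact"] * 400 + ["fuzzy_scdf"] * 44,
    }
)
worksheet = qa_sample(population, n=10, seed=7)
print("seeded QA worksheet (fuzzy assignments flagged for dual verification):")
print(worksheet.to_string(index=False))

print()
print("Every report row satisfies correct + flagged + unmatched = stage input;")
print("percentages divide by the phase total (e.g. 14,273/16,902 = 84.4%).")
print("The same 10-row sample reappears for any auditor using seed 7.")
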