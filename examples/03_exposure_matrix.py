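"""Pivot classified medication records into a participant×visit exposure matrix.

Two participants over two visits: P1 takes two different statins (they
collapse into one class indicator) plus an ACE inhibitor; P2 takes
metformin at visit 1 only.  A visit roster adds P2's medication-free
second visit as an all-zero row, and a merge map shows class
consolidation.
"""

import pandas as pd

from medharmonize import summarize_exposure, to_wide

long_rows = pd.DataFrame(
    [
        ("P1", "V1", "atorvastatin", "24:06.08", "Antihyperlipidemic Agents"),
        ("P1", "V1", "simvastatin", "24:06.08", "Antihyperlipidemic Agents"),
        ("P1", "V1", "lisinopril", "24:32.04", "ACE Inhibitors"),
        ("P1", "V2", "atorvastatin", "24:06.08", "Antihyperlipidemic Agents"),
        ("P2", "V1", "metformin", "68:20.04", "Biguanides"),
    ],
    columns=["participant_id", "visit_id", "canonical_name", "AHFSClassNum",
             "class_label"],
)
roster = pd.DataFrame(
    {"participant_id": ["P1", "P1", "P2", "P2"],
     "visit_id": ["V1", "V2", "V1", "V2"]}
)

matrix = to_wide(long_rows, roster=roster)
print("level-4 exposure matrix (1 = any drug of that class at that visit):")
print(matrix.to_string())

prevalence, burden = summarize_exposure(matrix)
print("\nper-class prevalence across participant-visits:")
print(prevalence.to_string())
print("\nclass count per visit (polypharmacy proxy):")
print(burden.to_string())

merged = to_wide(long_rows, roster=roster, level=2)
print("\nrolled up to level 2 (24:06 and 24:32 both fall under 24:xx groups):")
print(merged.to_string())

print()
print("P1/V1 holds two statins but a single 24:06.08 indicator — exposure is")
print("per class, not per drug; P2/V2 appears as an all-zero row only")
print("because the roster says the visit happened with no medications.")
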