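"""Map standardized generic names onto a four-level therapeutic-class hierarchy.

Builds a three-drug reference set in memory (generic names, one brand,
clinical drug-form strings, the class table) and classifies a mixed batch
of names: exact generic hits, a brand name, a one-edit misspelling caught
by Levenshtein matching against a drug-form string, and one unmappable
name left for the expert queue.
"""

import pandas as pd

from medharmonize import AHFSReferenceSet, classify_all

refset = AHFSReferenceSet(
    generics=pd.DataFrame(
        {
            "UN": ["G1", "G2", "G3"],
            "GenDrugName": ["atorvastatin", "metformin", "lisinopril"],
            "AHFSClassID": ["C1", "C2", "C3"],
        }
    ),
    tradenames=pd.DataFrame(
        {"UN": ["T1"], "Tradename": ["lipitor"], "GenDrugName": ["atorvastatin"]}
    ),
    scdf=pd.DataFrame(
        {
            "SCDF_STR": [
                "atorvastatin oral tablet",
                "metformin oral tablet",
                "lisinopril oral tablet",
            ],
            "SCDF_CUI": ["CUI1", "CUI2", "CUI3"],
            "AHFSClassNum": ["24:06.08", "68:20.04", "24:32.04"],
        }
    ),
    classes=pd.DataFrame(
        {
            "AHFSClassID": ["C1", "C2", "C3"],
            "AHFSClassNum": ["24:06.08", "68:20.04", "24:32.04"],
            "AHFSClassText": [
                "Antihyperlipidemic Agents", "Biguanides", "ACE Inhibitors",
            ],
        }
    ),
    classes_extended=pd.DataFrame(
        {
            "AHFSClassNum": ["24:06.08", "68:20.04", "24:32.04"],
            "AHFSClassText_2": ["24:06", "68:20", "24:32"],
            "AHFSClassText_3": ["24:06.08", "68:20.04", "24:32.04"],
            "AHFSClassText_4": ["24:06.08", "68:20.04", "24:32.04"],
        }
    ),
)

names = ["atorvastatin", "lipitor", "lisinoprik", "metformin", "mysterydrug"]
classmap, unresolved, counts = classify_all(names, refset)

print(f"{'name':<14}{'class num':<12}{'class text':<28}{'method':<14}score")
for name in names:
    assignments = classmap.get(name)
    if not assignments:
        continue
    for a in assignments:
        score = f"{a.score.percent:.1f}%" if a.score else "-"
        print(f"{name:<14}{a.ahfs_class_num:<12}{a.ahfs_class_text:<28}"
              f"{a.method:<14}{score}")
print(f"unresolved (expert queue): {unresolved}")

print()
for c in counts:
    print(f"{c.process_label}: {c.correct} of {c.total} resolved")
print()
print("'lisinoprik' is one edit from 'lisinopril' (similarity 90.0%), so the")
print("drug-form fuzzy stage places it; the class hierarchy levels travel")
print("with every assignment for later level-2/3 roll-ups.")
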