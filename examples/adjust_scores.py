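"""Demographically adjust raw MoCA totals under the three Italian normative datasets.

Shows how the same raw score maps to different adjusted values and
impaired/normal calls depending on the normative system, and how degenerate
demographics (0 years of education) are clamped and flagged.
"""

from moca_psci import NORMATIVE_DATASETS, adjust_score

patients = [
    ("78-year-old, 5 years of school, raw 16", 16, 78, 5),
    ("62-year-old, 13 years of school, raw 16", 16, 62, 13),
    ("85-year-old, no formal schooling, raw 16", 16, 85, 0),
]

for label, raw, age, edu in patients:
    print(f"\n{label}")
    for name, ds in NORMATIVE_DATASETS.items():
        s = adjust_score(raw, age, edu, ds)
        flags = " [inputs clamped]" if s.clamped_inputs else ""
        flags += " [outside normative age range]" if s.extrapolated else ""
        print(f"  {name:11s} adjusted {s.value:6.2f}  (ES=0 cut-off {ds.es0_cutoff:5.2f})"
              f" -> {s.performance}{flags}")

print("\nThe adjustment rewards old age and penalizes long schooling, so the")
print("same raw total can be impaired under one normative system and normal")
print("under another; classification is strict: adjusted < cut-off = impaired.")
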