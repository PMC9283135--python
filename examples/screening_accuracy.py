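"""Diagnostic accuracy of normative ES=0 thresholds against the PSCI outcome.

Takes the published follow-up cohort's 2x2 counts (baseline impaired/normal
vs PSCI yes/no under each normative dataset) and recomputes sensitivity,
specificity, predictive values and the chi-square association.
"""

from moca_psci import ContingencyTable2x2, accuracy_indices, pearson_chi2
from moca_psci.diagnostics import format_p

# (tp, fp, fn, tn): baseline-impaired & PSCI, impaired & no PSCI,
# normal & PSCI, normal & no PSCI — follow-up cohort n = 118
TABLES = {
    "aiello": (36, 2, 41, 39),
    "conti": (31, 2, 46, 39),
    "santangelo": (27, 1, 50, 40),
}

print(f"{'dataset':12s} {'Se%':>4s} {'Sp%':>4s} {'PPV%':>5s} {'NPV%':>5s}  p")
for name, counts in TABLES.items():
    table = ContingencyTable2x2(*counts)
    acc = accuracy_indices(table).as_percents()
    _, p = pearson_chi2(table)
    print(f"{name:12s} {acc['sensitivity']:4.0f} {acc['specificity']:4.0f} "
          f"{acc['ppv']:5.0f} {acc['npv']:5.0f}  {format_p(p)}")

print("\nEvery normative threshold is highly specific (95-98%) but misses more")
print("than half of the patients who go on to PSCI (Se 35-47%): general-")
print("population normality cut-offs under-detect at-risk acute stroke patients.")
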