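"""Apply the record-selection rules to a simulated cohort.

Shows the creatinine mass-balance rule (dTBCr = dPCr * 0.6 * weight,
exclude beyond 1.5 mmol/day), the 3-30 mmol/day plausibility bounds and
the one-week repeat-scan rule, with per-reason counts.
"""

from collections import Counter

from craftct import CohortConfig, apply_filters, delta_tbcr, generate_cohort

print("hand check: dPCr 0.02 mmol/L/day at 80 kg ->", delta_tbcr(0.02, 80.0), "mmol/day")

config = CohortConfig.default_study(n_subjects=400, seed=2)
records, _ = generate_cohort(config)
outcomes = apply_filters(records)

counts = Counter(reason for o in outcomes for reason in o.reasons)
included = sum(o.included for o in outcomes)
print(f"included {included} of {len(outcomes)} scan records")
for reason, n in counts.most_common():
    print(f"  excluded {n:3d} for {reason}")
print(
    "nonsteady = plasma creatinine drifting enough that excretion no longer\n"
    "equals production; duplicate_window = repeat scan within one week."
)
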