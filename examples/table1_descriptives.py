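"""Descriptive summary of the packaged 40-study treadmill table.

Twenty studies measured VO2peak with gas analysis and twenty predicted it
from treadmill speed, incline or protocol time. The predicted-arm studies
enrol roughly tenfold more subjects — the bias that motivates checking
prediction equations against an independent surrogate.
"""

from hrindex import Arm, load_table1, summarize_arm

records = load_table1()
print(f"loaded {len(records)} study records\n")

for arm in Arm:
    s = summarize_arm(records, arm)
    print(f"{arm.value} arm: {s.n_studies} studies")
    print(f"  subjects: {s.n_total} total "
          f"(range {s.n_min} to {s.n_max}, median {s.n_median:g})")
    print(f"  n-weighted demographics: {s.age_weighted_mean:.1f} y, "
          f"{s.male_pct_weighted:.1f}% male\n")

ratio = (summarize_arm(records, Arm.PREDICTED).n_total
         / summarize_arm(records, Arm.MEASURED).n_total)
print(f"prediction-based studies enrol {ratio:.1f}x more subjects")
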