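"""End-to-end method comparison on a synthetic biased cohort.

Generates a 57-point equation-predicted cohort carrying a 21.1%
over-prediction bias, then runs the full comparison against the
heart-rate-index surrogate: pooled difference, paired t-test,
Bland-Altman agreement and fitness tertiles. The analysis should recover
the injected bias and flag it as highly significant.
"""

from hrindex import Arm, compare_arm, generate_cohort, predicted_arm_config
from hrindex.report import fmt_p

config = predicted_arm_config(seed=42)
cohort = generate_cohort(config)
print(f"simulated {len(cohort)} study-level data points "
      f"(injected bias {100 * config.overprediction_bias:.1f}%)\n")

result = compare_arm(cohort, Arm.PREDICTED)
c = result.comparison
print(f"treadmill-predicted mean {c.tm_mean:.2f} ± {c.tm_sd:.2f} METs")
print(f"surrogate (HRI) mean     {c.hri_mean:.2f} ± {c.hri_sd:.2f} METs")
print(f"difference {c.abs_diff:.2f} METs ({c.pct_diff:.1f}%), "
      f"paired t({c.df}) p = {fmt_p(c.p_value)}")

ba = result.bland_altman
print(f"Bland-Altman bias {ba.bias:.2f} METs, "
      f"95% LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")

print("\nby fitness tertile (1 = least fit):")
for row in result.tertiles:
    print(f"  tertile {row.tertile} (n={row.n_points}): "
          f"{row.pct_diff:5.1f}%  p = {fmt_p(row.p_value)}")
print("\nover-prediction is recovered across the board; with a graded "
      "bias it concentrates in the least-fit tertile")
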