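"""Heart-rate-index conversions on the model's worked examples.

The surrogate relation METs = 6*HRI - 5 maps the ratio of activity to
resting heart rate onto oxygen uptake. This script evaluates it at the
clinically anchored points: rest, the 5/10/15 MET Kaplan-Meier cut points,
and the elite-athlete ceiling of 19 METs.
"""

from hrindex import HriEstimate, hri_from_mets, mets_from_hri

print("index -> METs")
for hri in (1.0, 1.67, 2.5, 3.33, 4.0):
    print(f"  HRI {hri:4.2f}  ->  {mets_from_hri(hri):5.2f} METs")

print("\nMETs -> index (one MET costs 1/6 of an index unit)")
for mets in (5.0, 10.0, 15.0, 19.0):
    print(f"  {mets:4.1f} METs  ->  HRI {hri_from_mets(mets):.2f}")

est = HriEstimate.from_heart_rates(hr_max=147.1, hr_rest=77.6)
print(f"\nfrom group-mean heart rates 147.1 / 77.6 beats/min:")
print(f"  HRI = {est.hri:.2f}, VO2 = {est.mets:.2f} METs "
      f"= {est.vo2_ml:.1f} mL O2/kg/min")
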