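"""Treadmill-parameter VO2 predictions and the handrail correction.

Evaluates the shipped registry equations — walking and running forms in
speed and grade, and a cubic in Bruce-protocol time — then shows how a
20% handrail-support inflation is divided back out of a prediction.
"""

from hrindex import (handrail_adjust, load_registry, ml_to_mets,
                     vo2_from_protocol_time, vo2_walk)
from hrindex.records import RailSupport

reg = load_registry()
print("registered equations:", ", ".join(reg.names()), "\n")

# Bruce stage 3 conditions: 3.4 mph (~91.2 m/min) at 14% grade
vo2 = vo2_walk(speed=91.2, grade=0.14)
print(f"walking at 91.2 m/min, 14% grade: {vo2:.1f} mL/kg/min "
      f"({ml_to_mets(vo2):.1f} METs)")

bruce = reg["bruce_time"]
for minutes in (6.0, 9.0, 12.0):
    vo2_t = vo2_from_protocol_time(bruce, minutes)
    print(f"Bruce time {minutes:4.1f} min: {vo2_t:5.1f} mL/kg/min "
          f"({ml_to_mets(vo2_t):4.1f} METs)")

print()
inflated = vo2_from_protocol_time(bruce, 12.0)
corrected = handrail_adjust(inflated, RailSupport.LIGHT_SUPPORT, 20.0)
print(f"12-min Bruce with light rail support: predicted {inflated:.1f}, "
      f"corrected {corrected:.1f} mL/kg/min")
print("(rail support lengthens test time, inflating time-based "
      "predictions by ~20-30%)")
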