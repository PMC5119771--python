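{
  "acsm_walk": {
    "kind": "speed_grade_walk",
    "coefficients": [3.5, 0.1, 1.8],
    "valid_range": {"speed": [0.0, 134.0], "grade": [0.0, 0.4]},
    "source_note": "ACSM metabolic equation for walking: VO2 = 3.5 + 0.1*speed + 1.8*speed*grade (speed in m/min, grade as fraction)."
  },
  "acsm_run": {
    "kind": "speed_grade_run",
    "coefficients": [3.5, 0.2, 0.9],
    "valid_range": {"speed": [0.0, 402.0], "grade": [0.0, 0.4]},
    "source_note": "ACSM metabolic equation for running: VO2 = 3.5 + 0.2*speed + 0.9*speed*grade."
  },
  "bruce_time": {
    "kind": "protocol_time_poly",
    "coefficients": [14.76, -1.379, 0.451, -0.012],
    "valid_range": {"minutes": [3.0, 21.0]},
    "source_note": "Foster et al. 1984 cubic for Bruce-protocol treadmill time: VO2 = 14.76 - 1.379t + 0.451t^2 - 0.012t^3 (t in minutes); monotone increasing over the declared range."
  }
}
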