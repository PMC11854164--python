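[
 {"name": "pH", "low": 4.0, "center": 5.0, "high": 6.0, "unit": ""},
 {"name": "enzyme_addition", "low": 1.5, "center": 3.0, "high": 4.5, "unit": "%"},
 {"name": "ultrasonic_time", "low": 40.0, "center": 60.0, "high": 80.0, "unit": "min"}
]
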