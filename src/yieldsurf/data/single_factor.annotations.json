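{
 "note": "Univariate screening yields quoted in the reference study's prose, at the screening baseline (enzyme 3.0 %, ultrasonic time 30 min, pH 5, 50 degC) with one factor varied per row. Full screening curves were published only graphically and are not packaged.",
 "source": "reported",
 "baseline": {"pH": 5, "enzyme_pct": 3.0, "time_min": 30, "temp_C": 50}
}
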