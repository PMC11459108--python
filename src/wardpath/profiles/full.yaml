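# All seven rules, including the two duration rules that could not be
# expert-validated (use with care; thresholds below are the defaults).
profile: full
enabled_rules: [1, 2, 3, 4, 5, 6, 7]
ed_los_max_hours: 10
buffer_window_days: 7.5
awaiting_bed_label: "awaiting bed"
los_excess_factor: 1.0
require_specialized_successor: true
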