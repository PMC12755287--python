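# Reference Monte Carlo benchmark grid: 360 scenarios
# (5 sample sizes x 3 allocations x 4 control event rates x 6 relative risks)
sample_sizes: [60, 100, 200, 400, 800]
allocations: ["1:1", "2:1", "3:2"]
control_event_rates: [0.05, 0.10, 0.20, 0.40]
relative_risks: [1.00, 0.90, 0.80, 0.70, 0.60, 1.10]
reps: 2000
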