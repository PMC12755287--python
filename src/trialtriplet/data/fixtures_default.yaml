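# Default synthetic trial-collection recipe: a heterogeneous mix of null
# and non-null effects over log-uniform trial sizes, shaped to exercise
# every evidence-pattern class.
n_trials: 200
effect_mixture:
  - [1.00, 0.40]
  - [0.80, 0.20]
  - [0.60, 0.15]
  - [0.40, 0.15]
  - [1.50, 0.10]
n_min: 20
n_max: 2000
cer_min: 0.05
cer_max: 0.50
allocations: ["1:1", "2:1", "3:2"]
seed: 0
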