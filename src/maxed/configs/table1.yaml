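# Operating-characteristic grid: five continuous-monitoring designs across
# the twelve standard two-dose scenarios (true toxicity 0.15 per arm).
# All decision thresholds are the package defaults: Pa=0.65, Pb=1.2,
# Pc=0.8, Pa*=0.7, Pd=0.11, Pe=0.7, Pf=0.65, Pg=1.3, Ph=0.65, Pi=0.65,
# Pj=0.4, Pk=0.02, delta=0.1; burn-in 24 total (12 per arm for the
# independent design), maximum 54 total (27 per arm independent).
designs:
  - bht-a
  - bht-b
  - indep-bht
  - bma
  - bit
toxicity:
  enabled: true
  priors: [[0.5, 16.5], [0.5, 8.5]]
  p_bar: 0.3
  Pc: 0.8
scenarios:
  - {response: [0.1, 0.1], toxicity: [0.15, 0.15]}
  - {response: [0.2, 0.2], toxicity: [0.15, 0.15]}
  - {response: [0.1, 0.2], toxicity: [0.15, 0.15]}
  - {response: [0.3, 0.3], toxicity: [0.15, 0.15]}
  - {response: [0.4, 0.4], toxicity: [0.15, 0.15]}
  - {response: [0.5, 0.5], toxicity: [0.15, 0.15]}
  - {response: [0.1, 0.3], toxicity: [0.15, 0.15]}
  - {response: [0.1, 0.4], toxicity: [0.15, 0.15]}
  - {response: [0.3, 0.4], toxicity: [0.15, 0.15]}
  - {response: [0.3, 0.5], toxicity: [0.15, 0.15]}
  - {response: [0.4, 0.5], toxicity: [0.15, 0.15]}
  - {response: [0.4, 0.6], toxicity: [0.15, 0.15]}
n_reps: 1000
seed: 20140729
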