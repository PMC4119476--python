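# Futility-only comparison grid: the futility-only BHT variant (stop on
# p(H0|x) > 0.848, close the lower arm on p(H1|x) > 0.848, end-of-trial
# claims above 0.5, H2/H3 marginal-ratio split at 1.37, 45 patients per
# arm) against three observed-rate variants of the independent Simon
# optimal two-stage design (17/45 per arm; H2 when RR1 >= RR2 - delta).
# Toxicity monitoring is off: this comparison considers efficacy only.
designs:
  - bht-futility
  - simon-i     # delta = 0.05
  - simon-ii    # delta = 0.03
  - simon-iii   # delta = 0.07
toxicity:
  enabled: false
scenarios:
  - {response: [0.1, 0.1]}
  - {response: [0.2, 0.2]}
  - {response: [0.1, 0.2]}
  - {response: [0.3, 0.3]}
  - {response: [0.4, 0.4]}
  - {response: [0.5, 0.5]}
  - {response: [0.1, 0.3]}
  - {response: [0.1, 0.4]}
  - {response: [0.3, 0.4]}
  - {response: [0.3, 0.5]}
  - {response: [0.4, 0.5]}
  - {response: [0.4, 0.6]}
n_reps: 1000
seed: 20140729
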