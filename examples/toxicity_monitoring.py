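"""Order-constrained continuous toxicity monitoring.

Builds the informative beta priors from toxicity-free phase I data (three
higher-level patients count as five lower-level patients), then shows the
isotonic-projection exceedance probabilities and the resulting actions.
"""

import numpy as np

from maxed import DoseData, ToxConfig, elicit_toxicity_priors, tox_action, tox_posterior_exceedance, weighted_pava

priors = elicit_toxicity_priors()  # four phase I levels, 3 patients each, 0 DLTs
print("elicited priors:", priors)  # Beta(0.5, 16.5) low dose, Beta(0.5, 8.5) high

cfg = ToxConfig(priors=tuple(priors))
rng = np.random.default_rng(0)
for tox, label in [((0, 1), "little toxicity"), ((2, 7), "worrying but tolerable"), ((8, 9), "toxic high dose")]:
    data = DoseData(x=(3, 4), n=(15, 15), tox=tox)
    exc = tox_posterior_exceedance(data, cfg, rng)
    action, doses = tox_action(exc, cfg)
    print(f"{label}: P(rate > 0.3) = ({exc[0]:.3f}, {exc[1]:.3f}) -> {action} {doses}")

# the projection itself: precision-weighted pooling restores the ordering
print("projection of (0.3, 0.1) with weights (3, 1):", weighted_pava([0.3, 0.1], [3, 1]))
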