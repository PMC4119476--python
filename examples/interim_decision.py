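"""Interim monitoring decisions for observed two-dose trial data.

Feeds per-dose response/toxicity counts to the joint hypothesis-testing
design (BHT-A) and the model-averaging design (BMA) and prints what each
would do next.
"""

from maxed import BHTConfig, BMAConfig, DoseData, bht_interim, bma_interim

# 12 patients per dose; the low dose looks inert, the high dose active
data = DoseData(x=(1, 6), n=(12, 12), tox=(0, 1))

dec = bht_interim(data, BHTConfig())
print("BHT-A posteriors:", {k: round(v, 3) for k, v in dec.posterior.items()})
print("BHT-A action:    ", dec.action, dec.conclusion or "")
# p(H1|x) dominates: the evidence says only the higher dose is promising,
# and the trial stops as soon as that posterior clears Pa = 0.65.

dec = bma_interim(data, BMAConfig())
print("BMA tails:       ", {k: round(v, 3) for k, v in dec.posterior.items()})
print("BMA action:      ", dec.action, dec.conclusion or "")
# Under model averaging the same data split their mass between p1 (both
# promising) and p2 (only the high dose promising): neither p1 > Pe = 0.7
# nor p2 + p3 > Pf = 0.65 holds yet, so the BMA design keeps enrolling
# where the sharper hypothesis test already stopped.
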