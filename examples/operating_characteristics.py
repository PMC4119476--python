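"""Simulate operating characteristics of the joint BHT design.

Runs the monitored two-dose design under a null and a fully promising
scenario (200 replicates each for speed; the published tables use 1,000)
and prints the conclusion frequencies.
"""

from maxed import BHTDesign, Scenario, operating_characteristics

design = BHTDesign()  # Pa=0.65, Pb=1.2, burn-in 24, max 54, toxicity monitored

for scenario in (
    Scenario(response=(0.1, 0.1), toxicity=(0.15, 0.15)),   # neither dose works
    Scenario(response=(0.3, 0.3), toxicity=(0.15, 0.15)),   # both hit the target
):
    oc = operating_characteristics(design, scenario, n_reps=200, seed=20140729)
    print(f"scenario {scenario.label}:")
    for k in ("H0", "H1", "H2", "H3", "H2*"):
        print(f"  P({k}) = {oc.probs[k]:.3f}")
    print(f"  avg sample size = {oc.avg_total_n:.1f}, inconclusive = {oc.pct_inconclusive:.3f}")
# Under the null the trial usually stops at the 24-patient burn-in look
# concluding H0; at the target rate it stops for H2* and the marginal
# ratio p(x|H2)/p(x|H3) > 1.2 refines most stops to H2 (equal rates, so
# the lower dose is the maximum effective dose).
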