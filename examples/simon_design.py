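"""Extend the Simon optimal two-stage design to two independent doses.

Controls overall type I error 5% / type II error 20% across two doses by
splitting the errors per arm, then searches exhaustively for the optimal
two-stage design at the per-arm rates.
"""

from maxed import Scenario, SimonTwoDoseConfig, SimonTwoDoseDesign, operating_characteristics, simon_optimal, split_errors

alpha, beta = split_errors(0.05, 0.2, J=2)
print(f"per-dose errors: alpha = {alpha:.4f}, beta = {beta:.4f}")

design = simon_optimal(p0=0.1, p1=0.3, alpha=alpha, beta=beta)
print(design)
# 17 patients in stage 1 (stop if <= 2 responses), 45 total (reject the
# dose if <= 8 responses); expected size under the null is ~23.7.

two_dose = SimonTwoDoseDesign(SimonTwoDoseConfig(design, delta=0.05))
oc = operating_characteristics(two_dose, Scenario(response=(0.1, 0.1)), n_reps=500, seed=20140729)
exact = (1 - design.alpha) ** 2
print(f"simulated P(conclude H0 | null) = {oc.probs['H0']:.3f}   exact (1-alpha)^2 = {exact:.4f}")
print(f"average total sample size       = {oc.avg_total_n:.1f}")
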