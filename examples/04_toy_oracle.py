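"""Analytic oracle check of the control-coefficient machinery.

A hub-and-chains toy network has closed-form coefficients under proportional
sibling rescale: +1 for the perturbed branch's own terminal species and
-f/(1-f) for every other branch.  The numerical scan must reproduce them to
high accuracy - this is the correctness anchor for the whole MCA pipeline.
"""

from liversim import SensitivityAnalysis, generate_toy_branch_network

doc, analytic = generate_toy_branch_network([0.2, 0.3, 0.5], chain_depth=2)
engine = SensitivityAnalysis(doc, sex=None, challenge=None)

print(f"{'perturbed':10s} {'observed':14s} {'analytic':>9s} {'computed':>10s}")
for (branch, terminal), expected in sorted(analytic.items()):
    c = engine.record(branch, terminal).headline
    print(f"{branch:10s} {terminal:14s} {expected:+9.4f} {c:+10.6f}")
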