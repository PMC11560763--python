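"""Recovering model parameters from noisy synthetic ELISA panels.

Generates replicate IL-6 readouts for the 10-condition panel with 10%
multiplicative noise, then fits the melanoma induced-transcription
capacity k1 by bounded multistart optimisation of a log-space
least-squares loss, and reports the recovery error against the
generating truth.
"""

import il6loop as il

obs = il.gen_cytokine_observations(cv=0.1, n_rep=3, seed=1)
print(obs.frame.head(6).to_string(index=False))
print(f"... {len(obs.frame)} rows total\n")

spec = il.FitSpec(free={"melanoma.k1": (0.5, 50.0)}, multistart=3, seed=1)
result = il.fit_parameters(obs, spec)
truth = {"melanoma.k1": il.kinetics_defaults().k1}  # the generating value
report = il.recovery_report(result, truth)
print(report.to_string(index=False))
print(f"\nloss at optimum: {result.loss_value:.4f} "
      f"(start losses: {[f'{v:.3f}' for v in result.start_losses]})")
print("The estimate lands within a few percent of the generating value;")
print("the residual loss reflects the injected measurement noise, not")
print("optimisation failure.")
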