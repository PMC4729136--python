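"""Generate a synthetic cohort and run the full evaluation pipeline.

Ten simulated participants each produce 400 time bins whose switch
decisions are Bernoulli draws from the model's own predictions, so the
cohort is perfectly calibrated by construction. The evaluation then fits
five logistic variants under leave-one-participant-out cross-validation
and reports AUC, precision/recall at 0.5, and per-participant switch-rate
agreement for each.
"""

from fluidevents import GeneratorParams, evaluate_cohort, generate_cohort

streams = generate_cohort(GeneratorParams(n_participants=10,
                                          bins_per_stream=400, seed=11))
report = evaluate_cohort(streams, seed=3)

print(f"{report.n_participants} participants, {report.n_bins} bins")
print(f"point-biserial r = {report.point_biserial:.3f} "
      f"(permuted baseline {report.randomized_r:+.3f})")
print(f"calibration slope = {report.calibration.slope:.3f}, "
      f"intercept = {report.calibration.intercept:+.3f}")
print()
print(report.variant_table().to_string(index=False))
print()
print("The summed-factor model should clearly beat the trial-number null")
print("(AUC well above 0.5), the individual-factor refit should match or")
print("slightly exceed it, and the permuted baseline should sit near zero.")
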