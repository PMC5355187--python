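"""A ground-truth-known synthetic monitoring study at the agouti scale.

Generates a scenario with a 65-species credit, rank-skewed encounter rates
(common species are found early, rare ones late) and a 36-month horizon,
then runs the whole accounting pipeline against it and compares the outcome
with the configured truth.
"""

from ecocredit import (
    AsymptoticFit,
    SyntheticScenario,
    accumulation_curve,
    estimate_credit,
    fit_accumulation,
    generate_scenario,
)

scenario = SyntheticScenario(seed=42)  # defaults: overlap=65, skew=1.5, 36 months
flora, reference, log, truth = generate_scenario(scenario)

est = estimate_credit(flora, reference)
curve = accumulation_curve(
    log, est.eligible_species, bin_width=1.0, horizon=scenario.horizon_months
)

print(f"true credit (configured overlap): {truth.credit0}")
print(f"estimated credit:                 {est.credit0}")
print(f"monitoring events:                {log.n_events}")
print(f"richness by month 15:             {curve.richness_at(15)}")
print(f"richness by month 36:             {curve.max_richness}")
print(f"remaining credit at month 36:     {est.credit0 - curve.max_richness}")

fit = fit_accumulation(curve)
if isinstance(fit, AsymptoticFit):
    print(f"fitted asymptote:                 {fit.asymptote:.1f}")

common = truth.eligible_species[0]
rare = truth.eligible_species[-1]
print(
    f"\nencounter rates: commonest {truth.rates[common]:.3f}/month, "
    f"rarest {truth.rates[rare]:.4f}/month — the rarest species may stay"
    "\nunobserved for years, which is why observed richness is a lower bound"
    "\non true rewiring and the curve flattens long before the credit is"
    "\nfully cashed."
)
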