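"""Accumulation curve, remaining credit, asymptotic fit, success criterion.

Feeds the toy monitoring log through the full accounting pipeline: monthly
accumulation of first-observed interactions, the remaining-credit ledger,
a Michaelis-Menten (Clench) extrapolation, and the a-priori success rule.
"""

from ecocredit import (
    AsymptoticFit,
    accumulation_curve,
    estimate_credit,
    fit_accumulation,
    read_flora,
    read_monitoring,
    read_reference,
    success_assessment,
)
from ecocredit.datasets import toy_diet_path, toy_flora_path, toy_monitoring_path

flora = read_flora(toy_flora_path())
reference = read_reference(toy_diet_path())
log = read_monitoring(toy_monitoring_path())

est = estimate_credit(flora, reference)
curve = accumulation_curve(log, est.eligible_species, bin_width=1.0, horizon=15)

print(curve.to_frame(credit0=est.credit0).to_string(index=False))
a = curve.audit
print(
    f"\nevent audit: {a.eligible_first} first observations, "
    f"{a.eligible_repeat} repeats, {a.unexpected} unexpected, "
    f"{a.beyond_horizon} beyond horizon (total {a.total_events})"
)

fit = fit_accumulation(curve, "michaelis_menten")
if isinstance(fit, AsymptoticFit):
    print(
        f"\nClench fit: asymptote={fit.asymptote:.1f} species, "
        f"half-saturation={fit.rate_or_halfsat:.1f} months"
    )
    print(f"extrapolated time to 90% of the asymptote: "
          f"{fit.time_to_fraction(0.9):.1f} months")

for proportion in (0.5, 1.0):
    r = success_assessment(curve, est.credit0, proportion)
    when = "not yet" if r.time_achieved is None else f"month {r.time_achieved:g}"
    print(
        f"success at proportion {proportion}: achieved={r.achieved} "
        f"(threshold {r.threshold} species, {when}); "
        f"proportion cashed so far: {r.proportion_cashed:.2f}"
    )
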