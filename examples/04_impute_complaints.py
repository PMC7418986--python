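"""Impute total complaints for years when only site visits were logged.

Phone-handled complaints went unrecorded in 1981-83 and 1986-95.  The
phone-handled fraction rose roughly linearly wherever both counts exist,
so a least-squares line on calendar year predicts the missing fraction
p(y), and the total is onsite / (1 - p).
"""

from ursaconflict import (
    SimConfig,
    anchors_from_series,
    fit_phone_trend,
    impute_totals,
    render_observables,
    simulate_truth,
)

cfg = SimConfig(seed=1)
truth = simulate_truth(cfg)
observed = render_observables(truth, cfg)

anchors = anchors_from_series(observed.complaints)
trend = fit_phone_trend(anchors)
print("anchor phone fractions:", {y: round(f, 3) for y, f in anchors.items()})
print(f"fitted trend: fraction = {trend.intercept:.3f} + {trend.slope:.5f} * year")

complaints = impute_totals(observed.complaints, trend)
print(complaints[complaints["imputed"] == 1].head(6).round(1).to_string(index=False))
print(f"\n{int(complaints['imputed'].sum())} of {len(complaints)} years imputed")
# Imputed totals inflate the recorded on-site counts by the estimated share
# of complaints that would have been handled by phone in those years.
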