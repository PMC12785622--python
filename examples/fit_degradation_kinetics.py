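"""Fit zero- and first-order kinetics to one stored-product quality series.

Loads the packaged consumer-panel study, takes the colour-acceptance series
for the clear plastic bag at 25 °C, prepends the week-0 baseline score, and
fits both reaction orders.  The rate constant k says how fast the hedonic
score decays (units/week for zero order, 1/week for first order); the order
with the higher R² is the one used for shelf-life prediction downstream.
"""

import shelfkin as sk

dataset = sk.builtin_fixture("table2_sensory")
condition = sk.StorageCondition("clear_plastic", 25.0)
series = dataset.get("color_acceptance", condition).with_baseline(
    dataset.baseline["color_acceptance"]
)

zero, first = sk.fit_both_orders(series)
best = sk.select_order(zero, first)

print(f"Colour acceptance, {condition} ({len(series)} sessions incl. baseline)")
for fit in (zero, first):
    print(
        f"  {fit.order:>5}-order: k = {fit.k:.4f}/week,  "
        f"Q0_hat = {fit.q0_hat:.2f},  R² = {fit.r_squared:.3f}"
    )
print(f"Selected order: {best.order} (higher R² wins, ties go to first order)")
print(
    f"Score the {best.order}-order model expects after 12 weeks: "
    f"{sk.predict_quality(best.order, best.k, best.q0_hat, 12.0):.2f}"
)
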