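"""Estimate activation energies from multi-temperature rate constants.

Uses the packaged table of printed first-order colour-acceptance rate
constants (4/25/35/45 °C per packaging) and regresses ln k on 1/T.  The
slope gives the activation energy Ea — the temperature sensitivity of the
browning-driven quality loss, in kJ/mol — and the fitted line lets you read
off k at any temperature, which is what makes accelerated (hot) storage
trials informative about ambient shelf life.
"""

import shelfkin as sk

rates = sk.builtin_fixture("table4_color_k")
table = sk.arrhenius_table(rates, order="first")

print("Activation energy per packaging (first-order colour-acceptance k):")
for _, row in table.iterrows():
    print(
        f"  {row['packaging']:<14} Ea = {row['ea_kj_mol']:5.2f} kJ/mol   "
        f"ln A = {row['ln_a']:6.2f}   R² = {row['r_squared']:.3f}   "
        f"({row['n_temps']} temperatures)"
    )

sub = rates[(rates["order"] == "first") & (rates["packaging"] == "clear_plastic")]
fit = sk.fit_arrhenius(
    sk.RatePoint(float(t), float(k))
    for t, k in zip(sub["temperature_c"], sub["k"])
)
print(
    f"\nClear plastic, extrapolated k at 30 °C: {sk.k_at(fit, 30.0):.4f}/week "
    f"(between the 25 °C and 35 °C inputs, as an Ea > 0 law requires)"
)
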