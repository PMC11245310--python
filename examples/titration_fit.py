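"""Titration holdup fitting with the partial-activity model FB = a*c/(c+Kd).

The amplitude a < 1 captures partial binding activity: only part of the prey
population is binding-competent, so the curve saturates below 1 even at
bait excess.
"""

from affinomap import fit_titration, make_dilution_series
from affinomap.synthetic import simulate_titration

# effective bait series from resin-mixing proportions of a 2 uM stock,
# two-fold steps spanning both sides of the expected Kd
props = [1 / 2**k for k in range(8)] + [0.0]
concs = make_dilution_series(2e-6, props)
print("Effective bait series (uM):", [round(float(c) * 1e6, 4) for c in concs])

# a prey with Kd = 100 nM and 60% active fraction, measured with 3% noise
curve = simulate_titration(100e-9, 0.6, concs, sd=0.03, seed=1, label="prey")
fit = fit_titration(curve)
print(
    f"\nFit: Kd = {fit.kd * 1e9:.1f} nM (pK {fit.pk:.2f}), "
    f"active fraction = {fit.active_fraction:.3f} "
    f"(+/- {fit.se_kd * 1e9:.1f} nM, {fit.se_active:.3f})"
)
print("Truth: Kd = 100 nM, active fraction = 0.600")
print("The sub-unity amplitude is the partial binding activity of the prey.")

# a flat curve is reported as censored, not force-fitted
flat = simulate_titration(1.0, 0.0, concs, sd=0.005, seed=2)
res = fit_titration(flat)
print(f"\nFlat curve -> no_binding = {res.no_binding} (no Kd is reported)")
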