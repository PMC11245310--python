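"""Core holdup arithmetic: depletion fraction <-> dissociation constant.

A holdup assay measures the fraction of prey depleted by bait-saturated
resin (binding intensity, BI). Under the single-site hyperbolic model this
converts directly to an equilibrium dissociation constant given the
immobilized-bait concentration.
"""

from affinomap import BaitConcentration, bi_to_kd, censor_affinity, kd_to_bi, kd_to_pk

bait = BaitConcentration.from_micromolar(10.0)

print("Anchor points of the pK scale (pK = -log10 Kd/M):")
for kd_uM in (100.0, 10.0, 1.4, 0.1):
    print(f"  Kd = {kd_uM:7.1f} uM  ->  pK = {kd_to_pk(kd_uM * 1e-6):.2f}")

print("\nDepletion at 10 uM bait:")
for bi in (0.5, 0.227273, 0.952381):
    kd = bi_to_kd(bi, bait)
    print(f"  BI = {bi:.3f}  ->  Kd = {kd * 1e6:6.2f} uM (pK {kd_to_pk(kd):.2f})")
print("  (BI = 0.5 is half-saturation: Kd equals the bait concentration)")

print("\nCensoring at a BI detection threshold of 0.128:")
for bi in (0.05, 0.128, 0.40):
    aff = censor_affinity(bi, 0.128, bait)
    tag = "below detection (pk is an upper bound)" if aff.censored else "quantified"
    print(f"  BI = {bi:.3f}  ->  pK {aff.pk:.2f}  [{tag}]")

print("\nForward model: BI expected for a 34 uM binder at 10 uM bait:")
print(f"  BI = {kd_to_bi(34e-6, bait):.4f}")
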