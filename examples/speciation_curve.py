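"""Casein charge-state speciation across the pH range of electroacidification.

Caseinate in the feed is soluble and negatively charged (Cas-).  As protons
injected by the bipolar membrane lower the local pH toward the isoelectric
region, casein converts to its neutral, insoluble form HCas0 (pKa = 4.8 on
the mol/L scale); that species is what deposits on the membrane.
"""

from foulsim import equilibrium_speciation

TOTAL = 13.0  # mol/m^3, total casein in the model feed

print(f"{'pH':>5} {'Cas- (mol/m3)':>14} {'HCas0 (mol/m3)':>15} {'% neutral':>10}")
for ph in (6.5, 6.0, 5.5, 5.0, 4.8, 4.5, 4.0, 3.5, 3.0):
    c_cas, c_h0 = equilibrium_speciation(TOTAL, ph)
    print(f"{ph:5.1f} {c_cas:14.3f} {c_h0:15.3f} {100 * c_h0 / TOTAL:9.1f}%")

print()
print("At the bulk pH of 6.5 casein is ~98% dissociated; at the pulse-end")
print("surface pH of ~2.8 it is almost entirely neutral, which is why the")
print("deposit forms at the membrane and redissolves as the pause lets the")
print("pH recover above ~5.")
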