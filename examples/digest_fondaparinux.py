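"""Exolytic digestion of fondaparinux, the 3-O-sulfated pentasaccharide.

The exolytic heparinase releases exactly one trisulfated disaccharide
(carrying the methyl-glycoside reducing end) and then stalls: the next
release would contain the 3-O-sulfated glucosamine, which blocks cleavage,
and the DP3 remainder is below the enzyme's minimum substrate size.
"""

import hepseq as hs

fonda = hs.fixtures()["fondaparinux"]
print("substrate:", hs.format_chain(fonda))

result = hs.digest_exo(fonda)
print("released: ", [hs.format_chain(c) for c in result.released])
print("remainder:", hs.format_chain(result.remainder))

formula = hs.formula_of(fonda)
print(f"substrate formula {formula}  monoisotopic {formula.monoisotopic_mass:.4f} Da")
for z in (1, 2, 3):
    print(f"  [M-{z}H]{z}-  m/z {hs.mz(formula.monoisotopic_mass, z):.4f}")
# One DP2 product and an inert 3S-containing trisaccharide remainder mirror
# the single-disaccharide chromatogram seen for this substrate.
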