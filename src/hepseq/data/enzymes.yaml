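# Default heparin-lyase specificity specs.
#
# cleavable_uronate_classes: which uronate sulfation class on the RE side of a
#   hexosamine->uronate linkage the enzyme accepts ("2S-uronate" = GlcA2S/IdoA2S,
#   "unsulfated-uronate" = GlcA/IdoA).  Epimer-level rate preferences are a
#   kinetics concern, not part of this yes/no predicate.
# blocks_on_3S: a site is uncleavable when the hexosamine at the +2 subsite
#   (the one that ends up in the new Delta-bearing disaccharide) carries 3-O-sulfate.
# min_substrate_dp: shortest chain the enzyme acts on (4 for the exolytic enzyme,
#   whose smallest demonstrated substrate is a tetrasaccharide; 3 for endolytic).
hepI:
  mode: endo
  cleavable_uronate_classes: [2S-uronate]
  blocks_on_3S: true
  min_substrate_dp: 3
hepII:
  mode: endo
  cleavable_uronate_classes: [2S-uronate, unsulfated-uronate]
  blocks_on_3S: true
  min_substrate_dp: 3
hepIII:
  mode: endo
  cleavable_uronate_classes: [unsulfated-uronate]
  blocks_on_3S: true
  min_substrate_dp: 3
exoHep:
  mode: exo
  cleavable_uronate_classes: [2S-uronate, unsulfated-uronate]
  blocks_on_3S: true
  min_substrate_dp: 4
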