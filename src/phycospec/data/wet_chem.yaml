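# Spectrophotometric pigment-equation coefficients, treated by the code as
# opaque linear maps so any coefficient set can be swapped in.
#
# phyco_matrix: rows (PE, PC, APC) x absorbances (A498, A614, A651),
# transcribed from the red-algal phycobiliprotein equations of
# Kursar, van der Meer & Alberte (1983) and rescaled from ug/mL to mg/mL
# extract so that tissue content (mg/g) = extract_conc * volume / weight.
#
# chla_vector: (A646, A663) coefficients for chlorophyll-a in 80% (v/v)
# acetone from Wellburn (1994), same mg/mL rescaling.
phyco_matrix:
  - [0.1558,  -0.0400, -0.0105]
  - [0.0,      0.1511, -0.0991]
  - [0.0,     -0.0223,  0.1813]
chla_vector: [-0.00281, 0.01221]

# Extraction protocol scale: two 4 mL phosphate-buffer extractions pooled for
# the phycobiliproteins, one 6 mL acetone extraction for chlorophyll, on a
# nominal 0.5 g fresh-weight subsample.
extract_volume_phyco: 8.0
extract_volume_chl: 6.0
fresh_weight: 0.5

# Fixed A646/A663 shape ratio of a pure chlorophyll-a extract, used only to
# close the otherwise underdetermined concentration -> absorbance inverse
# when simulating readings.
a646_over_a663: 0.35
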