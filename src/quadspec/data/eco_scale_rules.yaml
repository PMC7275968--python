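# Analytical Eco-Scale penalty rule tables.
#
# Editable, versioned constants.  A reagent's penalty is
# amount_points x hazard_points; hazard_points is the number of GHS
# pictograms multiplied by the signal-word score (warning: 1, danger: 2).
# A non-hazardous reagent (hazard_points 0) therefore contributes zero
# penalty under the literal multiplication rule, which is the arithmetic
# the worked example sheet in this package reproduces.
reagent_amount_points:
  "<10 mL (<10 g)": 1
  "10-100 mL (10-100 g)": 2
  ">100 mL (>100 g)": 3
signal_word_score:
  none: 0
  warning: 1
  danger: 2
instrument_energy_points:
  "<=0.1 kWh per sample": 0
  "<=1.5 kWh per sample": 1
  ">1.5 kWh per sample": 2
occupational_hazard_points:
  "hermetic process": 0
  "emission of vapors and gases to the air": 3
waste_points:
  none: 0
  "<1 mL (<1 g)": 1
  "1-10 mL (1-10 g)": 3
  ">10 mL (>10 g)": 5
common_reagent_hazards:   # pictograms, signal word
  water: {pictograms: 0, signal_word: none}
  ethanol: {pictograms: 1, signal_word: danger}
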