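# Default QQQ source/collision voltages for Amadori-PE acquisition.
# DP declustering potential, EP entrance potential, CE collision energy,
# CXP collision cell exit potential; all in volts.  These were optimized
# empirically on a 4000 QTRAP with each synthetic standard, so they are
# configuration, not computation.  The PIS DP entries are ramp ranges
# and are stored as opaque strings.
mrm:
  "34:1 Glc-PE": {DP: 120, EP: 10, CE: 45, CXP: 18}
  "36:1 Glc-PE": {DP: 102, EP: 10, CE: 53, CXP: 18}
  "36:2 Glc-PE": {DP: 102, EP: 10, CE: 53, CXP: 18}
  "34:1 Lac-PE": {DP: 125, EP: 10, CE: 56, CXP: 30}
  "36:1 Lac-PE": {DP: 115, EP: 10, CE: 57, CXP: 28}
  "36:2 Lac-PE": {DP: 115, EP: 10, CE: 57, CXP: 28}
# Fallback voltages for species without an explicit entry, per sugar class.
mrm_class_defaults:
  glucose: {DP: 102, EP: 10, CE: 53, CXP: 18}
  lactose: {DP: 115, EP: 10, CE: 57, CXP: 28}
pis:
  glucose: {DP: "90-156", EP: 10, CE: 45, CXP: 18}
  lactose: {DP: "115-166", EP: 10, CE: 56, CXP: 28}
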