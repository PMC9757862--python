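# Default annotation mass-list configuration.
#
# Classes and carbon / double-bond ranges approximate the composition of a
# routine human-plasma DIMS annotation list (several thousand (m/z, species,
# adduct) entries across both polarities). Adduct sets follow standard
# direct-infusion plasma lipidomics practice.
mz_window: [150.0, 1200.0]
adducts:
  positive: ["[M+H]+", "[M+NH4]+", "[M+Na]+"]
  negative: ["[M-H]-", "[M+CH3COO]-"]
classes:
  TG: {carbons: [38, 64], double_bonds: [0, 10]}
  DG: {carbons: [26, 46], double_bonds: [0, 8]}
  PC: {carbons: [26, 46], double_bonds: [0, 10]}
  PE: {carbons: [26, 46], double_bonds: [0, 10]}
  SM: {carbons: [28, 46], double_bonds: [0, 5]}
  CE: {carbons: [12, 24], double_bonds: [0, 6]}
  FA: {carbons: [10, 26], double_bonds: [0, 6]}
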