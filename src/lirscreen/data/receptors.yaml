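# Receptor anchor tables for the LIR/SIM interface classifier.
#
# LC3/Atg8-family entries define, in receptor residue numbering:
#   hp0/hp1/hp2: two anchor Calpha residues with distance cutoffs (Angstrom);
#     a peptide residue engages the pocket when any of its heavy atoms is
#     within cutoff1 of anchor1's Calpha AND within cutoff2 of anchor2's Calpha.
#   hp0_gate: HP0 is usable only when the pocket is open, i.e. the minimum
#     distance between anchor1's Calpha and any non-hydrogen sidechain atom of
#     the gate residue exceeds open_threshold.
#   beta2: the beta-2 strand between HP1 and HP2 (backbone H-bond partner of
#     canonical LIRs, and LDS-proximity reference).
#   uds: the UIM-docking-site residues.
# SUMO entries define only the SIM-binding-groove beta strand.
version: 1
receptors:
  LC3B:
    family: LC3
    hp0: {anchor1: 7,  cutoff1: 4.50, anchor2: 34,  cutoff2: 6.25}
    hp0_gate: {ca_residue: 7, sidechain_residue: 50, open_threshold: 9.0}
    hp1: {anchor1: 52, cutoff1: 5.25, anchor2: 108, cutoff2: 9.75}
    hp2: {anchor1: 54, cutoff1: 4.75, anchor2: 67,  cutoff2: 9.50}
    beta2: [50, 55]
    uds: [79, 82]
  ATG8E:
    family: LC3
    hp0: {anchor1: 7,  cutoff1: 4.50, anchor2: 34,  cutoff2: 6.25}
    hp0_gate: {ca_residue: 7, sidechain_residue: 49, open_threshold: 9.0}
    hp1: {anchor1: 51, cutoff1: 5.25, anchor2: 106, cutoff2: 9.75}
    hp2: {anchor1: 53, cutoff1: 4.75, anchor2: 66,  cutoff2: 9.50}
    beta2: [49, 54]
    uds: [78, 81]
  ATG8CL:
    family: LC3
    hp0: {anchor1: 6,  cutoff1: 4.50, anchor2: 33,  cutoff2: 6.25}
    hp0_gate: {ca_residue: 6, sidechain_residue: 48, open_threshold: 9.0}
    hp1: {anchor1: 50, cutoff1: 5.25, anchor2: 105, cutoff2: 9.75}
    hp2: {anchor1: 52, cutoff1: 4.75, anchor2: 65,  cutoff2: 9.50}
    beta2: [48, 53]
    uds: [77, 80]
  GABARAP:
    family: LC3
    hp0: {anchor1: 5,  cutoff1: 4.50, anchor2: 32,  cutoff2: 6.25}
    hp0_gate: {ca_residue: 5, sidechain_residue: 47, open_threshold: 9.0}
    hp1: {anchor1: 49, cutoff1: 5.25, anchor2: 104, cutoff2: 9.75}
    hp2: {anchor1: 51, cutoff1: 4.75, anchor2: 64,  cutoff2: 9.50}
    beta2: [47, 52]
    uds: [76, 79]
  Atg8:
    family: LC3
    hp0: {anchor1: 5,  cutoff1: 4.50, anchor2: 32,  cutoff2: 6.25}
    hp0_gate: {ca_residue: 5, sidechain_residue: 47, open_threshold: 9.0}
    hp1: {anchor1: 49, cutoff1: 5.25, anchor2: 104, cutoff2: 9.75}
    hp2: {anchor1: 51, cutoff1: 4.75, anchor2: 64,  cutoff2: 9.50}
    beta2: [47, 52]
    uds: [76, 79]
  SUMO2:
    family: SUMO
    sim_groove: [29, 34]
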