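{
  "_comment": "Amino-acid residue masses (Da) and ionizable-group pKa sets. Residue masses are for the residue within a peptide chain (monomer minus water); a free peptide adds one water. Modification deltas are additive mass shifts. pKa sets: EMBOSS (iep) and Bjellqvist; side-chain keys are one-letter residue codes, 'nterm'/'cterm' are the free termini.",
  "residue_mono": {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931
  },
  "residue_avg": {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132
  },
  "water_mono": 18.010565,
  "water_avg": 18.01528,
  "modifications": {
    "carbamidomethyl_c": {"target": "C", "mono": 57.02146, "avg": 57.0513},
    "oxidation_m": {"target": "M", "mono": 15.9949, "avg": 15.9994}
  },
  "pka_sets": {
    "emboss": {
      "nterm": 8.6, "cterm": 3.6,
      "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
      "K": 10.8, "R": 12.5, "Y": 10.1
    },
    "bjellqvist": {
      "nterm": 7.5, "cterm": 3.55,
      "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98,
      "K": 10.0, "R": 12.0, "Y": 10.0
    }
  }
}
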