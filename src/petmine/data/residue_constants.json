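{
  "comment": "Per-residue physical constants. max_asa: theoretical maximum solvent-accessible surface area (A^2, Tien et al. 2013 theoretical scale). heat_capacity: partial molar heat capacity (cal mol^-1 K^-1, Hutchens 1970). mass: average residue (monomer minus water) mass in Da. pka: ionizable-group pKa values (EMBOSS set). background: SwissProt-like amino-acid frequencies used as the default null/background distribution.",
  "max_asa": {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0
  },
  "heat_capacity": {
    "A": 29.22, "R": 26.37, "N": 38.30, "D": 37.09, "C": 50.70,
    "Q": 44.02, "E": 41.84, "G": 23.71, "H": 59.64, "I": 45.00,
    "L": 48.03, "K": 57.10, "M": 69.32, "F": 48.52, "P": 36.13,
    "S": 32.40, "T": 35.20, "W": 56.92, "Y": 51.73, "V": 40.35
  },
  "mass": {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13
  },
  "water_mass": 18.02,
  "pka": {
    "n_terminus": 8.6, "c_terminus": 3.6,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    "H": 6.5, "K": 10.8, "R": 12.5
  },
  "background": {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0473,
    "S": 0.0665, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686
  }
}
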