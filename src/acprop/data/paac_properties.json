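{
 "hydrophobicity": {
  "A": 0.62,
  "C": 0.29,
  "D": -0.9,
  "E": -0.74,
  "F": 1.19,
  "G": 0.48,
  "H": -0.4,
  "I": 1.38,
  "K": -1.5,
  "L": 1.06,
  "M": 0.64,
  "N": -0.78,
  "P": 0.12,
  "Q": -0.85,
  "R": -2.53,
  "S": -0.18,
  "T": -0.05,
  "V": 1.08,
  "W": 0.81,
  "Y": 0.26
 },
 "hydrophilicity": {
  "A": -0.5,
  "C": -1.0,
  "D": 3.0,
  "E": 3.0,
  "F": -2.5,
  "G": 0.0,
  "H": -0.5,
  "I": -1.8,
  "K": 3.0,
  "L": -1.8,
  "M": -1.3,
  "N": 0.2,
  "P": 0.0,
  "Q": 0.2,
  "R": 3.0,
  "S": 0.3,
  "T": -0.4,
  "V": -1.5,
  "W": -3.4,
  "Y": -2.3
 },
 "side_chain_mass": {
  "A": 15.0,
  "C": 47.0,
  "D": 59.0,
  "E": 73.0,
  "F": 91.0,
  "G": 1.0,
  "H": 82.0,
  "I": 57.0,
  "K": 73.0,
  "L": 57.0,
  "M": 75.0,
  "N": 58.0,
  "P": 42.0,
  "Q": 72.0,
  "R": 101.0,
  "S": 31.0,
  "T": 45.0,
  "V": 43.0,
  "W": 130.0,
  "Y": 107.0
 }
}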