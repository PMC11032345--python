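{
 "CIDH920105": {
  "A": 0.02,
  "C": 0.77,
  "D": -1.04,
  "E": -1.14,
  "F": 1.35,
  "G": -0.8,
  "H": 0.26,
  "I": 1.81,
  "K": -0.41,
  "L": 1.14,
  "M": 1.0,
  "N": -0.77,
  "P": -0.09,
  "Q": -1.1,
  "R": -0.42,
  "S": -0.97,
  "T": -0.77,
  "V": 1.13,
  "W": 1.71,
  "Y": 1.11
 },
 "BHAR880101": {
  "A": 0.357,
  "C": 0.346,
  "D": 0.511,
  "E": 0.497,
  "F": 0.314,
  "G": 0.544,
  "H": 0.323,
  "I": 0.462,
  "K": 0.466,
  "L": 0.365,
  "M": 0.295,
  "N": 0.463,
  "P": 0.509,
  "Q": 0.493,
  "R": 0.529,
  "S": 0.507,
  "T": 0.444,
  "V": 0.386,
  "W": 0.305,
  "Y": 0.42
 },
 "CHAM820101": {
  "A": 0.046,
  "C": 0.128,
  "D": 0.105,
  "E": 0.151,
  "F": 0.29,
  "G": 0.0,
  "H": 0.23,
  "I": 0.186,
  "K": 0.219,
  "L": 0.186,
  "M": 0.221,
  "N": 0.134,
  "P": 0.131,
  "Q": 0.18,
  "R": 0.291,
  "S": 0.062,
  "T": 0.108,
  "V": 0.14,
  "W": 0.409,
  "Y": 0.298
 },
 "CHAM820102": {
  "A": -0.368,
  "C": 4.53,
  "D": 2.06,
  "E": 1.77,
  "F": 1.06,
  "G": -0.525,
  "H": 0.0,
  "I": 0.791,
  "K": 0.0,
  "L": 1.07,
  "M": 0.656,
  "N": 0.0,
  "P": -2.24,
  "Q": 0.731,
  "R": -1.03,
  "S": -0.524,
  "T": 0.0,
  "V": 0.401,
  "W": 1.6,
  "Y": 4.91
 },
 "CHOC760101": {
  "A": 115,
  "C": 135,
  "D": 150,
  "E": 190,
  "F": 210,
  "G": 75,
  "H": 195,
  "I": 175,
  "K": 200,
  "L": 170,
  "M": 185,
  "N": 160,
  "P": 145,
  "Q": 180,
  "R": 225,
  "S": 115,
  "T": 140,
  "V": 155,
  "W": 255,
  "Y": 230
 },
 "BIGC670101": {
  "A": 52.6,
  "C": 68.3,
  "D": 68.4,
  "E": 84.7,
  "F": 113.9,
  "G": 36.3,
  "H": 91.9,
  "I": 102.0,
  "K": 105.1,
  "L": 102.0,
  "M": 97.7,
  "N": 75.7,
  "P": 73.6,
  "Q": 89.7,
  "R": 109.1,
  "S": 54.9,
  "T": 71.2,
  "V": 85.1,
  "W": 135.4,
  "Y": 116.2
 },
 "CHAM810101": {
  "A": 0.52,
  "C": 0.62,
  "D": 0.76,
  "E": 0.68,
  "F": 0.7,
  "G": 0.0,
  "H": 0.7,
  "I": 1.02,
  "K": 0.68,
  "L": 0.98,
  "M": 0.78,
  "N": 0.76,
  "P": 0.36,
  "Q": 0.68,
  "R": 0.68,
  "S": 0.53,
  "T": 0.5,
  "V": 0.76,
  "W": 0.7,
  "Y": 0.7
 },
 "DAYM780201": {
  "A": 100,
  "C": 20,
  "D": 106,
  "E": 102,
  "F": 41,
  "G": 49,
  "H": 66,
  "I": 96,
  "K": 56,
  "L": 40,
  "M": 94,
  "N": 134,
  "P": 56,
  "Q": 93,
  "R": 65,
  "S": 120,
  "T": 97,
  "V": 74,
  "W": 18,
  "Y": 41
 }
}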