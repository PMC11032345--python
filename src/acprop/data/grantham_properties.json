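{
 "alpha": 1.833,
 "beta": 0.1018,
 "gamma": 0.000399,
 "rho": 50.723,
 "composition": {
  "A": 0.0,
  "C": 2.75,
  "D": 1.38,
  "E": 0.92,
  "F": 0.0,
  "G": 0.74,
  "H": 0.58,
  "I": 0.0,
  "K": 0.33,
  "L": 0.0,
  "M": 0.0,
  "N": 1.33,
  "P": 0.39,
  "Q": 0.89,
  "R": 0.65,
  "S": 1.42,
  "T": 0.71,
  "V": 0.0,
  "W": 0.13,
  "Y": 0.2
 },
 "polarity": {
  "A": 8.1,
  "C": 5.5,
  "D": 13.0,
  "E": 12.3,
  "F": 5.2,
  "G": 9.0,
  "H": 10.4,
  "I": 5.2,
  "K": 11.3,
  "L": 4.9,
  "M": 5.7,
  "N": 11.6,
  "P": 8.0,
  "Q": 10.5,
  "R": 10.5,
  "S": 9.2,
  "T": 8.6,
  "V": 5.9,
  "W": 5.4,
  "Y": 6.2
 },
 "volume": {
  "A": 31.0,
  "C": 55.0,
  "D": 54.0,
  "E": 83.0,
  "F": 132.0,
  "G": 3.0,
  "H": 96.0,
  "I": 111.0,
  "K": 119.0,
  "L": 111.0,
  "M": 105.0,
  "N": 56.0,
  "P": 32.5,
  "Q": 85.0,
  "R": 124.0,
  "S": 32.0,
  "T": 61.0,
  "V": 84.0,
  "W": 170.0,
  "Y": 136.0
 }
}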