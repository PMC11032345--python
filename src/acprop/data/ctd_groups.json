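{
 "prop1": {
  "name": "hydrophobicity",
  "G1": "RKEDQN",
  "G2": "GASTPHY",
  "G3": "CLVIMFW"
 },
 "prop2": {
  "name": "normalized_vdw_volume",
  "G1": "GASTPDC",
  "G2": "NVEQIL",
  "G3": "MHKFRYW"
 },
 "prop3": {
  "name": "polarity",
  "G1": "LIFWCMVY",
  "G2": "PATGS",
  "G3": "HQRKNED"
 },
 "prop4": {
  "name": "polarizability",
  "G1": "GASDT",
  "G2": "CPNVEQIL",
  "G3": "KMHFRYW"
 },
 "prop5": {
  "name": "charge",
  "G1": "KR",
  "G2": "ANCQGHILMFPSTWYV",
  "G3": "DE"
 },
 "prop6": {
  "name": "secondary_structure",
  "G1": "EALMQKRH",
  "G2": "VIYCWFT",
  "G3": "GNPSD"
 },
 "prop7": {
  "name": "solvent_accessibility",
  "G1": "ALFCGIVW",
  "G2": "RKQEND",
  "G3": "MSPTHY"
 }
}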