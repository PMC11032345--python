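kinase,uniprot,aa_count,n_structures,n_inhibitors,n_mmps,n_acs,acs_over_mmps_pct,test_set
ABL1,P00519,1130,12,1414,858,24,2.8,1
ACK1(TNK2),Q07912,1038,7,376,54,1,1.9,0
AKT2,P31751,481,4,784,201,0,0.0,0
ALK,Q9UM73,1620,18,827,194,0,0.0,0
AURKA (Aurora A),O14965,403,19,1137,341,5,1.5,1
AXL(UFO),P30530,894,1,434,87,0,0.0,0
BRK(PTK6),Q13882,451,2,398,65,1,1.5,0
BTK,Q06187,659,18,764,170,1,0.6,0
CAMK2D,Q13557,499,4,626,153,0,0.0,0
CDK2,P24941,298,20,1115,541,21,3.9,0
CHEK1 (CHK1),O14757,476,19,1041,272,4,1.5,0
CHEK2,O96017,543,20,675,165,0,0.0,0
CLK2,P49760,499,6,886,220,5,2.3,0
CLK4,Q9HAZ1,481,1,985,208,4,1.9,0
CNK(PLK3),Q9H4B4,646,1,722,184,0,0.0,0
CSF1R (FMS),P07333,972,7,959,254,11,4.3,1
CSNK1A1 (CK1α1),P48729,337,1,919,224,0,0.0,0
CSNK1D,P48730,415,17,733,186,0,0.0,0
CSNK2A1(CK2α1),P68400,391,19,814,215,6,2.8,0
DAPK3 (ZIPK),O43293,454,5,919,249,2,0.8,0
DCLK1,O15075,740,5,608,129,0,0.0,0
DYRK1A,Q13627,763,20,1047,275,6,2.2,1
EGFR (ErbB1),P00533,1210,17,1557,419,11,2.6,0
EPHA2(ECK),P29317,976,17,694,174,1,0.6,0
FAK1(PTK2),Q05397,1052,19,725,158,0,0.0,0
FES,P07332,822,1,392,68,0,0.0,1
FGFR1,P11362,822,8,986,252,1,0.4,1
FGFR3(JTK4),P22607,806,2,657,160,0,0.0,0
FLT1,P17948,1338,1,1588,286,11,3.8,1
FLT3,P36888,993,5,1025,275,7,2.5,0
FYN,P06241,537,1,1665,325,2,0.6,0
GSK3B (GSK3 beta),P49841,420,20,1356,529,35,6.6,0
HCCS-4,Q9NYL2,800,3,604,125,0,0.0,0
HER2 (erbB2),P04626,1255,2,1390,222,0,0.0,0
HER4 (ErbB4),Q15303,1308,2,670,167,0,0.0,1
HIPK2,Q9H2X6,1198,2,680,175,0,0.0,0
IGF1R,P08069,1367,11,870,257,0,0.0,0
INSR,P06213,1382,2,734,183,0,0.0,0
IRAK4,Q9NWZ3,460,20,869,264,3,1.1,0
ITK,Q08881,620,8,736,181,1,0.6,1
JAK2,O60674,1132,20,1743,816,19,2.3,0
KDR (VEGFR2),P35968,1356,14,1276,372,8,2.2,0
KIT(SCFR),P10721,976,5,688,184,15,8.2,0
KRS1(MST2),Q13188,491,1,810,228,1,0.4,0
LCK,P06239,509,20,1761,353,1,0.3,0
LIMK1,P53667,647,4,762,169,0,0.0,0
LYN,P07948,512,2,619,171,0,0.0,0
MAP4K4 (HGK),O95819,1239,14,980,251,8,3.2,0
MAPK1 (ERK2),P28482,360,19,1653,387,2,0.5,1
MAPK13(SAPK4),O15264,365,4,730,185,0,0.0,1
MAPK8 (JNK1),P45983,427,12,927,220,0,0.0,0
MAPKA(3PK) (3pK),Q16644,382,5,737,192,0,0.0,1
MARK2(EMK1),Q7KZI7,788,3,646,161,0,0.0,0
MELK(PK38),Q14680,651,18,576,142,5,3.5,0
MET,P08581,1390,18,1265,352,1,0.3,0
NEK2,P51955,445,19,894,220,0,0.0,1
NTRK1 (TRKA),P04629,796,17,884,222,1,0.5,1
NTRK2 (TRKB),Q16620,822,3,919,234,2,0.9,0
NTRK3 (TRKC),Q16288,839,4,680,142,1,0.7,0
PAK1,Q13153,545,8,879,256,0,0.0,0
PAK4,O96013,591,13,1197,354,0,0.0,1
PDK1,Q15118,436,20,709,179,0,0.0,0
PHKG2(PSK-C3),P15735,406,1,580,116,0,0.0,1
PI3K-alpha,P42336,1068,13,1075,672,8,1.2,0
PIM1,P11309,313,17,2498,1372,17,1.2,1
PIM2,Q9P1W9,311,2,866,286,5,1.7,0
PKN2(PRKCL2),Q16513,984,1,701,167,4,2.4,1
PLK1,P53350,603,5,829,218,1,0.5,0
PRKACA (PKA),P17612,351,17,1167,377,0,0.0,1
PRKCI (PKCiota),P41743,596,5,479,99,0,0.0,0
PYK2(FAK2),Q14289,1009,9,427,85,0,0.0,0
RET,P07949,1114,17,727,138,3,2.2,0
ROCK1,Q13464,1354,19,1127,382,0,0.0,0
RPS6KA3 (RSK2),P51812,740,8,1000,260,2,0.8,0
RPS6KB1 (S6K1),P23443,525,13,716,184,5,2.7,0
SRC,P12931,536,6,1056,547,7,1.3,0
SRPK1,Q96SB4,655,6,609,127,0,0.0,0
SYK,P43405,635,18,591,165,0,0.0,0
TYK2,P29597,1187,3,802,283,0,0.0,0
cTAK1(MARK3),P27448,753,1,760,202,1,0.5,0
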