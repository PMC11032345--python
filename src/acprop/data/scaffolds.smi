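# drug-like scaffold cores (>=10 heavy atoms), one attachment point [*:1]
# library is MMP-closed over the bundled substituents: no two scaffolds
# can yield molecules sharing a valid single-cut core
c1ncc2cc([*:1])ccc2n1
c1ccc(-c2ccc([*:1])cc2)cc1
c1ccc2c(c1)[nH]c1ccc([*:1])cc12
c1ccc2ncc([*:1])cc2c1
c1ccc2cc(C[*:1])ccc2c1
c1ccc(COc2ccc([*:1])cc2)cc1
Cc1ccc2nc([*:1])sc2c1
Fc1ccc2nc([*:1])[nH]c2c1
Cn1nc([*:1])c2cncnc21
c1cc([*:1])ccc1N1CCOCC1
Cc1cc(S(C)(=O)=O)ccc1[*:1]
c1cc(-c2ccc([*:1])cc2)ccn1
c1cncc(-c2ccc([*:1])cc2)c1
c1ccc(Oc2ccc([*:1])cc2)cc1
c1ccc(Cc2ccc([*:1])cc2)cc1
c1ccc(N2CCN([*:1])CC2)cc1
Cc1csc2ccc([*:1])cc12
c1cc2c(cc1[*:1])CCCC2
c1ccc(N2CCC([*:1])CC2)cc1
c1cc([*:1])ccc1CN1CCCC1
c1ccc(-c2ncc([*:1])cn2)cc1
c1cc2cc([*:1])ccc2cn1
c1ccc(-n2cc([*:1])cn2)cc1
c1ccc(-c2nc([*:1])cs2)cc1
c1ccc(-c2nnc([*:1])o2)cc1
c1ccc(-c2noc([*:1])n2)cc1
c1cc([*:1])ccc1OC1CCCC1
c1ccc2c(c1)CCN([*:1])C2
c1cnc2cc([*:1])ccc2n1
c1ccc(CCc2ccc([*:1])cc2)cc1
c1cc([*:1])ccc1CN1CCOCC1
Cc1cc(C)c2ccc([*:1])cc2n1
Cc1nc2cc([*:1])ccc2n1C
c1cc(N2CCCCC2)ncc1[*:1]
O=S(=O)(c1ccc([*:1])cc1)N1CCOCC1
O=S(=O)(c1ccc([*:1])cc1)N1CCCCC1
CN1CCN(Cc2ccc([*:1])cc2)CC1
Cc1nc(N2CCOCC2)ncc1[*:1]
Cc1nc([*:1])c2cc(C)sc2n1
Cc1c([*:1])sc2ncncc12
CC(C)c1c([*:1])oc2ccccc12
CS(=O)(=O)N1CCC([*:1])C(c2ccccc2)C1
O=C(C1CC1)N1CCC([*:1])CC1
c1cc2c(cc1[*:1])ncn2C1CCCC1
c1cnc2sc3cc([*:1])ccc3c2c1
c1cc2oc3cc([*:1])ccc3c2cn1
c1nc(C2CCOCC2)cc([*:1])n1
Cc1nc(-c2ccc([*:1])c(F)c2)cs1
c1ccc(N2CCOC([*:1])C2)nc1
c1csc(CN2CCC([*:1])C2)c1
Fc1cc(OCC2COC2)ccc1[*:1]
O=C(c1ccc([*:1])cc1)N1CCCC1
O=C(c1ccc([*:1])c(F)c1)N1CCOCC1
CCc1cc(OC)c(OC)cc1[*:1]
Fc1cc([*:1])c(F)cc1N1CCCC1
c1cc2c([*:1])nc(C3CC3)nc2[nH]1
CCc1nc([*:1])c(-c2ccccc2)s1
CC(C)Cc1nnc([*:1])n1C1CC1
Cc1c([*:1])cnn1CC1CCC1
Cn1c(=O)cc([*:1])c2ccccc21
c1sc(N2CCCC2)nc1[*:1]
c1ncn(C2CCC([*:1])CC2)n1
c1ccc(OC2CCC([*:1])CC2)cc1
Fc1ccccc1CC1CCC([*:1])CC1
CC1(c2ccc([*:1])cc2)CCOCC1
CCc1nnc2ccc([*:1])cn12
Cc1c([*:1])nc2ccccn12
Cc1c([*:1])ccn2cccc12
Clc1ccc2[nH]c([*:1])cc2c1
Brc1ccc2oc([*:1])cc2c1
N#Cc1ccc2cc([*:1])sc2c1
Cc1ccc(-c2ccc([*:1])cc2)s1
Cc1ccc(-c2ccc([*:1])cn2)o1
Fc1ccccc1-c1cnc([*:1])nc1
O=C1CCC(=O)N1c1ccc([*:1])cc1
CN1CCN(C(=O)c2ccco2)CC1[*:1]
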