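# Aqueous adsorption energies (kcal/mol) of 54 organic compounds on PE, POM and
# PVA microplastics from DFT computations, with curated SMILES.
# Curation notes:
#  - SMILES assigned by hand from compound name + CAS registry number.
#  - CAS 207122-16-5 (heptabromodiphenyl ether) is a congener-ambiguous entry;
#    the BDE-183 congener (2,2',3,4,4',5',6-heptabromodiphenyl ether) is used.
#  - CAS 26444-49-5 (cresyl diphenyl phosphate) is an isomer mixture; the
#    para-cresyl isomer is used.
index,cas,name,smiles,ead_pe,ead_pom,ead_pva
1,100-25-4,"1,4-dinitrobenzene",O=[N+]([O-])c1ccc(cc1)[N+](=O)[O-],-9.3,-2.76,-6.92
2,100-41-4,"ethylbenzene",CCc1ccccc1,-9.57,-6.83,-5.29
3,100-47-0,"benzonitrile",N#Cc1ccccc1,-7.89,-8.21,-3.47
4,100-51-6,"benzyl alcohol",OCc1ccccc1,-8.68,-7.99,-9.6
5,103-65-1,"n-propylbenzene",CCCc1ccccc1,-9.53,-7.51,-7.3
6,106-42-3,"p-xylene",Cc1ccc(C)cc1,-8.07,-6.14,-7.21
7,108-39-4,"m-cresol",Cc1cccc(O)c1,-10.15,-7.18,-6.54
8,108-68-9,"3,5-dimethylphenol",Cc1cc(C)cc(O)c1,-11.22,-7.19,-6.22
9,108-87-2,"methylcyclohexane",CC1CCCCC1,-8.46,-7.03,-7.1
10,108-88-3,"toluene",Cc1ccccc1,-9.58,-6.36,-3.24
11,108-95-2,"phenol",Oc1ccccc1,-8.02,-8.03,-6.48
12,110-82-7,"cyclohexane",C1CCCCC1,-7.55,-6.48,-5.89
13,118-79-6,"2,4,6-tribromophenol",Oc1c(Br)cc(Br)cc1Br,-54.13,-40.87,-52.16
14,120-12-7,"anthracene",c1ccc2cc3ccccc3cc2c1,-15.35,-7.07,-8.58
15,121-14-2,"2,4-dinitrotoluene",Cc1ccc([N+](=O)[O-])cc1[N+](=O)[O-],-11.55,-3.92,-8.05
16,122-79-2,"phenyl acetate",CC(=O)Oc1ccccc1,-9.59,-5.95,-5.82
17,123-07-9,"4-ethylphenol",CCc1ccc(O)cc1,-9.49,-9.22,-5.94
18,126-71-6,"triisobutyl phosphate",O=P(OCC(C)C)(OCC(C)C)OCC(C)C,-50.56,-40.86,-47.17
19,129-00-0,"pyrene",c1cc2ccc3cccc4ccc(c1)c2c34,-16.38,-9.82,-8.83
20,141-82-2,"malonic acid",OC(=O)CC(=O)O,-5.06,-7.79,-12.62
21,207122-16-5,"heptabromodiphenyl ether",O(c1c(Br)c(Br)c(Br)cc1Br)c1c(Br)cc(Br)c(Br)c1,-59.28,-44.49,-57.25
22,26444-49-5,"cresyl diphenyl phosphate",Cc1ccc(OP(=O)(Oc2ccccc2)Oc2ccccc2)cc1,-53.34,-41.23,-47.77
23,3322-93-8,"1,2-dibromo-4-(1,2-dibromoethyl)-cyclohexane",BrCC(Br)C1CCC(Br)C(Br)C1,-54.22,-42.69,-54.47
24,371-41-5,"4-fluorophenol",Oc1ccc(F)cc1,-7.82,-6.61,-6.81
25,41318-75-6,"2,4,4'-tribromodiphenyl ether",O(c1ccc(Br)cc1Br)c1ccc(Br)cc1,-54.36,-38.64,-47.54
26,50-00-0,"formaldehyde",C=O,-3.65,-3.63,-1.32
27,512-56-1,"trimethyl phosphate",COP(=O)(OC)OC,-49.29,-38.74,-46.15
28,513-02-0,"triisopropyl phosphate",CC(C)OP(=O)(OC(C)C)OC(C)C,-53.86,-38.07,-48.23
29,528-29-0,"1,2-dinitrobenzene",O=[N+]([O-])c1ccccc1[N+](=O)[O-],-8.61,-4.92,-3.46
30,585-71-7,"(1-bromoethyl)benzene",CC(Br)c1ccccc1,-50.45,-39.02,-49.56
31,587-03-1,"3-methylbenzyl alcohol",Cc1cccc(CO)c1,-9.54,-7.8,-13.43
32,60-12-8,"phenethyl alcohol",OCCc1ccccc1,-8.87,-9.39,-5.7
33,62-53-3,"aniline",Nc1ccccc1,-9.41,-9.0,-6.13
34,64-18-6,"formic acid",OC=O,-2.33,-4.97,-7.11
35,67-66-3,"chloroform",ClC(Cl)Cl,-28.06,-23.34,-28.63
36,71-43-2,"benzene",c1ccccc1,-7.68,-4.52,-2.67
37,75-07-0,"acetaldehyde",CC=O,-4.52,-4.52,-0.36
38,78-40-0,"triethyl phosphate",CCOP(=O)(OCC)OCC,-50.09,-40.27,-49.38
39,78-79-5,"isoprene",CC(=C)C=C,-7.86,-6.24,-4.77
40,791-28-6,"triphenyl phosphine oxide",O=P(c1ccccc1)(c1ccccc1)c1ccccc1,-51.38,-40.22,-49.18
41,813-78-5,"dimethyl phosphate",COP(=O)(O)OC,-50.17,-44.24,-52.52
42,85-01-8,"phenanthrene",c1ccc2c(c1)ccc1ccccc21,-13.3,-7.38,-8.47
43,86-73-7,"fluorene",C1c2ccccc2-c2ccccc21,-13.17,-10.25,-8.32
44,87-82-1,"hexabromobenzene",Brc1c(Br)c(Br)c(Br)c(Br)c1Br,-58.6,-41.97,-55.55
45,90-12-0,"1-methylnaphthalene",Cc1cccc2ccccc12,-12.52,-8.68,-6.24
46,91-20-3,"naphthalene",c1ccc2ccccc2c1,-9.2,-5.16,-6.09
47,923-99-9,"tripropyl phosphite",CCCOP(OCCC)OCCC,-53.68,-40.51,-48.42
48,92-52-4,"biphenyl",c1ccc(-c2ccccc2)cc1,-11.84,-7.04,-7.73
49,93-58-3,"methyl benzoate",COC(=O)c1ccccc1,-11.83,-7.16,-5.17
50,93-89-0,"ethyl benzoate",CCOC(=O)c1ccccc1,-13.14,-7.41,-9.58
51,98-86-2,"acetophenone",CC(=O)c1ccccc1,-11.95,-9.06,-4.1
52,98-95-3,"nitrobenzene",O=[N+]([O-])c1ccccc1,-9.41,-2.37,-2.62
53,99-65-0,"1,3-dinitrobenzene",O=[N+]([O-])c1cccc(c1)[N+](=O)[O-],-10.82,-4.39,-1.98
54,99-99-0,"4-nitrotoluene",Cc1ccc(cc1)[N+](=O)[O-],-10.29,-2.31,-3.56
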