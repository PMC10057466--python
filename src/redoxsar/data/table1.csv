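index,name,abbr,cas,smiles,split,K,tK
1,Alachlor,ALC,15972-60-8,CCc1cccc(CC)c1N(COC)C(=O)CCl,train,2.722,0.518
2,o-Aminobenzoic acid,o-aminoBenzAc,118-92-3,Nc1ccccc1C(=O)O,train,0.079,0.963
3,Amoxicillin,AMX,26787-78-0,CC1(C)S[C@@H]2[C@H](NC(=O)[C@@H](N)c3ccc(O)cc3)C(=O)N2[C@H]1C(=O)O,test,0.095,0.956
4,Atrazine,AZN,1912-24-9,CCNc1nc(Cl)nc(NC(C)C)n1,train,4.017,0.446
5,Benzoic acid,BenzAc,65-85-0,OC(=O)c1ccccc1,train,0.374,0.853
6,Bisphenol A,BPA,80-05-7,CC(C)(c1ccc(O)cc1)c1ccc(O)cc1,train,1.580,0.623
7,Ciprofloxacin,CIP,85721-33-1,OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O,test,0.852,0.735
8,Desloratadine,DSL,100643-71-8,Clc1ccc2c(c1)CCc1cccnc1C2=C1CCNCC1,train,1.442,0.640
9,Desvenlafaxine,DVF,93413-62-8,CN(C)CC(c1ccc(O)cc1)C1(O)CCCCC1,train,0.445,0.832
10,"2,4-Dichlorophenol",DCP,120-83-2,Oc1ccc(Cl)cc1Cl,train,3.358,0.479
11,Diclofenac,DCF,15307-79-6,OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl,train,0.457,0.829
12,"1,4-Dimethoxybenzene","1,4-DMB",150-78-7,COc1ccc(OC)cc1,test,0.400,0.845
13,"2,6-Dimethoxyphenol","2,6-DMP",91-10-1,COc1cccc(OC)c1O,train,0.053,0.974
14,Diuron,DIU,330-54-1,CN(C)C(=O)Nc1ccc(Cl)c(Cl)c1,train,8.358,0.327
15,Donepezil,DPH,120011-70-3,COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2,train,1.404,0.645
16,17a-Ethynylestradiol,EE2,57-63-6,C#C[C@]1(O)CC[C@H]2[C@@H]3CCc4cc(O)ccc4[C@H]3CC[C@@]21C,train,1.833,0.594
17,Etodolac,ETD,41340-25-4,CCc1cccc2c1[nH]c1c2CCOC1(CC)CC(=O)O,train,0.067,0.968
18,Hydrochlorothiazide,HCTZ,58-93-5,NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O,train,1.940,0.583
19,Ibuprofene,IBP,15687-27-1,CC(C)Cc1ccc(cc1)C(C)C(=O)O,train,0.402,0.844
20,p-Methoxyphenol,p-MP,150-76-5,COc1ccc(O)cc1,test,0.305,0.875
21,m-Nitrophenol,m-NP,554-84-7,Oc1cccc(c1)[N+](=O)[O-],train,1.965,0.581
22,p-Nitrophenol,p-NP,100-02-7,Oc1ccc(cc1)[N+](=O)[O-],train,1.437,0.641
23,Omeprazole,OMP,73590-58-6,COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1,train,0.302,0.876
24,Oxytetracycline,OXY,79-57-2,C[C@]1([C@H]2[C@@H]([C@@H]3[C@@H](C(=O)C(=C([C@]3(C(=O)C2=C(C4=C1C=CC=C4O)O)O)O)C(=O)N)N(C)C)O)O,train,1.916,0.586
25,Phenol,Ph,108-95-2,Oc1ccccc1,train,3.069,0.496
26,Salicylic acid,SalAc,69-72-7,OC(=O)c1ccccc1O,train,0.455,0.829
27,Simazine,SZM,122-34-9,CCNc1nc(Cl)nc(NCC)n1,test,2.171,0.562
28,Sulfanilic acid,SA,121-57-3,Nc1ccc(cc1)S(O)(=O)=O,train,0.682,0.771
29,Tobramycin,TB,32986-56-4,C1[C@H]([C@@H]([C@H]([C@@H]([C@H]1N)O[C@@H]2[C@@H]([C@H]([C@@H]([C@H](O2)CO)O)N)O)O)O[C@@H]3[C@@H](C[C@@H]([C@H](O3)CN)O)N)N,train,2.614,0.526
30,Vilazodone,VZD,163521-08-2,O=C(N)c1cc2cc(ccc2o1)N1CCN(CCCCc2c[nH]c3ccc(C#N)cc23)CC1,train,1.084,0.693
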