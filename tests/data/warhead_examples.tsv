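warhead_id	example_smiles
acrylamide	C=CC(=O)Nc1ccccc1
crotonamide	C/C=C/C(=O)Nc1ccccc1
methacrylamide	C=C(C)C(=O)Nc1ccccc1
cyanoacrylamide	C=C(C#N)C(=O)Nc1ccccc1
acrylate_ester	C=CC(=O)OCC
vinyl_ketone	C=CC(=O)c1ccccc1
acrylonitrile	C=CC#N
vinyl_sulfone	C=CS(=O)(=O)c1ccccc1
vinyl_sulfonamide	C=CS(=O)(=O)N(C)C
vinyl_sulfonate_ester	C=CS(=O)(=O)OC
vinyl_phosphonate	C=CP(=O)(OC)OC
nitroalkene	O=[N+]([O-])/C=C/c1ccccc1
maleimide	O=C1C=CC(=O)N1C
quinone	O=C1C=CC(=O)C=C1
vinyl_azine	C=Cc1ccccn1
enal	C=CC=O
fumarate_diester	COC(=O)/C=C/C(=O)OC
propiolamide	C#CC(=O)Nc1ccccc1
propiolate_ester	C#CC(=O)OC
ynone	C#CC(=O)c1ccccc1
alkynyl_sulfone	C#CS(=O)(=O)c1ccccc1
chloroacetamide	ClCC(=O)Nc1ccccc1
bromoacetamide	BrCC(=O)Nc1ccccc1
iodoacetamide	ICC(=O)Nc1ccccc1
fluoroacetamide	FCC(=O)Nc1ccccc1
chloromethyl_ketone	ClCC(=O)c1ccccc1
bromomethyl_ketone	BrCC(=O)c1ccccc1
fluoromethyl_ketone	FCC(=O)c1ccccc1
acyloxymethyl_ketone	CC(=O)COC(=O)c1ccccc1
diazomethyl_ketone	CC(=O)C=[N+]=[N-]
alpha_halo_ester	ClCC(=O)OCC
alpha_halo_nitrile	ClCC#N
benzyl_halide	ClCc1ccccc1
alkyl_sulfonate_ester	COS(C)(=O)=O
epoxide	CC1CO1
aziridine	CC1CN1
epoxyketone	CC(=O)C1(C)CO1
aziridine_amide	CC(=O)N1CC1
beta_lactam	O=C1CCN1c1ccccc1
beta_lactone	O=C1CCO1
aldehyde	O=Cc1ccccc1
trifluoromethyl_ketone	FC(F)(F)C(=O)c1ccccc1
alpha_ketoamide	CC(=O)C(=O)NC
alpha_ketoester	CC(=O)C(=O)OC
cyanamide	N#CN1CCCC1
azine_nitrile	N#Cc1ncccn1
boronic_acid	OB(O)c1ccccc1
boronate_ester	COB(OC)c1ccccc1
benzoxaborole	OB1OCc2ccccc21
sulfonyl_fluoride	CS(=O)(=O)F
fluorosulfate	O=S(=O)(F)Oc1ccccc1
sulfamoyl_fluoride	CN(C)S(F)(=O)=O
isocyanate	O=C=Nc1ccccc1
isothiocyanate	S=C=Nc1ccccc1
aryl_ester	CC(=O)Oc1ccccc1
thioester	CC(=O)SCC
carbamate	CN(C)C(=O)Oc1ccccc1
carbonate	COC(=O)Oc1ccccc1
anhydride	CC(=O)OC(C)=O
phosphonate_ester	COP(=O)(OC)OC
phosphonofluoridate	CCOP(C)(=O)F
halo_azine	Clc1ccccn1
halo_triazine	Clc1nc(N)nc(N)n1
halo_benzazole	Clc1nc2ccccc2s1
halo_quinazoline	Clc1ncnc2ccccc12
nitroaryl_halide	Fc1ccccc1[N+](=O)[O-]
disulfide	CSSC
methanethiosulfonate	CS(=O)(=O)SC
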