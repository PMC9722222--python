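warhead_id	name	smarts	residues	reaction_ids	parent_id
acrylamide	acrylamide	[CX3;H2]=[CX3;H1][CX3](=[OX1])[NX3]	Cys	acrylamide__Cys	
crotonamide	beta-substituted acrylamide	[CX3;H1]([CX4])=[CX3;H1][CX3](=[OX1])[NX3]	Cys	crotonamide__Cys	
methacrylamide	alpha-methyl acrylamide	[CX3;H2]=[CX3]([CX4])[CX3](=[OX1])[NX3]	Cys	methacrylamide__Cys	
cyanoacrylamide	2-cyanoacrylamide	[CX3;H2]=[CX3]([CX2]#[NX1])[CX3](=[OX1])[NX3]	Cys	cyanoacrylamide__Cys	
acrylate_ester	acrylate ester	[CX3;H2]=[CX3;H1][CX3](=[OX1])[OX2][#6]	Cys	acrylate_ester__Cys	
vinyl_ketone	vinyl ketone	[CX3;H2]=[CX3;H1][CX3](=[OX1])[#6;CX4,c]	Cys	vinyl_ketone__Cys	
acrylonitrile	acrylonitrile	[CX3;H2]=[CX3;H1][CX2]#[NX1]	Cys	acrylonitrile__Cys	
vinyl_sulfone	vinyl sulfone	[CX3;H2]=[CX3;H1][SX4](=[OX1])(=[OX1])[#6]	Cys;Lys	vinyl_sulfone__Cys;vinyl_sulfone__Lys	
vinyl_sulfonamide	vinyl sulfonamide	[CX3;H2]=[CX3;H1][SX4](=[OX1])(=[OX1])[NX3]	Cys;Lys	vinyl_sulfonamide__Cys;vinyl_sulfonamide__Lys	
vinyl_sulfonate_ester	vinyl sulfonate ester	[CX3;H2]=[CX3;H1][SX4](=[OX1])(=[OX1])[OX2][#6]	Cys	vinyl_sulfonate_ester__Cys	
vinyl_phosphonate	vinyl phosphonate	[CX3;H2]=[CX3;H1][PX4](=[OX1])([OX2])[OX2]	Cys	vinyl_phosphonate__Cys	
nitroalkene	nitroalkene	[CX3;H1]=[CX3;H1][NX3+](=[OX1])[OX1-]	Cys	nitroalkene__Cys	
maleimide	maleimide	[CX3;H1]1=[CX3;H1][CX3](=[OX1])[NX3][CX3]1=[OX1]	Cys	maleimide__Cys	
quinone	1,4-quinone	[OX1]=[CX3]1[CX3;H1]=[CX3;H1][CX3](=[OX1])[CX3]=[CX3]1	Cys	quinone__Cys	
vinyl_azine	2-vinyl azine	[CX3;H2]=[CX3;H1][c]1[n][c][c][c][c]1	Cys	vinyl_azine__Cys	
enal	alpha,beta-unsaturated aldehyde	[CX3;H2]=[CX3;H1][CX3;H1]=[OX1]	Cys	enal__Cys	aldehyde
fumarate_diester	fumarate/maleate diester	[#6][OX2][CX3](=[OX1])[CX3;H1]=[CX3;H1][CX3](=[OX1])[OX2][#6]	Cys	fumarate_diester__Cys	acrylate_ester
propiolamide	propiolamide	[CX2;H1]#[CX2][CX3](=[OX1])[NX3]	Cys;Lys	propiolamide__Cys;propiolamide__Lys	
propiolate_ester	propiolate ester	[CX2;H1]#[CX2][CX3](=[OX1])[OX2][#6]	Cys	propiolate_ester__Cys	
ynone	alkynyl ketone	[CX2;H1]#[CX2][CX3](=[OX1])[#6;CX4,c]	Cys	ynone__Cys	
alkynyl_sulfone	alkynyl sulfone	[CX2;H1]#[CX2][SX4](=[OX1])(=[OX1])[#6]	Cys	alkynyl_sulfone__Cys	
chloroacetamide	chloroacetamide	[Cl][CX4;H2][CX3](=[OX1])[NX3]	Cys	chloroacetamide__Cys	
bromoacetamide	bromoacetamide	[Br][CX4;H2][CX3](=[OX1])[NX3]	Cys	bromoacetamide__Cys	
iodoacetamide	iodoacetamide	[I][CX4;H2][CX3](=[OX1])[NX3]	Cys	iodoacetamide__Cys	
fluoroacetamide	fluoroacetamide	[F][CX4;H2][CX3](=[OX1])[NX3]	Cys	fluoroacetamide__Cys	
chloromethyl_ketone	chloromethyl ketone	[Cl][CX4;H2][CX3](=[OX1])[#6;CX4,c]	Cys;Ser	chloromethyl_ketone__Cys;chloromethyl_ketone__Ser	
bromomethyl_ketone	bromomethyl ketone	[Br][CX4;H2][CX3](=[OX1])[#6;CX4,c]	Cys	bromomethyl_ketone__Cys	
fluoromethyl_ketone	fluoromethyl ketone	[F][CX4;H2][CX3](=[OX1])[#6;CX4,c]	Cys	fluoromethyl_ketone__Cys	
acyloxymethyl_ketone	acyloxymethyl ketone	[CX3](=[OX1])[CX4;H2][OX2][CX3](=[OX1])[#6]	Cys	acyloxymethyl_ketone__Cys	
diazomethyl_ketone	diazomethyl ketone	[CX3](=[OX1])[CX3;H1]=[NX2+]=[NX1-]	Cys	diazomethyl_ketone__Cys	
alpha_halo_ester	alpha-halo ester	[Cl,Br][CX4;H2][CX3](=[OX1])[OX2][#6]	Cys	alpha_halo_ester__Cys	
alpha_halo_nitrile	alpha-halo nitrile	[Cl,Br][CX4;H2][CX2]#[NX1]	Cys	alpha_halo_nitrile__Cys	
benzyl_halide	benzylic halide	[Cl,Br][CX4;H2][c]	Cys	benzyl_halide__Cys	
alkyl_sulfonate_ester	methyl sulfonate ester	[CX4;H3][OX2][SX4](=[OX1])(=[OX1])[CX4,c]	Cys	alkyl_sulfonate_ester__Cys	
epoxide	epoxide	[CX4]1[OX2][CX4]1	Cys;Asp;Glu	epoxide__Cys;epoxide__Asp;epoxide__Glu	
aziridine	aziridine	[CX4]1[NX3][CX4]1	Cys;Asp;Glu	aziridine__Cys;aziridine__Asp;aziridine__Glu	
epoxyketone	alpha,beta-epoxyketone	[CX3](=[OX1])[CX4]1[OX2][CX4;H2]1	Thr;Cys	epoxyketone__Thr;epoxyketone__Cys	epoxide
aziridine_amide	N-acyl aziridine	[CX3](=[OX1])[NX3]1[CX4][CX4]1	Cys	aziridine_amide__Cys	aziridine
beta_lactam	beta-lactam	[CX3]1(=[OX1])[CX4][CX4][NX3]1	Ser	beta_lactam__Ser	
beta_lactone	beta-lactone	[CX3]1(=[OX1])[CX4][CX4][OX2]1	Ser;Thr	beta_lactone__Ser;beta_lactone__Thr	
aldehyde	aldehyde	[CX3;H1](=[OX1])[#6]	Cys;Ser;Lys	aldehyde__Cys;aldehyde__Ser;aldehyde__Lys	
trifluoromethyl_ketone	trifluoromethyl ketone	[F][CX4]([F])([F])[CX3](=[OX1])[#6]	Ser;Cys	trifluoromethyl_ketone__Ser;trifluoromethyl_ketone__Cys	
alpha_ketoamide	alpha-ketoamide	[#6][CX3](=[OX1])[CX3](=[OX1])[NX3]	Ser;Cys	alpha_ketoamide__Ser;alpha_ketoamide__Cys	
alpha_ketoester	alpha-ketoester	[#6][CX3](=[OX1])[CX3](=[OX1])[OX2][#6]	Ser;Cys	alpha_ketoester__Ser;alpha_ketoester__Cys	
cyanamide	cyanamide	[NX3][CX2]#[NX1]	Cys	cyanamide__Cys	
azine_nitrile	2-cyanoazine	[NX1]#[CX2][c]1[n][c][c][c][n]1	Cys	azine_nitrile__Cys	
boronic_acid	boronic acid	[BX3]([OX2H])[OX2H]	Ser;Thr	boronic_acid__Ser;boronic_acid__Thr	
boronate_ester	boronate ester	[BX3]([OX2][#6])[OX2][#6]	Ser;Thr	boronate_ester__Ser;boronate_ester__Thr	
benzoxaborole	benzoxaborole	[BX3]1[OX2][CX4][c]2[c][c][c][c][c]12	Ser	benzoxaborole__Ser	boronic_acid
sulfonyl_fluoride	sulfonyl fluoride	[#6][SX4](=[OX1])(=[OX1])[F]	Ser;Tyr;Lys	sulfonyl_fluoride__Ser;sulfonyl_fluoride__Tyr;sulfonyl_fluoride__Lys	
fluorosulfate	fluorosulfate	[OX2][SX4](=[OX1])(=[OX1])[F]	Tyr;Lys	fluorosulfate__Tyr;fluorosulfate__Lys	
sulfamoyl_fluoride	sulfamoyl fluoride	[NX3][SX4](=[OX1])(=[OX1])[F]	Lys;Tyr	sulfamoyl_fluoride__Lys;sulfamoyl_fluoride__Tyr	
isocyanate	isocyanate	[NX2]=[CX2]=[OX1]	Lys;Ser	isocyanate__Lys;isocyanate__Ser	
isothiocyanate	isothiocyanate	[NX2]=[CX2]=[SX1]	Cys;Lys	isothiocyanate__Cys;isothiocyanate__Lys	
aryl_ester	aryl ester	[#6][CX3](=[OX1])[OX2][c]	Ser;Lys	aryl_ester__Ser;aryl_ester__Lys	
thioester	thioester	[#6][CX3](=[OX1])[SX2][#6]	Cys;Lys	thioester__Cys;thioester__Lys	
carbamate	carbamate	[NX3][CX3](=[OX1])[OX2][#6]	Ser	carbamate__Ser	aryl_ester
carbonate	carbonate ester	[#6][OX2][CX3](=[OX1])[OX2][#6]	Ser	carbonate__Ser	aryl_ester
anhydride	carboxylic anhydride	[CX3](=[OX1])[OX2][CX3](=[OX1])	Ser;Lys	anhydride__Ser;anhydride__Lys	
phosphonate_ester	phosph(on)ate triester	[PX4](=[OX1])([OX2][#6])([OX2][#6])[OX2,CX4]	Ser	phosphonate_ester__Ser	
phosphonofluoridate	phosphonyl fluoride	[PX4](=[OX1])([F])([#6,OX2])[#6,OX2]	Ser	phosphonofluoridate__Ser	
halo_azine	2-halo azine	[Cl,F][c]1[n][c][c][c][c]1	Cys;Lys	halo_azine__Cys;halo_azine__Lys	
halo_triazine	halo triazine	[Cl,F][c]1[n][c]([NX3])[n][c]([NX3])[n]1	Cys;Lys	halo_triazine__Cys;halo_triazine__Lys	
halo_benzazole	2-halo benzazole	[Cl][c]1[n][c]2[c][c][c][c][c]2[s,o]1	Cys	halo_benzazole__Cys	
halo_quinazoline	4-halo quinazoline	[Cl,F][c]1[n][c][n][c]2[c][c][c][c][c]12	Cys;Lys	halo_quinazoline__Cys;halo_quinazoline__Lys	
nitroaryl_halide	ortho-nitroaryl halide	[F,Cl][c]1[c]([NX3+](=[OX1])[OX1-])[c][c][c][c]1	Cys;Lys	nitroaryl_halide__Cys;nitroaryl_halide__Lys	
disulfide	disulfide	[#6][SX2][SX2][#6]	Cys	disulfide__Cys	
methanethiosulfonate	thiosulfonate	[#6][SX4](=[OX1])(=[OX1])[SX2][#6]	Cys	methanethiosulfonate__Cys	
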