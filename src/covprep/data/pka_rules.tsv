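rule_id	name	smarts	site	kind	pka
carboxylic_acid	carboxylic acid	[CX3](=[OX1])[OX2;H1]	2	acid	4.5
sulfonic_acid	sulfonic acid	[SX4](=[OX1])(=[OX1])[OX2;H1]	3	acid	-1.0
phosphorus_oh	phosphate/phosphonate O-H	[PX4](=[OX1])[OX2;H1]	2	acid	2.0
tetrazole	tetrazole N-H	[nX3;H1]1[nX2][nX2][nX2][cX3]1	0	acid	4.9
thiol	aliphatic thiol	[SX2;H1][CX4]	0	acid	8.3
phenol	phenol	[cX3][OX2;H1]	1	acid	10.0
aliphatic_amine	aliphatic amine	[NX3;+0;!r3;$([NX3][CX4]);!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][a]);!$([NX3][SX4]);!$([NX3][PX4]);!$([NX3][NX2]);!$([NX3][OX2])]	0	base	10.6
amidine_guanidine	amidine / guanidine	[NX2;H1,H0;+0]=[CX3][NX3]	0	base	12.5
aromatic_amine	aromatic amine	[NX3;H2,H1;+0;$([NX3][a])]	0	base	4.6
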