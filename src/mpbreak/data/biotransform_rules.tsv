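rule_id	smarts	description
bt0001	[CX4;H2,H3][OX2H]	primary aliphatic alcohol (oxidation to aldehyde/acid)
bt0002	[CX4;H1]([#6])([#6])[OX2H]	secondary aliphatic alcohol (oxidation to ketone)
bt0003	c[OX2H]	phenolic hydroxyl (ring cleavage precursor, conjugation)
bt0004	[CX3](=O)[OX2H1]	carboxylic acid (CoA activation, beta-oxidation entry)
bt0005	[CX3](=O)[OX2][#6]	carboxylic acid ester (hydrolysis)
bt0006	[C;R](=O)[O;R]	lactone (ring-opening hydrolysis)
bt0007	[CX3](=O)[NX3]	amide (hydrolysis)
bt0008	[C;R](=O)[N;R]	lactam (ring-opening hydrolysis)
bt0009	[NX3][CX3](=O)[OX2][#6]	carbamate (hydrolysis)
bt0010	[NX3][CX3](=O)[NX3]	urea derivative (hydrolysis)
bt0011	[CX2]#[NX1]	nitrile (hydration to amide)
bt0012	[CX3H1]=O	aldehyde (oxidation to acid)
bt0013	[#6][CX3](=O)[#6]	ketone (reduction, Baeyer-Villiger oxidation)
bt0014	[CX4][OX2][CX4]	dialkyl ether (O-dealkylation)
bt0015	c[OX2][CH3]	aryl methyl ether (O-demethylation)
bt0016	c[OX2][CX4]	aryl alkyl ether (O-dealkylation)
bt0017	[CX4][NX3;H2]	primary aliphatic amine (oxidative deamination)
bt0018	[CX4][NX3;H1][CX4]	secondary aliphatic amine (N-dealkylation)
bt0019	[CX4][NX3]([CX4])[CX4]	tertiary aliphatic amine (N-dealkylation, N-oxidation)
bt0020	c[NX3;H2]	aromatic primary amine (acetylation, ring oxidation)
bt0021	c[NX3;H1][#6]	aromatic secondary amine (N-dealkylation)
bt0022	[NX3](~[OX1])~[OX1]	nitro group (reduction to amine)
bt0023	[NX2]=[NX2]	azo group (reductive cleavage)
bt0024	[NX3][NX3]	hydrazine/hydrazide (oxidative cleavage)
bt0025	[CX3]=[NX2][OX2H]	oxime (hydrolysis)
bt0026	[CX3]=[NX2]	imine/Schiff base (hydrolysis)
bt0027	[NX3][CX3](=[NX2])[NX3]	guanidine (hydrolytic degradation)
bt0028	c1ccccc1	benzene ring (dioxygenation, ring cleavage)
bt0029	c1ccc2ccccc2c1	fused bicyclic aromatic (dioxygenation)
bt0030	[cX3][CH3]	aromatic methyl (benzylic oxidation)
bt0031	c[CH2][#6]	benzylic methylene (benzylic oxidation)
bt0032	[n;R1]1cccc1	azole-type aromatic nitrogen heterocycle
bt0033	n1ccccc1	pyridine-type ring (ring hydroxylation)
bt0034	[CX4H3][CX4H2][CX4H2]	terminal propyl chain (omega/beta-oxidation)
bt0035	[CX4H2][CX4H2][CX4H2][CX4H2]	aliphatic chain of four methylenes (beta-oxidation)
bt0036	[CX3H2]=[CX3]	terminal alkene (hydration, epoxidation)
bt0037	[CX3]=[CX3]	internal alkene (hydration, epoxidation)
bt0038	[CX2]#[CX2]	alkyne (hydration)
bt0039	C1OC1	epoxide (hydrolysis to diol)
bt0040	[CX4;!$(C(F)(F)F)][F,Cl,Br,I]	alkyl halide (hydrolytic/reductive dehalogenation)
bt0041	c[F,Cl,Br,I]	aryl halide (oxidative/reductive dehalogenation)
bt0042	[CX3]=[CX3][F,Cl,Br,I]	vinyl halide (reductive dehalogenation)
bt0043	C(F)(F)F	trifluoromethyl (recalcitrance marker, defluorination)
bt0044	[SX2H]	thiol (oxidation to disulfide/sulfonate)
bt0045	[#6][SX2][#6]	thioether (S-oxidation)
bt0046	[#16X4](=[OX1])(=[OX1])[NX3]	sulfonamide (hydrolysis)
bt0047	[#16X4](=[OX1])(=[OX1])([#6])[OX1,OX2H]	sulfonate (desulfonation)
bt0048	[#6][OX2][#16X4](=[OX1])(=[OX1])[OX1,OX2H]	sulfate ester (hydrolysis)
bt0049	[PX4](=[OX1])([OX2])([OX2])[OX2]	phosphate triester/diester (hydrolysis)
bt0050	[PX4](=[SX1])([OX2])([OX2])[OX2]	phosphorothioate (oxidative desulfuration, hydrolysis)
bt0051	[CX4]([OX2])([OX2])[#6,#1]	acetal/hemiacetal carbon (hydrolysis)
bt0052	[NX4+]	quaternary ammonium (N-dealkylation)
bt0053	[OX2H][CX4][CX4][OX2H]	vicinal diol (oxidative cleavage)
bt0054	[CX3](=O)[CX3](=O)	alpha-dicarbonyl (hydrolytic cleavage)
bt0055	c[NX3](=[OX1])	aromatic N-oxide-like nitrogen (reduction)
bt0056	[OX2H][NX3]	hydroxylamine (reduction)
bt0057	[#6]C(=O)Oc	aryl ester (hydrolysis)
bt0058	[NX3;H2][CX3]=[OX1]	primary amide (hydrolysis to acid)
bt0059	[CX4]([F,Cl,Br,I])([F,Cl,Br,I])	geminal dihalide (hydrolytic dehalogenation)
bt0060	[OX2H][CX4][CX3](=O)[OX2H1]	alpha-hydroxy acid (oxidation)
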