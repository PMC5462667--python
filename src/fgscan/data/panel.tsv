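# Built-in fixture panel: hand-worked molecules covering every marking rule
# (heteroatom, c_multibond_het, c_c_multibond, acetal_c, three_ring) and every
# generalization exception. Columns:
#   name  smiles  cores  generalized  comment
# cores: per expected FG core "n_atoms|rule_tags|n_aliphatic_env|n_aromatic_env",
# cores joined by ';' (order-free, compared as multisets). generalized: the
# canonical pseudo-SMILES forms, ';'-joined. The comment records the hand
# derivation; the frozen strings are the canonical serializations of those
# hand-derived forms.
ethanol	CCO	1|heteroatom|1|0	CO[H]	single O core; aliphatic env C retained with type, O-H kept -> C-O-H
phenol	Oc1ccccc1	1|heteroatom|0|1	cO[H]	single O core; aromatic env c retained, O-H kept -> c-O-H (distinct from alcohol)
anisole	COc1ccccc1	1|heteroatom|1|1	COc	single O core flanked by one aliphatic and one aromatic carbon -> alkyl aryl ether
acetone	CC(C)=O	2|c_multibond_het+heteroatom|2|0	RC(R)=O	carbonyl C marked via C=O; both substituents on the carbonyl kept as R -> ketone
acetaldehyde	CC=O	2|c_multibond_het+heteroatom|1|0	RC=O	one carbonyl substituent -> R, the aldehyde H stays -> distinct from ketone
acetic_acid	CC(=O)O	3|c_multibond_het+heteroatom|1|0	RC(=O)O[H]	carbonyl + hydroxyl O merge; O-H kept by the -OH rule
methyl_acetate	COC(C)=O	3|c_multibond_het+heteroatom|2|0	ROC(R)=O	ester O has only one O/N/S neighbor on its methyl -> no acetal; both env C -> R
dimethoxymethane	COCOC	3|acetal_c+heteroatom|2|0	ROCOR	central sp3 C has two single-bonded O neighbors -> acetal carbon; methyls -> R
n_methylacetamide	CC(=O)NC	3|c_multibond_het+heteroatom|2|0	RC(=O)N(R)R	amide core C,O,N; N-H and both env C fill as R (amide substitution collapses)
urea	NC(N)=O	4|c_multibond_het+heteroatom|0|0	RN(R)C(=O)N(R)R	N,C,O,N core; all four N valences -> R
methylurea	CNC(N)=O	4|c_multibond_het+heteroatom|1|0	RN(R)C(=O)N(R)R	same generalized urea as the parent
trimethylurea	CNC(=O)N(C)C	4|c_multibond_het+heteroatom|3|0	RN(R)C(=O)N(R)R	same generalized urea
phenylurea	NC(=O)Nc1ccccc1	4|c_multibond_het+heteroatom|0|1	RN(R)C(=O)N(R)R	aromatic env on N also collapses to R
tetramethylurea	CN(C)C(=O)N(C)C	4|c_multibond_het+heteroatom|4|0	RN(R)C(=O)N(R)R	fully substituted urea, same generalized form
diphenylurea	O=C(Nc1ccccc1)Nc1ccccc1	4|c_multibond_het+heteroatom|0|2	RN(R)C(=O)N(R)R	two aromatic env carbons, same generalized form
acrylamide	C=CC(N)=O	5|c_c_multibond+c_multibond_het+heteroatom|0|0	RN(R)C(=O)C=C	alkene merges with amide through the shared carbonyl carbon -> C=C-C(=O)-N
methyl_acrylate	C=CC(=O)OC	5|c_c_multibond+c_multibond_het+heteroatom|1|0	ROC(=O)C=C	acrylester C=C-C(=O)-O-C; ester methyl -> R
acylhydrazone	CC(=O)NN=CC	5|c_multibond_het+heteroatom|2|0	RC(=O)N(R)N=C	C-C(=O)-N-N=C; imine env C deleted (non-carbonyl core C), carbonyl env -> R
acylsulfonamide	CC(=O)NS(C)(=O)=O	6|c_multibond_het+heteroatom|2|0	RC(=O)N(R)S(R)(=O)=O	C-C(=O)-N-S(=O)=O; N-H -> R, env C on S -> R
oxirane	C1CO1	3|heteroatom+three_ring|0|0	C1CO1	whole three-membered ring is the group; ring C-H stay implicit
aziridine	C1CN1	3|heteroatom+three_ring|0|0	RN1CC1	ring kept; N-H -> R (multi-atom core, not a simple amine)
thiirane	C1CS1	3|heteroatom+three_ring|0|0	C1CS1	whole ring
methyloxirane	CC1CO1	3|heteroatom+three_ring|1|0	C1CO1	env methyl on a ring carbon deleted -> parent oxirane form
pyrrole	c1cc[nH]c1	1|heteroatom|0|2	n	lone aromatic ring heteroatom -> bare lowercase symbol
n_acetylpyrrole	CC(=O)n1cccc1	3|c_multibond_het+heteroatom|1|2	RC(=O)n(R)R	acyl on aromatic N merges through the non-aromatic N-C bond
pyridine	c1ccncc1	1|heteroatom|0|2	n	lone aromatic heteroatom
pyridazine	c1ccnnc1	1|heteroatom|0|1;1|heteroatom|0|1	n;n	adjacent aromatic N do not merge across the aromatic bond -> two singleton cores
chlorobenzene	Clc1ccccc1	1|heteroatom|0|1	cCl	halogen core with aromatic env carbon retained -> aryl chloride
chloroethane	CCCl	1|heteroatom|1|0	CCl	halogen core with aliphatic env carbon -> alkyl chloride
dimethylamine	CNC	1|heteroatom|2|0	CN(C)[H]	simple amine: N-H kept, both env C retained with type -> secondary amine
trimethylamine	CN(C)C	1|heteroatom|3|0	CN(C)C	tertiary amine, no N-H
aniline	Nc1ccccc1	1|heteroatom|0|1	cN([H])[H]	primary aromatic amine: aromatic env c retained, both H kept
thiophenol	Sc1ccccc1	1|heteroatom|0|1	cS[H]	thiol S-H kept; aromatic env c retained
dimethyl_sulfide	CSC	1|heteroatom|2|0	CSC	sulfide: no S-H; env carbons retained with type
methyl_vinyl_ketone	CC(=O)C=C	4|c_c_multibond+c_multibond_het+heteroatom|1|0	RC(=O)C=C	Michael acceptor: alkene + carbonyl merge -> acryloyl C=C-C(=O)-C
propane	CCC			no heteroatom, no multiple bond, no marked atom -> zero functional groups
benzonitrile	N#Cc1ccccc1	2|c_multibond_het+heteroatom|0|1	C#N	nitrile C marked via C#N; aromatic env deleted (non-carbonyl core C)
trifluorotoluene	FC(F)(F)c1ccccc1	1|heteroatom|1|0;1|heteroatom|1|0;1|heteroatom|1|0	CF;CF;CF	CF3 carbon is unmarked (F is not O/N/S); three alkyl fluoride singletons
nitrobenzene	O=[N+]([O-])c1ccccc1	3|heteroatom|0|1	R[N+](=O)[O-]	internally compensated charges survive standardization; aromatic env -> R
2-butyne	CC#CC	2|c_c_multibond|2|0	C#C	pure C-C triple bond core; methyl envs deleted
methanesulfonamide	CS(N)(=O)=O	4|heteroatom|1|0	RN(R)S(R)(=O)=O	S,O,O,N core; env C on S -> R, N-H -> R
methyl_carbamate	COC(=O)NC	4|c_multibond_het+heteroatom|2|0	ROC(=O)N(R)R	urethane O-C(=O)-N; both env methyls -> R
guanidine	NC(=N)N	4|c_multibond_het+heteroatom|0|0	RN=C(N(R)R)N(R)R	central C marked via C=N; all N valences -> R
ethylene	C=C	2|c_c_multibond|0|0	C=C	plain alkene
diethyl_ether	CCOCC	1|heteroatom|2|0	COC	dialkyl ether: both env C retained with type
diphenyl_ether	c1ccc(Oc2ccccc2)cc1	1|heteroatom|0|2	cOc	diaryl ether
n_methylaniline	CNc1ccccc1	1|heteroatom|1|1	CN(c)[H]	sec. aliphatic/aromatic amine: mixed env types retained, N-H kept
dimethoxypropane	COC(C)(C)OC	3|acetal_c+heteroatom|4|0	ROCOR	ketal: central sp3 C with two single-bonded O -> acetal carbon; gem-dimethyls deleted, O-methyls -> R, same form as the acetal
aminal	CNCNC	3|acetal_c+heteroatom|2|0	RN(R)CN(R)R	aminal: central sp3 C between two single-bonded N -> acetal-type carbon; N-H and N-methyls -> R
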