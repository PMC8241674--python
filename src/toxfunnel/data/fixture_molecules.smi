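# Hand-curated fixture molecules: "SMILES<TAB>id", one per line.
# The first 20 carry hand-counted substructure ground truth
# (see fixture_ground_truth.csv).
c1ccccc1	benzene
c1ccncc1	pyridine
c1cc[nH]c1	pyrrole
c1cnc[nH]1	imidazole
c1cncnc1	pyrimidine
CCN	ethylamine
CCNCC	diethylamine
CCN(CC)CC	triethylamine
NCCN	ethylenediamine
Nc1ccccc1	aniline
CC(N)=O	acetamide
NC(=O)c1ccccc1	benzamide
C1CCNCC1	piperidine
C1COCCN1	morpholine
C1CNCCN1	piperazine
c1ccc2ncccc2c1	quinoline
C=CCN	allylamine
NCc1ccccc1	benzylamine
O=[N+]([O-])c1ccccc1	nitrobenzene
CN1CCC[C@H]1c1cccnc1	nicotine
CCCCCC	hexane
CCO	ethanol
CC(=O)Oc1ccccc1C(=O)O	aspirin
CC(C)Cc1ccc(cc1)C(C)C(=O)O	ibuprofen
CC(=O)Nc1ccc(O)cc1	paracetamol
Cn1cnc2c1c(=O)n(C)c(=O)n2C	caffeine
OC(=O)c1ccccc1O	salicylic_acid
CCOC(=O)c1ccccc1	ethyl_benzoate
CC(C)O	isopropanol
OCC(O)CO	glycerol
C1CCCCC1	cyclohexane
c1ccc2ccccc2c1	naphthalene
Cc1ccccc1	toluene
Oc1ccccc1	phenol
COc1ccccc1	anisole
ClCCl	dichloromethane
FC(F)(F)c1ccccc1	benzotrifluoride
BrCCBr	dibromoethane
CC#N	acetonitrile
CS(C)=O	dmso
O=S(=O)(N)c1ccccc1	benzenesulfonamide
CC(C)(C)c1ccc(O)cc1	tert_butylphenol
OC(=O)CC(O)(CC(=O)O)C(=O)O	citric_acid
OC(=O)C(O)C(O)C(=O)O	tartaric_acid
C(CO)O	ethylene_glycol
CC(=O)C	acetone
CCOCC	diethyl_ether
O=CC=C	acrolein
C1OC1C	propylene_oxide
NN(C)C	dimethylhydrazine
N#Cc1ccccc1	benzonitrile
CCCCN	butylamine
CCCCCN	pentylamine
NC1CCCCC1	cyclohexylamine
CN(C)CCO	dimethylaminoethanol
NCCO	ethanolamine
CNC	dimethylamine
CN(C)C	trimethylamine
NCCCN	propanediamine
C1CCNC1	pyrrolidine
c1ccc(cc1)Cn1ccnc1	benzylimidazole
c1ccc2[nH]ccc2c1	indole
c1cnccn1	pyrazine
c1ccnnc1	pyridazine
Cc1ccncc1	picoline
c1ccc(nc1)c1ccccn1	bipyridine
Nc1ccncc1	aminopyridine
CC(C)NCC(O)COc1ccccc1	propranolol_fragment
CNCC(O)c1ccc(O)c(O)c1	epinephrine
NCCc1ccc(O)c(O)c1	dopamine
NCCc1c[nH]c2ccccc12	tryptamine
CN(C)CCc1c[nH]c2ccccc12	dmt
OCC1OC(O)C(O)C(O)C1O	glucose
CC(N)C(=O)O	alanine
NCC(=O)O	glycine
NC(Cc1ccccc1)C(=O)O	phenylalanine
NC(CS)C(=O)O	cysteine
NC(CCSC)C(=O)O	methionine
OC(=O)CCC(=O)O	succinic_acid
CCCCCCCCCCCCCCCC(=O)O	palmitic_acid
CCCCCCCC=CCCCCCCCC(=O)O	oleic_acid
C1CCOC1	thf
O1CCOCC1	dioxane
CSc1ccccc1	thioanisole
S1C=CC=C1	thiophene
c1ccc2c(c1)oc1ccccc12	dibenzofuran
Clc1ccccc1Cl	dichlorobenzene
Clc1ccc(cc1)C(c1ccc(Cl)cc1)C(Cl)(Cl)Cl	ddt
CC12CCC3c4ccc(O)cc4CCC3C1CCC2O	estradiol
CC(C)=CCCC(C)=CCO	geraniol
CC1=CCC(CC1)C(C)C	terpinene_like
c1ccc(cc1)c1ccccc1	biphenyl
O=C1CCCCC1	cyclohexanone
O=C(O)c1ccc(N)cc1	paba
CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1	atropine
COc1cc2c(cc1OC)CN1CCc3cc(OC)c(OC)cc3C1C2	tetrahydropapaverine_like
CC(=O)OCC(COC(C)=O)OC(C)=O	triacetin
Oc1ccc(cc1)C(=O)OC	methylparaben_iso
CCOC(=O)C1=C(C)NC(C)=C(C1c1ccccc1[N+](=O)[O-])C(=O)OCC	nifedipine_analog
CCCCO	butanol
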