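CCO	ethanol
c1ccccc1	benzene
Oc1ccccc1	phenol
CC(C)(c1ccc(O)cc1)c1ccc(O)cc1	bisphenol_a
C[C@]12CC[C@H]3[C@@H](CCc4cc(O)ccc43)[C@@H]1CC[C@@H]2O	estradiol
CC12CCC3C(CCc4cc(O)ccc43)C1CCC2O	estradiol_stereo_free
CC/C(=C(\CC)c1ccc(O)cc1)c1ccc(O)cc1	diethylstilbestrol
O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12	genistein
CC/C(=C(\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1	tamoxifen
C[C@]12CC[C@H]3[C@@H](CCc4cc(O)ccc43)[C@@H]1CCC2=O	estrone
CCCCCCCCCc1ccc(O)cc1	4-nonylphenol
CC(=O)[O-].[Na+]	sodium_acetate
Cl.NCCc1ccccc1	phenethylamine_hydrochloride
C[N+](C)(C)CCO.[Cl-]	choline_chloride
CCCCCCCCCCCCCCCCCC(=O)[O-].CCCCCCCCCCCCCCCCCC(=O)[O-].[Mg+2]	magnesium_stearate
C/C=C/C=C/C(=O)[O-].[K+]	potassium_sorbate
O=S(=O)(O)O	sulfuric_acid
O	water
[Na+].[Cl-]	sodium_chloride
OB(O)O	boric_acid
CC[Sn](CC)CC	tetraethyltin
C[Al](C)C	trimethylaluminum
CC[Pb](CC)(CC)CC	tetraethyllead
CC(C)C[C@@H]1NC(=O)[C@H](C)N(C)C(=O)[C@H](C(C)C)N(C)C(=O)CN(C)C(=O)[C@@H](CC(C)C)NC(=O)[C@H](C)NC(=O)[C@@H](CC(C)C)N(C)C(=O)[C@H](C(C)C)NC(=O)[C@@H](CC(C)C)N(C)C(=O)CN(C)C(=O)[C@H](C)NC1=O	synthetic_cyclic_peptide_mw_over_1000
C[C@H](O)CC	r_butan-2-ol
C[C@@H](O)CC	s_butan-2-ol
C/C=C/C(=O)O	trans_crotonic_acid
C/C=C\C(=O)O	cis_crotonic_acid
C[N+](=O)[O-]	nitromethane_charge_separated
CN(=O)=O	nitromethane_pentavalent
CC(=O)CC(C)=O	pentane-2,4-dione_keto
CC(O)=CC(C)=O	pentane-2,4-dione_enol
[O-]c1ccccc1	phenolate
C(C(=O)[O-])[NH3+]	glycine_zwitterion
C[N+](C)(C)C	tetramethylammonium
Cn1c(=O)c2c(ncn2C)n(C)c1=O	caffeine
CC(=O)Oc1ccccc1C(=O)O	aspirin
CC(C)Cc1ccc(C(C)C(=O)O)cc1	ibuprofen
CN1CCC[C@H]1c1cccnc1	nicotine
OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O	glucose
CCNc1nc(Cl)nc(NC(C)C)n1	atrazine
Clc1ccc(C(c2ccc(Cl)cc2)C(Cl)(Cl)Cl)cc1	ddt
COc1ccc(C(c2ccc(OC)cc2)C(Cl)(Cl)Cl)cc1	methoxychlor
CCOP(=S)(OCC)Oc1ccc([N+](=O)[O-])cc1	parathion
C[Si](C)(C)O	trimethylsilanol
C[Se]CCC(N)C(=O)O	selenomethionine
OB(O)c1ccccc1	phenylboronic_acid
C=CC1(C)OC(=O)N(c2cc(Cl)cc(Cl)c2)C1=O	vinclozolin
C#CC1(O)CCC2C1(C)CCC1C2CCc2cc(O)ccc21	ethinylestradiol_stereo_free
CC(C)(C)c1ccc(O)cc1	4-tert-butylphenol
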