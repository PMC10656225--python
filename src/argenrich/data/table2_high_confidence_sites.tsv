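protein_names	gene_names	r_positions	r_me_positions	r_me2_positions	peptide	localization_probability	pep	note
26S proteasome non-ATPase regulatory subunit 2	Psmd2	E76			DTSLYRPALE(R)ELR	0.95191	0.00496884	E77 identified in KO
Acidic leucine-rich nuclear phosphoprotein 32 family member B	Anp32b	D119, E124			SLD(R)LFGCE(R)VTNRSDYR	0.99997	0.00584857
Actin, alpha cardiac muscle 1	Actc1		D294		D(R-me)LYANNVLSGGTTMYPGIADR	1	2.79152E-11	Arginylation of D292 of Actb/Actg1 identified in KO
Actin, alpha cardiac muscle 1; actin, alpha skeletal muscle; actin, cytoplasmic 1; actin, cytoplasmic 2	Actc1; Acta1; Actb; Actg1	D58; D58; D56; D56			DSYVGD(R)EAQSK	0.904826	0.000375832
Anthrax toxin receptor 1	Antxr1	D115			VLPGGD(R)TYMHEGFER	0.996989	0.00619278
CAAX prenyl protease 1 homolog	Zmpste24		E311	E307, D309	NEGE(R-me2)GD(R-me2)SE(R-me)EVK	0.890795	0.00069882
Eukaryotic translation initiation factor 3 subunit G	Eif3g	D5, D7, E21, D22			PTGD(R)FD(R)SKPSWADQVEEEGE(R)D(R)DK	0.779874	0.00363262
F-actin-capping protein subunit beta	Capzb	E264			SKQEALKNDLVE(R)ALK	0.999565	0.00581404
Myosin-10	Myh10	E1887			QLE(R)EAEEEATR	0.866771	0.00166674
Myosin-9	Myh9	E1385			KKMEDGVGCLETAEE(R)AK	0.83621	0.00066077
Myotubularin-related protein 5	Sbf1	D1341			PD(R)PLQQWELVPIEVFEAR	0.999425	0.000338381
Neurogenic locus notch homolog protein 1	Notch1	E1655, D1657			RE(R)LD(R)PMDIR	0.998716	0.00855934
Palladin	Palld	D220			LLGAD(R)SANVFNIQEPEETAANQEYK	1	9.39096E-17
Plectin	Plec	D685; D537			ID(R)SAEWGVDLPSVEAQLGSHR	0.974335	0.00000241981
Plectin	Plec	E2069; E1921			QVE(R)EEIMALK	0.811853	0.0080895
Ribosome-binding protein 1	Rrbp1	E1081			ESEE(R)ALQK	0.930368	0.0146506
Unconventional myosin-Ic	Myo1c	E55			VGVQDFVLLE(R)NFTSEAAFIENLR	0.983825	2.0807E-12
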