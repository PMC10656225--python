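protein_names	gene_names	fold_change	p_value
SH3 domain-binding glutamic acid-rich-like protein 3	Sh3bgrl3	2206.8	2.4E-04
Proliferation-associated protein 2G4	Pa2g4	275.7	6.3E-03
Smoothelin	Smtn	99.6	1.1E-03
Sorbin and SH3 domain-containing protein 2	Sorbs2	87.4	1.9E-02
60S ribosomal protein L5	Rpl5	63.7	1.2E-03
Ribosome-binding protein 1	Rrbp1	57.2	4.7E-02
PDZ and LIM domain protein 7	Pdlim7	51.1	5.3E-03
Mitogen-activated protein kinase 1	Mapk1	45.2	9.8E-04
PDZ and LIM domain protein 5	Pdlim5	37.7	9.9E-04
Testin	Tes	35.6	4.1E-03
Glycylpeptide N-tetradecanoyltransferase 1	Nmt1	35.5	5.3E-02
Collagen alpha-2(I) chain	Col1a2	32.6	5.2E-02
Nestin	Nes	30.9	2.7E-03
Procollagen C-endopeptidase enhancer 1	Pcolce	30.2	2.1E-02
ATP-dependent Clp protease ATP-binding subunit clpX-like, mitochondrial	Clpx	27.0	4.1E-03
Peptidyl-prolyl cis-trans isomerase B	Ppib	27.0	2.3E-02
2,4-dienoyl-CoA reductase, mitochondrial	Decr1	26.3	1.8E-02
NADH-cytochrome b5 reductase 3; NADH-cytochrome b5 reductase 3 membrane-bound form; NADH-cytochrome b5 reductase 3 soluble form	Cyb5r3	23.9	6.4E-03
Structural maintenance of chromosomes protein 2	Smc2	22.0	8.0E-03
Tubulin beta-3 chain	Tubb3	21.1	2.3E-03
Prolyl 4-hydroxylase subunit alpha-1	P4ha1	18.3	3.4E-03
Dedicator of cytokinesis protein 7	Dock7	17.1	5.0E-02
Filamin A-interacting protein 1-like	Filip1l	16.3	1.4E-02
Transcription factor BTF3	Btf3	15.5	3.3E-02
Pleckstrin homology-like domain family B member 1	Phldb1	14.9	2.6E-02
Epiplakin	Eppk1	14.3	3.8E-02
Guanine nucleotide-binding protein G(s) subunit alpha isoforms short; guanine nucleotide-binding protein G(s) subunit alpha isoforms XLas	Gnas	13.9	4.7E-03
Leucine--tRNA ligase, cytoplasmic	Lars	13.7	5.1E-02
Dolichyl-diphosphooligosaccharide--protein glycosyltransferase 48 kDa subunit	Ddost	13.6	4.1E-02
Actin-binding protein anillin	Anln	12.6	1.7E-02
Leucine zipper protein 1	Luzp1	12.1	3.2E-02
Microtubule-associated protein 2	Map2	11.6	1.1E-03
Sulfide:quinone oxidoreductase, mitochondrial	Sqrdl	11.6	4.4E-02
NADH dehydrogenase (ubiquinone) 1 alpha subcomplex subunit 8	Ndufa8	11.5	2.6E-02
Myb-binding protein 1A	Mybbp1a	10.9	1.1E-02
Fibulin-2	Fbln2	10.4	2.0E-02
Annexin A6	Anxa6	10.4	3.0E-02
Leiomodin-1	Lmod1	8.9	6.4E-04
Protein-lysine 6-oxidase	Lox	8.5	1.2E-02
60S ribosomal protein L4	Rpl4	8.4	2.1E-02
ATP-binding cassette subfamily F member 1	Abcf1	7.8	1.9E-02
Collagen alpha-1(I) chain	Col1a1	7.7	2.3E-02
Filamin-C	Flnc	7.5	2.8E-03
Ras GTPase-activating-like protein IQGAP1	Iqgap1	7.3	1.9E-02
Tubulointerstitial nephritis antigen-like	Tinagl1	6.8	5.5E-03
Aspartyl/asparaginyl beta-hydroxylase	Asph	6.6	1.2E-02
Collagen alpha-1(XII) chain	Col12a1	6.0	3.7E-03
Tubulin beta-2B chain	Tubb2b	5.8	4.6E-02
Nascent polypeptide-associated complex subunit alpha, muscle-specific form; nascent polypeptide-associated complex subunit alpha	Naca	5.1	1.0E-03
Paired mesoderm homeobox protein 2; paired mesoderm homeobox protein 1	Prrx2; Prrx1	4.9	1.1E-03
60S ribosomal protein L34	Rpl34	4.5	2.5E-02
Reticulon-4	Rtn4	4.2	5.2E-02
Vigilin	Hdlbp	4.2	4.0E-02
Fibronectin; anastellin	Fn1	4.2	4.9E-04
Ras-related protein Rab-2A; Ras-related protein Rab-2B	Rab2a; Rab2b	4.1	3.8E-02
Protein-glutamine gamma-glutamyltransferase 2	Tgm2	3.9	1.2E-02
40S ribosomal protein S16	Rps16	3.8	1.4E-02
40S ribosomal protein S28	Rps28	3.7	3.0E-02
Thrombospondin-1	Thbs1	3.7	2.9E-02
Tubulin alpha-1A chain; tubulin alpha-3 chain	Tuba1a; Tuba3a	3.6	5.3E-03
40S ribosomal protein S23	Rps23	3.5	3.6E-03
Serine/threonine-protein phosphatase 2A 55 kDa regulatory subunit B alpha isoform; serine/threonine-protein phosphatase 2A 55 kDa regulatory subunit B delta isoform	Ppp2r2a; Ppp2r2d	3.5	1.7E-02
ADP-ribosylation factor-like protein 8A; ADP-ribosylation factor-like protein 8B	Arl8a; Arl8b	3.4	3.5E-02
A-kinase anchor protein 2	Akap2	3.2	2.1E-02
Bystin	Bysl	3.2	4.5E-02
40S ribosomal protein S2	Rps2	3.1	2.7E-03
Developmentally regulated GTP-binding protein 1	Drg1	3.1	1.3E-02
60S ribosomal protein L18a	Rpl18a	2.9	4.4E-02
60S ribosomal protein L13	Rpl13	2.9	1.0E-02
60S ribosomal protein L26	Rpl26	2.9	2.4E-02
Calponin-2	Cnn2	2.8	1.6E-02
GMP synthase (glutamine-hydrolyzing)	Gmps	2.8	1.3E-02
Serine/arginine-rich splicing factor 2	Srsf2	2.7	5.1E-02
RNA-binding protein 3	Rbm3	2.6	2.4E-04
40S ribosomal protein S5; 40S ribosomal protein S5, N-terminally processed	Rps5	2.5	2.3E-02
LIM and SH3 domain protein 1	Lasp1	2.5	1.2E-02
Allograft inflammatory factor 1-like	Aif1l	2.5	8.0E-03
60S ribosomal protein L38	Rpl38	2.5	5.2E-02
Succinyl-CoA ligase (ADP/GDP-forming) subunit alpha, mitochondrial	Suclg1	2.4	3.0E-02
Serine/arginine-rich splicing factor 3	Srsf3	2.4	2.7E-03
60S ribosomal protein L27	Rpl27	2.4	1.6E-02
Alpha-crystallin B chain	Cryab	2.3	2.5E-02
Serine/threonine-protein kinase DCLK1	Dclk1	2.3	2.4E-03
Ubiquitin-associated protein 2-like	Ubap2l	2.2	1.1E-02
40S ribosomal protein S3a	Rps3a	2.2	3.5E-03
40S ribosomal protein S14	Rps14	2.2	2.6E-02
Aminoacyl tRNA synthase complex-interacting multifunctional protein 2	Aimp2	2.2	1.8E-02
60S ribosomal protein L27a	Rpl27a	2.2	5.2E-02
F-actin-capping protein subunit alpha-1	Capza1	2.1	3.0E-02
Heterogeneous nuclear ribonucleoprotein F; heterogeneous nuclear ribonucleoprotein F, N-terminally processed	Hnrnpf	2.1	1.6E-02
Uridine 5-monophosphate synthase; orotate phosphoribosyltransferase; orotidine 5-phosphate decarboxylase	Umps	2.0	4.7E-02
ATP-dependent RNA helicase DDX3X; putative ATP-dependent RNA helicase Pl10	Ddx3x; D1Pas1	2.0	5.2E-02
Protein hook homolog 3	Hook3	2.0	3.8E-02
ATP synthase subunit O, mitochondrial	Atp5o	1.9	2.5E-02
Heterogeneous nuclear ribonucleoprotein U	Hnrnpu	1.9	4.2E-02
Eukaryotic initiation factor 4A-I	Eif4a1	1.9	5.2E-02
Filamin-B	Flnb	1.8	2.4E-02
Heterogeneous nuclear ribonucleoprotein H; heterogeneous nuclear ribonucleoprotein H, N-terminally processed	Hnrnph1	1.7	3.5E-02
Ataxin-2-like protein	Atxn2l	1.7	3.9E-03
Polypyrimidine tract-binding protein 1	Ptbp1	1.7	2.5E-02
40S ribosomal protein S27; 40S ribosomal protein S27-like	Rps27; Rps27l	1.7	4.3E-02
Protein S100-A4	S100a4	1.7	3.1E-02
ELAV-like protein 1	Elavl1	1.6	2.3E-02
Actin, alpha cardiac muscle 1; actin, alpha skeletal muscle	Actc1; Acta1	1.6	4.4E-02
Poly(rC)-binding protein 2	Pcbp2	1.6	4.2E-02
CTP synthase 1	Ctps1	1.6	9.8E-03
60S ribosomal protein L9	Rpl9	1.5	8.0E-03
Nuclease-sensitive element-binding protein 1	Ybx1	1.5	5.0E-02
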