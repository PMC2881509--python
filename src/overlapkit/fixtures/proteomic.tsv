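gene	description	tumor_stroma	recurrence_prone	metastasis_prone	member
Capg	capping protein (actin filament), gelsolin-like	4.18e-38	4.07e-03		0
Sparc	secreted acidic cysteine rich glycoprotein	1.49e-35			0
Arhgdib	Rho, GDP dissociation inhibitor (GDI) beta	3.92e-32			0
Gpd2	glycerol phosphate dehydrogenase 2, mitochondrial	1.39e-29			1
Upp1	uridine phosphorylase 1	2.77e-28			1
Col3a1	collagen, type III, alpha 1	3.30e-27	8.00e-05		0
Col1a2	collagen, type I, alpha 2	1.07e-27			0
Tpm1	tropomyosin 1, alpha	2.20e-26	5.23e-07		0
Sh3bgrl3	SH3 domain binding glutamic acid-rich protein-like 3	4.35e-24			0
Col1a1	collagen, type I, alpha 1	3.20e-17	2.46e-03		0
Eef1d	eukaryotic translation elongation factor 1 delta (guanine nucleotide exchange protein)	2.00e-12			0
Nme2	non-metastatic cells 2, protein (NM23B) expressed in	2.39e-09			0
Sncg	synuclein, gamma (breast cancer-specific protein 1)	8.86e-08			0
Ldhc	lactate dehydrogenase C	1.26e-07	1.78e-03		1
Myl1	myosin, light chain 1, alkali; skeletal, fast	3.60e-07			0
Gsn	gelsolin	6.30e-05			0
Ckm	creatine kinase, muscle	3.88e-05			1
Tpm2	tropomyosin 2, beta	1.38e-03	2.22e-03		0
Cnn2	calponin 2		2.26e-02		0
Fth1	ferritin, heavy polypeptide 1		2.72e-02		0
Pdha1	pyruvate dehydrogenase E1 alpha subunit		2.85e-02		1
Pgk1	phosphoglycerate kinase 1		3.21e-02		1
Eno3	enolase 3, beta muscle			1.29e-03	1
Aldoa	aldolase A, fructose-bisphosphate			1.69e-03	1
Afp	alpha fetoprotein			3.06e-02	0
Pkm2	pyruvate kinase, muscle			3.73e-02	1
Alb	albumin			3.95e-02	0
Pgd	phosphogluconate dehydrogenase			4.19e-02	1
Serpinb2	serine (or cysteine) peptidase inhibitor, clade B, member 2			4.27e-02	0
Eef2	eukaryotic translation elongation factor 2			4.41e-02	0
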