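gene	description	tumor_stroma	recurrence_prone	metastasis_prone	member
Gcm1	glial cells missing homolog 1 (Drosophila)	6.50e-21	8.39e-04		0
Gfap	glial fibrillary acidic protein	1.64e-18	1.36e-03	2.28e-02	1
Gfra2	glial cell line derived neurotrophic factor family receptor alpha 2	2.28e-17	3.58E-02		0
Slc1a3	solute carrier family 1 (glial high affinity glutamate transporter), member 3	4.22e-17	5.70e-03		0
Gfra3	glial cell line derived neurotrophic factor family receptor alpha 3	2.97e-16			0
Gdnf	glial cell line derived neurotrophic factor	6.48e-14			0
Gcm2	glial cells missing homolog 2 (Drosophila)	1.38e-05	2.06e-02		0
Gfra4	glial cell line derived neurotrophic factor receptor alpha 4			1.02e-02	0
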