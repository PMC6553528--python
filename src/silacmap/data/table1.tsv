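uniprot_id	protein_name	gene_name	log2_ap1	log2_ap2	log2_ap3	class_label
P08670	Vimentin	VIM	5.061	2.741	0.107	I
O15231	Zinc finger protein 185	ZNF185	5.600	2.710	1.282	I
A6NMH6	Septin-8	SEPT8	7.346	—	3.568	I
Q15019	Septin-2	SEPT2	2.167	2.595	1.856	I
E7ES33	Septin-7	SEPT7	2.639	4.887	1.778	I
D6RGI3	Septin-11	SEPT11	2.901	3.891	2.060	I
D6RGI3	Aminopeptidase N	ANPEP	3.029	2.185	—	I
Q8WWI1	LIM domain only protein 7	LMO7	—	2.225	3.794	I
E9PDF6	Unconventional myosin-Ib	MYO1B	4.846	2.220	0.623	II
E7EPZ9	Tenascin-X	TNXB	7.652	—	—	II
P17252	Protein kinase C alpha type	PRKCA	3.279	—	—	II
Q9UBI6	Guanine nucleotide-binding protein G(I)/G(S)/G(O) subunit gamma-12	GNG12	3.828	—	—	II
P10301	Ras-related protein R-Ras	RRAS	6.174	—	—	II
Q96FN4	Copine-2	CPNE2	3.924	—	—	II
E9PNW4	CD59 glycoprotein	CD59	5.288	—	0.635	II
Q6YHK3	CD109 antigen	CD109	6.287	—	—	II
Q6XZB0	Lipase member I	LIPI	3.524	—	—	II
P05362	Intercellular adhesion molecule 1	ICAM1	4.501	—	—	II
H3BNE1	Synaptosomal-associated protein 23	SNAP23	4.958	—	—	II
Q86WV6	Stimulator of interferon genes protein	TMEM173	4.491	—	—	II
O43707	Alpha-actinin-4	ACTN4	2.456	2.004	0.377	II
H0Y7A7	Calmodulin	CALM2	2.538	2.054	1.017	II
P08754	Guanine nucleotide-binding protein G(k) subunit alpha	GNAI3	3.005	—	—	II
F8W7R3	Fanconi anemia group I protein	FANCI	3.075	—	—	II
Q15283	Ras GTPase-activating protein 2	RASA2	3.116	—	—	II
Q9Y2F5	Little elongation complex subunit 1	ICE1	—	—	6.978	II
Q15746	Myosin light chain kinase	MYLK	—	4.389	1.663	II
Q9P2N5	RNA-binding protein 27	RBM27	—	6.739	0.250	II
Q9BX40	Protein LSM14 homolog B	LSM14B	—	3.080	1.798	II
Q9BX40	Protein LSM14 homolog A	LSM14A	—	3.078	1.797	II
Q03135	Caveolin-1;Caveolin	CAV1	1.941	3.644	—	II
E9PE29	Zinc finger protein 106	ZNF106	—	3.688	—	II
Q6NYC8	Phostensin	PPP1R18	—	6.145	—	II
Q8IYI6	Exocyst complex component 8	EXOC8	—	—	6.289	II
Q86UE4	Protein LYRIC	MTDH	—	3.969	—	II
P00505	Aspartate aminotransferase, mitochondrial	GOT2	—	—	3.541	II
F5H6E2	Unconventional myosin-Ic	MYO1C	4.519	1.450	0.357	III
F8W6L6	Myosin-10	MYH10	2.339	0.585	0.376	III
Q9UHB6	LIM domain and actin-binding protein 1	LIMA1	2.690	1.281	1.174	III
O14974	Protein phosphatase 1 regulatory subunit 12A	PPP1R12A	2.987	0.130	0.486	III
Q6WCQ1	Myosin phosphatase Rho-interacting protein	MPRIP	3.061	0.159	0.560	III
E7EW20	Unconventional myosin-VI	MYO6	3.767	1.913	—	III
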