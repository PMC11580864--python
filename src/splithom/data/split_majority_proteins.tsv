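# Published survey counts: human proteins with more split than full-length gut microbial homologs.
entry	entry_name	description	n_full	n_split
P54886	P5CS_HUMAN	Delta-1-pyrroline-5-carboxylate synthase	27	293
P22102	PUR2_HUMAN	Trifunctional purine biosynthetic protein adenosine-3	0	200
P22234	PUR6_HUMAN	Bifunctional phosphoribosylaminoimidazole carboxylase/phosphoribosylaminoimidazole succinocarboxamide synthetase	0	145
P27708	PYR1_HUMAN	Multifunctional protein CAD	0	120
Q9NZB8	MOCS1_HUMAN	Molybdenum cofactor biosynthesis protein 1	0	75
P11586	C1TC_HUMAN	C-1-tetrahydrofolate synthase, cytoplasmic	0	64
O14841	OPLA_HUMAN	5-oxoprolinase	7	54
O95479	G6PE_HUMAN	GDH/6PGL endoplasmic bifunctional protein	7	47
Q6UB35	C1TM_HUMAN	Monofunctional C1-tetrahydrofolate synthase, mitochondrial	4	47
Q06278	AOXA_HUMAN	Aldehyde oxidase	3	46
P47989	XDH_HUMAN	Xanthine dehydrogenase/oxidase	0	38
O95340	PAPS2_HUMAN	Bifunctional 3'-phosphoadenosine 5'-phosphosulfate synthase 2	0	28
Q9NQX3	GEPH_HUMAN	Gephyrin	0	27
Q12882	DPYD_HUMAN	Dihydropyrimidine dehydrogenase	24	26
O43252	PAPS1_HUMAN	Bifunctional 3'-phosphoadenosine 5'-phosphosulfate synthase 1	0	24
P11172	UMPS_HUMAN	Uridine 5'-monophosphate synthase	0	22
Q86Z14	KLOTB_HUMAN	Beta-klotho	0	12
Q709F0	ACD11_HUMAN	Acyl-CoA dehydrogenase family member 11	0	11
Q7Z3D6	GLUCM_HUMAN	D-glutamate cyclase, mitochondrial	0	6
Q9H9Y6	RPA2_HUMAN	DNA-directed RNA polymerase I subunit RPA2	2	5
Q9UEF7	KLOT_HUMAN	Klotho	0	5
P51659	DHB4_HUMAN	Peroxisomal multifunctional enzyme type 2	0	1
Q8IYQ7	THNS1_HUMAN	Threonine synthase-like 1	0	1
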