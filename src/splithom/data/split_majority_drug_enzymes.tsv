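# Published survey counts: drug-metabolizing enzymes with more split (partial) than full-length gut microbial homologs, with substrate drugs.
enzyme	description	n_split	n_full	drugs
AOX1	Aldehyde oxidase	46	3	crizotinib, allopurinol, ziprasidone, vortioxetine, aciclovir, pyrazinamide, capmatinib, nicotine iminium ion, thioguanine
XDH	Xanthine dehydrogenase / oxidase	38	0	doxorubicin, 1-methylxanthine, theophylline, allopurinol, pyrazinoic acid, pyrazinamide, mercaptopurine, thioxanthine
DPYD	Dihydropyrimidine dehydrogenase	26	24	fluorouracil
UMPS	Uridine 5'-monophosphate synthase	22	0	fluorouracil
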