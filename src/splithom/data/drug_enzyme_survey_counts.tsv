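# Headline counts of the published drug-metabolizing-enzyme survey.
quantity	count
proteins_screened	154
proteins_with_homolog	126
proteins_full_majority	122
drugs_metabolized_by_full_majority	215
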