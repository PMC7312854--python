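variant_key	source	classification	review_status
BRCA2:c.9155G>A	ARUP	Likely benign	single_submitter
BRCA2:c.8023A>G	ClinVar	Likely pathogenic	multiple_submitters
BRCA2:c.6131G>T	ENIGMA	Benign	expert_panel
BRCA2:c.2350A>G	ENIGMA	Benign	expert_panel
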