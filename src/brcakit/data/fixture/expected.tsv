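variant_key	expected_tier	expected_efficacy	expected_monitor
BRCA1:c.4957G>T	Likely pathogenic	response	false
BRCA1:c.4957G>A	Likely pathogenic	response	false
BRCA1:c.3283A>G	VUS	not_covered	false
BRCA1:c.3707A>G	VUS	not_covered	false
BRCA1:c.4093C>G	VUS	not_covered	false
BRCA2:c.520C>T	VUS	not_covered	false
BRCA2:c.1744A>C	Benign	low_efficacy	true
BRCA2:c.2350A>G	Benign	resistance	false
BRCA2:c.3067_3072del	VUS	not_covered	false
BRCA2:c.5158A>G	VUS	resistance	false
BRCA2:c.6131G>T	Benign	resistance	false
BRCA2:c.6322C>T	Benign	low_efficacy	true
BRCA2:c.8023A>G	Likely pathogenic	low_efficacy	true
BRCA2:c.9155G>A	Likely benign	resistance	false
BRCA2:c.10219del	VUS	not_covered	false
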