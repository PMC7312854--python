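case_id	variant_key
BRCA006	BRCA1:c.4957G>T
BRCA006	BRCA2:c.6131G>T
BRCA008	BRCA1:c.4957G>T
BRCA008	BRCA2:c.6131G>T
BRCA008	BRCA1:c.3707A>G
BRCA008	BRCA2:c.2350A>G
BRCA052	BRCA1:c.4957G>T
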