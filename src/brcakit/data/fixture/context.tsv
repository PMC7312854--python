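variant_key	insilico_deleterious_fraction	in_functional_domain	domain_name	in_repeat_region	same_residue_known_pathogenic	healthy_adult_observations
BRCA1:c.4957G>T		true	BRCT	false	none	0
BRCA1:c.4957G>A		true	BRCT	false	none	0
BRCA1:c.3283A>G		false		false	none	0
BRCA1:c.3707A>G		false		false	none	0
BRCA1:c.4093C>G		false		false	none	0
BRCA2:c.520C>T		false		false	none	0
BRCA2:c.1744A>C		false		false	none	0
BRCA2:c.2350A>G		false		false	none	0
BRCA2:c.3067_3072del		false		false	none	0
BRCA2:c.5158A>G		false		false	none	0
BRCA2:c.6131G>T		false		false	none	0
BRCA2:c.6322C>T		false		false	none	0
BRCA2:c.8023A>G		false		false	none	0
BRCA2:c.9155G>A	0.05	false		false	none	0
BRCA2:c.10219del		false		false	none	0
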