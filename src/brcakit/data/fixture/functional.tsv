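variant_key	assay_type	result	hr_impact	citation_tag
BRCA1:c.4957G>T	saturation_editing	deleterious	complete_deficiency	sge_cell_viability
BRCA1:c.4957G>A	transcription_activation	deleterious	complete_deficiency	transactivation_loss
BRCA2:c.9155G>A	complementation	neutral	proficient	complementation_assay
BRCA2:c.9155G>A	HR_capacity	neutral	proficient	hr_capacity_assay
BRCA2:c.9155G>A	drug_sensitivity	neutral	proficient	cisplatin_sensitivity
BRCA2:c.8023A>G	splicing	deleterious	partial_deficiency	splice_minigene
BRCA2:c.1744A>C	protein_interaction	intermediate	proficient	midbody_interaction
BRCA2:c.6322C>T	HR_capacity	neutral	increased_activity	intrachromosomal_hr
BRCA2:c.6131G>T	complementation	neutral	proficient	complementation_assay
BRCA2:c.2350A>G	complementation	neutral	proficient	complementation_assay
BRCA2:c.5158A>G	splicing	neutral	proficient	minigene_neutral
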