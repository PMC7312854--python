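variant_key	cohort_id	cohort_kind	allele_count	allele_number
BRCA2:c.6131G>T	ToMMo	japanese	107	7108
BRCA2:c.6131G>T	1000G_JPT	japanese	4	208
BRCA2:c.2350A>G	ToMMo	japanese	149	7108
BRCA2:c.1744A>C	ToMMo	japanese	85	7108
BRCA2:c.6322C>T	ToMMo	japanese	78	7108
BRCA2:c.9155G>A	GnomAD_EAS	east_asian	11	200000
BRCA2:c.520C>T	GnomAD_EAS	east_asian	9	200000
BRCA2:c.5158A>G	GnomAD_EAS	east_asian	7	200000
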