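# brcakit

Consolidated germline interpretation of *BRCA1/2* variants: an automated
ACMG/AMP evidence-code engine, a reputable-database consensus, concordance
analytics between classification sets, and prediction of PARP-inhibitor
efficacy from curated homologous-recombination (HR) functional evidence.

## Who this is for

Clinical and research groups interpreting germline *BRCA1/2* panel results
for hereditary breast/ovarian cancer (HBOC) risk and PARP-inhibitor therapy
decisions. Everything runs from local tables — no web queries — so curated
evidence is swappable and every run is reproducible.

## What it computes

**ACMG arm.** For each variant, 17 of the 28 ACMG/AMP evidence codes are
evaluated automatically from per-variant evidence (PVS1; PS1, PS3; PM1, PM2,
PM4, PM5; PP2, PP3, PP5; BA1; BS1, BS2, BS3; BP1, BP3, BP4); case-level
codes and BP7 are out of scope. Triggered codes are combined by the ACMG
rules into the five-tier scale B < LB < VUS < LP < P. Two BRCA-specific
behaviours: PVS1 is downgraded to moderate strength for truncations starting
in the final exon (possible NMD escape), and the frequency rules are strict —
BA1 fires at allele frequency > 1% in an outbred cohort, BS1 at > 0.01%
(the HBOC-gene threshold), with Japanese-cohort data (ToMMo) first-class
because global cohorts underestimate Japanese-specific allele frequencies.

**Consensus arm.** Assertions from ENIGMA, BIC, ClinVar, and ARUP are
summarized: expert-panel assertions win outright; otherwise sources must
agree at the decision-pole level, else the consensus is Conflicting. Many
clinically observed variants are in no database: that state (NotDocumented)
is explicit.

**Consolidation.** The ACMG call stands unless the consensus is definitive;
an ACMG VUS adopts a definitive consensus tier (the VUS-reclassification
pathway); same-pole disagreement resolves to the more confident tier;
opposite poles surface as a conflict-flagged VUS, never a silent flip.

**Concordance.** Two classification sets are cross-tabulated under the 3- or
5-tier system: overall and per-cluster concordance (denominators on the
reference side A), and decision-impact flagging of discordances where exactly
one side calls the pathogenic/likely-pathogenic pole.

**PARP efficacy.** Functional records map to a predicted efficacy category
independent of the tier: complete HR deficiency → response; neutral evidence
→ resistance; partial HR deficiency, hypomorphic interaction/splicing defects
with retained HR function, and hypermorphic (increased HR activity) variants
→ low efficacy with a monitoring flag; no evidence → not covered.

Variants are identified on GRCh37 against packaged exon models of
NM_007294.3 (*BRCA1*, chr17, minus strand) and NM_000059.3 (*BRCA2*, chr13,
plus strand); c. ↔ g. mapping needs no reference FASTA.

## Worked example

Classify the packaged case-study fixture (15 curated variants with
frequencies, functional-assay records, database assertions, and domain
context):

```
$ FD=$(python -c "from importlib import resources; print(resources.files('brcakit')/'data/fixture')")
$ brcakit classify $FD/variants.tsv --kb-dir $FD --out-dir out
classified 15 variants (0 skipped)
```

`out/classifications.tsv` then contains (abridged):

```
variant_key       hgvs_p     acmg_tier          triggered_codes  consensus          tier
BRCA1:c.4957G>T   p.V1653L   Likely pathogenic  PS3,PM1,PM2,PP2  NotDocumented      Likely pathogenic
BRCA2:c.6131G>T   p.G2044V   Benign             BA1,BS3,BP1      Benign             Benign
BRCA1:c.3707A>G   p.N1236S   VUS                PM2,PP2          NotDocumented      VUS
BRCA2:c.8023A>G   p.I2675V   VUS                PM2,BP1          Likely pathogenic  Likely pathogenic
BRCA2:c.10219del  p.N3407fs  VUS                PVS1(PM),PM2     NotDocumented      VUS
```

Reading the rows: p.V1653L reaches likely pathogenic from a deleterious
saturation-editing result (PS3) plus rarity and domain context; p.G2044V is
benign outright from a Japanese cohort frequency above 1% (BA1); p.I2675V is
a VUS on evidence codes alone but adopts the definitive ClinVar assertion
through consolidation; and the last-exon frameshift p.N3407fs stays VUS
because PVS1 is downgraded to moderate strength there. The JSON sidecar
(`classifications.json`) records every evaluated code with the evidence item
that fired it.

Predicted PARP efficacy for the same set
(`brcakit efficacy out/classifications.tsv --kb-dir $FD --out-dir out`)
maps p.I2675V (splicing defect, partial HR deficiency) and the hypomorphic
p.T582P / hypermorphic p.R2108C to `low_efficacy` with the monitor flag, the
functionally neutral p.R3052Q to `resistance`, and evidence-free variants to
`not_covered` — tier and efficacy deliberately disagree where the biology
does.

Other subcommands: `brcakit compare-sets A.tsv B.tsv --system five` (matrix,
concordance rates, decision-impact list) and `brcakit simulate --seed 7
--n 100 --out-dir sim` (synthetic variants + evidence tables + truth labels).

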