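# Methods

## Transcript models and coordinate handling

Variants are interpreted against fixed RefSeq transcript models on GRCh37:
NM_007294.3 (*BRCA1*, chr17, minus strand, CDS 5592 nt) and NM_000059.3
(*BRCA2*, chr13, plus strand, CDS 10257 nt), shipped as a versioned JSON
asset (`data/transcripts_grch37.json`) holding 1-based inclusive exon
intervals and CDS bounds. c.→g. mapping walks the coding segments in
transcript order; on the minus strand, substitution alleles are
reverse-complemented. The asset's correctness is pinned by four published
g./c. anchor pairs that the test suite asserts in both directions, by the
CDS-length checks, and by an exhaustive round-trip test over every coding
position of both genes.

Protein consequences are classified from HGVS strings alone (frameshift,
nonsense, missense, synonymous, canonical ±1/±2 splice, in-frame indel);
they are never recomputed from genome sequence, which keeps the package
reference-FASTA-free. The price is that a c.-only substitution without a
p. string is classified `other` — callers who need missense/synonymous
resolution must supply the p. term. `last_exon_truncation` is true when a
truncating consequence starts at a CDS position inside the final exon.

Indel normalization: inputs are taken as written (left-aligned HGVS is
assumed); no re-alignment is performed, and VCF anchor bases for indels are
never reconstructed (that would require the reference genome, which is out
of scope). The synthetic generator invents its own indel anchor bases,
seeded.

## Evidence model

All evidence lives in an `AnnotationBundle`, strictly separated from the
engine. Absence is representable and distinct from negative evidence:

* no frequency record means "absent from cohorts" (PM2 territory), not
  frequency zero;
* `in_functional_domain` is tri-state — `True`/`False` are explicit curated
  annotations, `None` means the domain context was never assessed, and
  neither PM1 nor BP1 can fire from `None`;
* an unknown variant key returns the distinguished empty bundle, realizing
  the "not documented in the public domain" state without an error path.

Cohort kinds (`japanese`, `east_asian`, `global`) exist because global
cohorts are poor estimators of Japanese-specific allele frequencies; each
frequency criterion takes its own cohort filter (default: all kinds), and
`EngineConfig.restrict_cohorts` / the CLI `--cohorts` flag reproduce
"with vs without the Japanese cohort" analyses.

## ACMG engine

Implemented code set (17): PVS1; PS1, PS3; PM1, PM2, PM4, PM5; PP2, PP3,
PP5; BA1; BS1, BS2, BS3; BP1, BP3, BP4. Case-level codes (PS2, PS4, PM3,
PM6, PP1, PP4, BS4, BP2, BP5) need family/segregation data and are not
automatable from per-variant evidence; BP7 needs splice-prediction scores
the bundle does not carry. BP6 is implemented but outside the default set:
database assertions feed the consensus arm, and enabling PP5/BP6
(`use_db_assertions=True`) would count the same assertion in both arms of
the consolidation, so both are inert by default while PP5 remains in the
reported inventory.

Key per-code decisions:

* **PVS1 last-exon downgrade.** Truncations starting in the final exon may
  escape nonsense-mediated decay; PVS1 still triggers but at moderate (PM)
  strength via `strength_override`. A lone last-exon frameshift therefore
  combines as one PM → VUS rather than pathogenic.
* **Frequency thresholds are strict.** BA1 at PF > 1% (`ba1_pf=0.01`), BS1
  at PF > 0.01% (`bs1_pf=1e-4`, the threshold used for HBOC genes), PM2 at
  PF < 1e-5 or absent (`pm2_max_pf`). A frequency exactly at a threshold
  classifies on the non-triggering side; the threshold-sharpness tests and
  the acceptance script verify the boundaries by bisection.
* **PS3/BS3 assay qualification.** The well-established set is
  complementation, HR capacity, drug sensitivity, saturation editing, and
  transcription activation. Splicing and protein-interaction assays are
  informative for efficacy prediction but do not qualify for PS3/BS3 —
  which is why a variant with only neutral splicing evidence stays VUS yet
  predicts resistance.
* **PP2/BP1 gene policy.** PP2 applies to *BRCA1* missense; BP1 to *BRCA2*
  missense explicitly annotated outside functional domains. Both are
  config-visible sets, so the policy is auditable and reversible.
* **PP3/BP4** consume a single summarized fraction of concordant in-silico
  predictors (defaults ≥ 0.9 / ≤ 0.1) rather than named tool scores.
* **BS2** defaults to ≥ 5 confirmed healthy adult observations.

Combining follows the ACMG rule sets verbatim, with two resolutions the
guideline leaves open: when Pathogenic and Likely-pathogenic sets are both
satisfied the stronger wins, and when any pathogenic-pole set and any
benign-pole set are simultaneously satisfied the call is VUS with a
conflict flag (no separate "conflicting" tier). The implementation is
checked exhaustively against an independently coded clause-list oracle over
all bounded count vectors, and fuzzed for monotonicity: extra
pathogenic-pole evidence never moves a call toward Benign and vice versa.

## Consensus and consolidation

Database consensus: expert-panel assertions win outright (disagreeing
expert panels → Conflicting); otherwise all sources must agree at the
decision-pole level, the most common tier wins, and ties resolve to the
less extreme tier — conservative by construction. Consolidation precedence:
(a) NotDocumented/Conflicting → ACMG stands; (b) ACMG VUS adopts a
definitive consensus tier; (c) same pole → the more confident tier;
(d) opposite poles → conflict-flagged VUS. These rules are the minimal set
reproducing the intended behaviours (VUS rescue toward a definitive tier,
preservation of pathogenic concordance, no silent pole flips); the algebra
is property-tested for identity on NotDocumented, totality, and pole
safety. All non-expert sources are weighted equally.

## Concordance

Cross-tabulation on the shared key set; keys on one side only are reported
and excluded. Per-cluster concordance divides by side A (the comparator),
matching the convention "concordance within the pathogenic subset" where
the subset is defined by the comparator's labels — the opposite convention
changes every per-cluster figure, so side order is documented at the API.
Decision impact = discordances where exactly one side is in the P/LP pole,
defined on the five-tier system. NotDocumented/Conflicting inputs map to
VUS with a warning. Invariants under test: transposition preserves the
overall rate and transposes the matrix; 3-tier coarsening can only merge
off-diagonal cells into the diagonal, so it never lowers concordance.

## PARP-efficacy ladder

Functional records only — never the tier — drive the category, so
tier/efficacy off-diagonals (benign → low efficacy, VUS → resistance) are
reproducible. Ladder: (1) no records → not_covered; (2) partial HR
deficiency, or a hypomorphic interaction/splicing defect with retained HR
function → low_efficacy + monitor; (3) increased HR activity → low_efficacy
+ monitor (hypermorphic variants are monitored under the same umbrella
rather than given a separate category); (4) all-neutral → resistance;
(5) deleterious with complete HR deficiency → response. Partial and
hypermorphic evidence deliberately outrank complete-deficiency evidence so
mixed profiles are flagged, not called responders. Records reaching no rung
(e.g. deleterious with unknown HR impact) carry no interpretable HR signal
and fall back to not_covered. Contradictory records (complete deficiency
and proficiency from the same assay type) warn; the monitor flag is only
ever set on low-efficacy calls. Predictions are idempotent under record
duplication and total over record combinations (both property-tested).

## Synthetic generator

`generate_kb` plants six evidence templates, all drawn well inside the
criterion thresholds so the engine recovers the intended tier with
probability 1 (boundary values are an opt-in stress flag whose variants sit
exactly on a strict threshold and must classify on the non-triggering
side):

| template | evidence | tier | efficacy |
|---|---|---|---|
| pathogenic_like | nonsense + deleterious complementation assay, absent from cohorts | P | response |
| benign_common | Japanese-cohort PF ~ U(2%, 20%), allele number 7108 (3554 individuals) | B | not covered |
| benign_functional | neutral well-established assay + PF ~ U(2e-5, 8e-5) + benign in-silico | LB | resistance |
| vus_empty | no evidence | VUS | not covered |
| hypomorphic | intermediate splicing defect with retained HR + modest PF | VUS | low efficacy |
| last_exon_truncating | frameshift in the final exon | VUS | not covered |

Default mix: 15/25/15/30/10/5%. Rare-class frequencies sit in
(2e-5, 8e-5) — above the PM2 ceiling, at or below the BS1 threshold — so
neither code fires. Residues are drawn without replacement from per-gene
pools (CDS body vs final exon), keeping keys unique and generation a pure
function of (spec, seed). The comparator generator perturbs each truth
label to a uniformly chosen different tier with the planted discordance
probability, making the overall concordance a binomially recoverable
parameter.

What the generator does not emulate: realistic mutational spectra,
haplotype structure, sequencing error, multi-variant carriers, or correlated
evidence sources. Passing tests therefore demonstrate the correctness of
the interpretation logic under clean planted evidence, not performance on
real-world noisy annotation.

## Packaged fixture

`data/fixture/` encodes fifteen curated case-study variants with their
evidence and expected behaviour: four from the per-case table (V1653L,
G2044V, N1236S, M784V), discordance-analysis variants (K1095E, R174C,
N1023_I1024del, N3407fs, R3052Q, L1365V), functionally characterized
variants (V1653M, I2675V, T582P, R2108C), and one synthetic entry
(BRCA2 c.5158A>G p.I1720V, marked `synthetic` in `variants.tsv`)
representing a VUS whose neutral functional evidence comes from an assay
outside the PS3/BS3 qualification set, hence resistance-predicted while
staying VUS. Exact fixture frequencies are implementation-chosen
(e.g. G2044V at 107/7108 ≈ 1.5%); only their relation to the thresholds is
meaningful. I2675V reaches likely pathogenic through the consolidation
pathway (definitive ClinVar assertion adopted over an ACMG VUS), its only
functional evidence being a splicing defect outside the PS3 set. The
per-case lists (`cases.tsv`) drive the family-risk count: three cases whose
only P/LP germline variant is BRCA1 c.4957G>T.

## Numerical and I/O choices

* Threshold localization (`find_pf_boundary`): coarse sweep (1001 points)
  to bracket the first activation, then 80 bisection steps; valid because
  each frequency criterion is a step function of PF on the searched
  interval. Probe bundles use allele number 1e9 so count rounding is
  negligible against the reported 6-decimal precision.
* Reports are TSV with a frozen column order plus a JSON sidecar carrying
  every evaluated code and its rationale; rationales are a first-class
  output (the workflow's transparency requirement), not debug logging.
* CLI exit status is nonzero exactly when input records were skipped;
  advisory conditions (unknown efficacy key → not_covered, undocumented
  tier mapped to VUS) warn without failing the run.
* Determinism: identical inputs yield byte-identical outputs; all
  randomness flows through a single seeded numpy Generator.

## Known limitations

Single-transcript interpretation only (no alternative isoforms); intronic
variants beyond ±2 are classified `other`; no large rearrangements /
copy-number events; no Bayesian/points-based ACMG refinements; no
drug-specific recommendations beyond the efficacy category; consensus
sources are equally weighted; c.-only substitutions cannot be resolved to
missense vs synonymous without a p. term.
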