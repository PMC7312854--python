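"""Synthetic variants, knowledge bases, and comparator sets; packaged fixtures.

Every stage of the interpretation pipeline is testable without downloads:

* :func:`generate_kb` plants variants of six evidence templates whose
  intended tier is known by construction (evidence is drawn well inside the
  criterion thresholds, never on a boundary, so the engine recovers the
  planted tier deterministically);
* :func:`generate_comparator` perturbs truth labels with a planted
  discordance rate, giving the concordance module a recoverable parameter;
* :func:`paper_fixture` returns the packaged curated fixture: the named
  BRCA1/2 case-study variants with their expected tiers and efficacy
  categories, plus the per-case variant lists used for family-risk
  flagging. One fixture entry (BRCA2 c.5158A>G) is synthetic, included to
  represent variants whose neutral functional evidence comes from an assay
  outside the well-established set.

All generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .knowledge_base import (
    AnnotationBundle,
    DatabaseAssertion,
    FunctionalRecord,
    KnowledgeBase,
    PopulationFrequency,
    load_kb,
)
from .parp import EfficacyCategory
from .tiers import Tier, pole
from .variant_model import (
    TranscriptModel,
    Variant,
    build_variant,
    load_transcript_models,
    read_variant_table,
    revcomp,
)

__all__ = [
    "SimulationSpec",
    "SpecError",
    "generate_kb",
    "generate_comparator",
    "write_fixture_files",
    "PaperFixture",
    "paper_fixture",
    "table1_cases",
    "single_lp_cases",
]

CLASS_TEMPLATES = (
    "pathogenic_like",
    "benign_common",
    "benign_functional",
    "vus_empty",
    "hypomorphic",
    "last_exon_truncating",
)

#: Intended engine tier per template (see generate_kb for the evidence laid
#: down by each template).
TEMPLATE_TIER = {
    "pathogenic_like": Tier.PATHOGENIC,
    "benign_common": Tier.BENIGN,
    "benign_functional": Tier.LIKELY_BENIGN,
    "vus_empty": Tier.VUS,
    "hypomorphic": Tier.VUS,
    "last_exon_truncating": Tier.VUS,
}

TEMPLATE_EFFICACY = {
    "pathogenic_like": EfficacyCategory.RESPONSE,
    "benign_common": EfficacyCategory.NOT_COVERED,
    "benign_functional": EfficacyCategory.RESISTANCE,
    "vus_empty": EfficacyCategory.NOT_COVERED,
    "hypomorphic": EfficacyCategory.LOW_EFFICACY,
    "last_exon_truncating": EfficacyCategory.NOT_COVERED,
}

_DEFAULT_MIX = {
    "pathogenic_like": 0.15,
    "benign_common": 0.25,
    "benign_functional": 0.15,
    "vus_empty": 0.30,
    "hypomorphic": 0.10,
    "last_exon_truncating": 0.05,
}

#: Per-class allele-frequency ranges (fractions). benign_common sits well
#: above the 1% stand-alone rule; the rare classes sit between the PM2
#: ultra-rare ceiling and the 0.01% BS1 threshold so neither code fires.
_DEFAULT_PF_RANGES = {
    "benign_common": (0.02, 0.20),
    "benign_functional": (2e-5, 8e-5),
    "hypomorphic": (2e-5, 8e-5),
}

_BASES = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"


class SpecError(ValueError):
    """Infeasible or malformed simulation spec."""


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    n_variants: int = 100
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    planted_discordance: float = 0.0
    pf_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PF_RANGES)
    )
    #: opt-in boundary stress: additionally emit one variant whose only
    #: evidence is a PF exactly at each strict threshold (must NOT trigger)
    boundary_stress: bool = False

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise SpecError("n_variants must be positive")
        unknown = set(self.class_mix) - set(CLASS_TEMPLATES)
        if unknown:
            raise SpecError(f"unknown class templates {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"class_mix fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.class_mix.values()):
            raise SpecError("class_mix fractions must be non-negative")
        if not 0.0 <= self.planted_discordance <= 1.0:
            raise SpecError("planted_discordance must lie in [0, 1]")


def _random_pf(rng, lo: float, hi: float, allele_number: int = 200000):
    pf = rng.uniform(lo, hi)
    ac = max(1, int(round(pf * allele_number)))
    rec = PopulationFrequency("GnomAD_EAS", "east_asian", ac, allele_number)
    return rec


def _common_japanese_pf(rng, lo: float, hi: float):
    an = 7108  # 3554 individuals
    pf = rng.uniform(lo, hi)
    ac = int(round(pf * an))
    return PopulationFrequency("ToMMo", "japanese", ac, an)


def generate_kb(
    spec: SimulationSpec,
    models: Optional[Mapping[str, TranscriptModel]] = None,
) -> tuple[list[Variant], KnowledgeBase, dict[str, Tier]]:
    """Generate (variants, knowledge base, truth labels) from a spec.

    Evidence per template:

    ``pathogenic_like``      nonsense + deleterious complementation assay,
                             absent from cohorts (PVS1 + PS3 + PM2).
    ``benign_common``        missense with a Japanese-cohort PF above 1%.
    ``benign_functional``    missense, neutral well-established assays plus
                             concordantly benign in-silico scores.
    ``vus_empty``            missense with no evidence at all.
    ``hypomorphic``          missense with an intermediate splicing defect
                             and retained HR function; modest PF.
    ``last_exon_truncating`` frameshift starting in the final exon.
    """
    models = models or load_transcript_models()
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    draws = rng.choice(len(classes), size=spec.n_variants, p=probs)

    variants: list[Variant] = []
    bundles: dict[str, AnnotationBundle] = {}
    truth: dict[str, Tier] = {}

    # disjoint per-gene residue pools (body of the CDS vs the final exon),
    # consumed without replacement so variant keys never collide
    pools: dict[tuple[str, str], list[int]] = {}
    for gene in ("BRCA1", "BRCA2"):
        tm = models[gene]
        n_res = tm.cds_length // 3 - 1  # exclude the stop codon
        last_first = (tm.last_exon_c_start + 2) // 3 + 1
        body = list(range(2, last_first - 1))
        last = list(range(last_first, n_res))
        rng.shuffle(body)
        rng.shuffle(last)
        pools[(gene, "body")] = body
        pools[(gene, "last")] = last

    def _draw_residue(gene: str, region: str) -> tuple[str, int]:
        pool = pools[(gene, region)]
        if not pool:  # this gene's region is exhausted; use the other gene
            gene = "BRCA2" if gene == "BRCA1" else "BRCA1"
            pool = pools[(gene, region)]
            if not pool:
                raise SpecError("residue pools exhausted; reduce n_variants")
        return gene, pool.pop()

    for i, ci in enumerate(draws):
        template = classes[ci]
        gene = "BRCA1" if rng.integers(2) == 0 else "BRCA2"
        region = "last" if template == "last_exon_truncating" else "body"
        gene, res = _draw_residue(gene, region)
        c_pos = 3 * res - 2
        if template == "pathogenic_like":
            ref, alt = "C", "T"
            aa = _AA[rng.integers(len(_AA))]
            v = build_variant(gene, f"c.{c_pos}{ref}>{alt}", f"p.{aa}{res}*", None, models)
        elif template == "last_exon_truncating":
            aa = _AA[rng.integers(len(_AA))]
            v = build_variant(gene, f"c.{c_pos}del", f"p.{aa}{res}fs", None, models)
            anchor = _BASES[rng.integers(4)]
            deleted = _BASES[rng.integers(4)]
            v = replace_alleles(v, anchor + deleted, anchor)
        else:
            ref, alt = rng.choice(list(_BASES), size=2, replace=False)
            a1, a2 = rng.choice(list(_AA), size=2, replace=False)
            v = build_variant(gene, f"c.{c_pos}{ref}>{alt}", f"p.{a1}{res}{a2}", None, models)

        key = v.key
        freqs: list[PopulationFrequency] = []
        funcs: list[FunctionalRecord] = []
        kwargs: dict = {}
        if template == "pathogenic_like":
            funcs.append(
                FunctionalRecord("complementation", "deleterious",
                                 "complete_deficiency", f"sim_assay_{i}")
            )
        elif template == "benign_common":
            lo, hi = spec.pf_ranges.get("benign_common", _DEFAULT_PF_RANGES["benign_common"])
            freqs.append(_common_japanese_pf(rng, lo, hi))
        elif template == "benign_functional":
            lo, hi = spec.pf_ranges.get(
                "benign_functional", _DEFAULT_PF_RANGES["benign_functional"]
            )
            freqs.append(_random_pf(rng, lo, hi))
            funcs.append(
                FunctionalRecord("complementation", "neutral", "proficient",
                                 f"sim_assay_{i}")
            )
            kwargs["insilico_deleterious_fraction"] = float(rng.uniform(0.0, 0.05))
        elif template == "hypomorphic":
            lo, hi = spec.pf_ranges.get("hypomorphic", _DEFAULT_PF_RANGES["hypomorphic"])
            freqs.append(_random_pf(rng, lo, hi))
            funcs.append(
                FunctionalRecord("splicing", "intermediate", "proficient",
                                 f"sim_assay_{i}")
            )
        # vus_empty and last_exon_truncating add no evidence

        bundle = AnnotationBundle(
            variant_key=key,
            frequencies=tuple(sorted(freqs)),
            functional=tuple(sorted(funcs)),
            **kwargs,
        )
        if not bundle.is_empty:
            bundles[key] = bundle
        variants.append(v)
        truth[key] = TEMPLATE_TIER[template]

    if spec.boundary_stress:
        # PF sitting exactly on a strict threshold must not trigger the code:
        # exactly 1% leaves only BS1 (one strong code -> VUS), exactly 0.01%
        # triggers nothing at all.
        for ac, an in ((100, 10000), (1, 10000)):
            _, res = _draw_residue("BRCA2", "body")
            c_pos = 3 * res - 2
            v = build_variant("BRCA2", f"c.{c_pos}A>G", f"p.T{res}A", None, models)
            bundles[v.key] = AnnotationBundle(
                variant_key=v.key,
                frequencies=(PopulationFrequency("ToMMo", "japanese", ac, an),),
            )
            variants.append(v)
            truth[v.key] = Tier.VUS

    return variants, KnowledgeBase(bundles), truth


def replace_alleles(v: Variant, ref: str, alt: str) -> Variant:
    """Copy of a variant with explicit (invented) genomic alleles."""
    return Variant(
        v.gene_symbol, v.chrom, v.g_pos, ref, alt, v.hgvs_g, v.hgvs_c,
        v.hgvs_p, v.rsid, v.consequence, v.last_exon_truncation,
    )


def generate_comparator(
    truth: Mapping[str, Tier],
    planted_discordance: float,
    seed: int,
) -> dict[str, Tier]:
    """Perturb truth labels: each label independently moves to a uniformly
    chosen *different* tier with probability ``planted_discordance``."""
    rng = np.random.default_rng(seed)
    out: dict[str, Tier] = {}
    tiers = list(Tier)
    for key in sorted(truth):
        t = truth[key]
        if rng.random() < planted_discordance:
            others = [x for x in tiers if x is not t]
            out[key] = others[int(rng.integers(len(others)))]
        else:
            out[key] = t
    return out


def write_fixture_files(
    out_dir,
    variants: Sequence[Variant],
    kb_tables_from: KnowledgeBase,
    truth: Mapping[str, Tier],
) -> dict[str, Path]:
    """Write a generated fixture set to disk: VCF + KB TSVs + truth labels.

    Emits the same TSV schemas the knowledge-base loader reads, so a round
    trip through disk reproduces the in-memory KB exactly.
    """
    from .variant_model import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["variants_vcf"] = out / "variants.vcf"
    write_vcf(paths["variants_vcf"], variants)

    freq_rows, func_rows, assert_rows, ctx_rows = [], [], [], []
    for key in kb_tables_from.keys():
        b = kb_tables_from.bundle(key)
        for f in b.frequencies:
            freq_rows.append((key, f.cohort_id, f.cohort_kind,
                              f.allele_count, f.allele_number))
        for r in b.functional:
            func_rows.append((key, r.assay_type, r.result, r.hr_impact, r.citation_tag))
        for a in b.assertions:
            assert_rows.append((key, a.source, a.classification.label, a.review_status))
        ctx_rows.append((
            key,
            "" if b.insilico_deleterious_fraction is None
            else repr(b.insilico_deleterious_fraction),
            "" if b.in_functional_domain is None
            else str(b.in_functional_domain).lower(),
            b.domain_name or "",
            str(b.in_repeat_region).lower(),
            b.same_residue_known_pathogenic,
            b.healthy_adult_observations,
        ))

    def _write(name, rows, cols):
        p = out / name
        pd.DataFrame(rows, columns=cols).to_csv(p, sep="\t", index=False)
        paths[name] = p

    _write("frequencies.tsv", freq_rows,
           ["variant_key", "cohort_id", "cohort_kind", "allele_count", "allele_number"])
    _write("functional.tsv", func_rows,
           ["variant_key", "assay_type", "result", "hr_impact", "citation_tag"])
    _write("assertions.tsv", assert_rows,
           ["variant_key", "source", "classification", "review_status"])
    _write("context.tsv", ctx_rows,
           ["variant_key", "insilico_deleterious_fraction", "in_functional_domain",
            "domain_name", "in_repeat_region", "same_residue_known_pathogenic",
            "healthy_adult_observations"])
    _write("truth.tsv", [(k, t.label) for k, t in sorted(truth.items())],
           ["variant_key", "tier"])
    return paths


# ---------------------------------------------------------------------------
# Packaged curated fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PaperFixture:
    variants: tuple[Variant, ...]
    kb: KnowledgeBase
    expected_tier: Mapping[str, Tier]
    expected_efficacy: Mapping[str, tuple[EfficacyCategory, bool]]
    cases: Mapping[str, tuple[str, ...]]


def _fixture_dir():
    return resources.files("brcakit") / "data" / "fixture"


def paper_fixture(
    models: Optional[Mapping[str, TranscriptModel]] = None,
) -> PaperFixture:
    """The packaged curated fixture set of named BRCA1/2 case-study variants,
    with their expected consolidated tiers and PARP-efficacy behaviour."""
    d = _fixture_dir()
    models = models or load_transcript_models()
    variants, skipped = read_variant_table(d / "variants.tsv", models)
    if skipped:  # pragma: no cover - packaged data must parse
        raise RuntimeError(f"packaged fixture failed to parse: {skipped}")
    kb = load_kb(
        frequencies=d / "frequencies.tsv",
        functional=d / "functional.tsv",
        assertions=d / "assertions.tsv",
        context=d / "context.tsv",
    )
    exp = pd.read_csv(d / "expected.tsv", sep="\t", dtype=str)
    expected_tier = {
        r.variant_key: Tier.from_string(r.expected_tier)
        for r in exp.itertuples(index=False)
    }
    expected_eff = {
        r.variant_key: (
            EfficacyCategory(r.expected_efficacy),
            r.expected_monitor == "true",
        )
        for r in exp.itertuples(index=False)
    }
    return PaperFixture(
        variants=tuple(variants),
        kb=kb,
        expected_tier=expected_tier,
        expected_efficacy=expected_eff,
        cases=table1_cases(),
    )


def table1_cases() -> dict[str, tuple[str, ...]]:
    """Per-case germline variant lists of the packaged case set."""
    df = pd.read_csv(_fixture_dir() / "cases.tsv", sep="\t", dtype=str)
    cases: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        cases.setdefault(r.case_id, []).append(r.variant_key)
    return {k: tuple(v) for k, v in cases.items()}


def single_lp_cases(
    case_map: Mapping[str, Sequence[str]],
    tiers: Mapping[str, Tier],
) -> dict[str, str]:
    """Cases whose germline carries exactly one pathogenic/likely-pathogenic
    variant: candidate disease-causing events with potential family risk.

    Returns {case_id: the single P/LP variant key}.
    """
    out: dict[str, str] = {}
    for case_id, keys in case_map.items():
        lp = [k for k in keys if pole(tiers[k]) == "pathogenic"]
        if len(lp) == 1:
            out[case_id] = lp[0]
    return out
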