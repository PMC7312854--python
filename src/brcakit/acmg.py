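"""Automated ACMG/AMP evidence-code evaluation and combining for BRCA1/2.

Seventeen of the 28 ACMG/AMP evidence codes can be computed from curated
per-variant evidence alone (no family segregation, co-occurrence, or
case-level data): PVS1; PS1, PS3; PM1, PM2, PM4, PM5; PP2, PP3, PP5;
BA1; BS1, BS2, BS3; BP1, BP3, BP4. Case-sensitive codes (PS2, PS4, PM3,
PM6, PP1, PP4, BS4, BP2, BP5) and the synonymous-splice code BP7 are not
automated; BP6 is implemented but outside the default set so that database
assertions feed the consensus arm exactly once.

Two deliberate BRCA-specific behaviours:

* the null-variant code PVS1 is downgraded to moderate strength when the
  truncation starts in the transcript's final exon, because such transcripts
  can escape nonsense-mediated decay and retain partial function;
* population-frequency codes use strict inequalities — BA1 fires above 1%
  allele frequency in an outbred cohort, BS1 above 0.01% (the threshold
  used for hereditary breast/ovarian cancer genes), and a frequency exactly
  at a threshold does not trigger the code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import yaml

from .knowledge_base import AnnotationBundle, max_pf
from .tiers import Tier, pole
from .variant_model import Consequence, Variant

__all__ = [
    "EngineConfig",
    "CriterionCode",
    "CriteriaProfile",
    "FiveTier",
    "Classification",
    "EvaluationError",
    "ConfigError",
    "DEFAULT_ENABLED_CODES",
    "evaluate_criteria",
    "combine_counts",
    "combine_criteria",
    "classify_acmg",
    "find_pf_boundary",
]

CATEGORIES = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")
PATHOGENIC_CATEGORIES = ("PVS", "PS", "PM", "PP")
BENIGN_CATEGORIES = ("BA", "BS", "BP")

#: The default automated code set (17 codes).
DEFAULT_ENABLED_CODES = (
    "PVS1",
    "PS1", "PS3",
    "PM1", "PM2", "PM4", "PM5",
    "PP2", "PP3", "PP5",
    "BA1",
    "BS1", "BS2", "BS3",
    "BP1", "BP3", "BP4",
)

_CODE_RE = re.compile(r"^([A-Z]+)\d+$")


def code_category(code: str) -> str:
    m = _CODE_RE.match(code)
    if not m or m.group(1) not in CATEGORIES:
        raise ConfigError(f"malformed criterion code {code!r}")
    return m.group(1)


class EvaluationError(ValueError):
    """A variant cannot be evaluated (e.g. missing consequence)."""


class ConfigError(ValueError):
    """Invalid engine configuration."""


@dataclass(frozen=True)
class EngineConfig:
    """Thresholds, cohort filters, and policy switches for the engine.

    Frequencies are fractions: ``ba1_pf=0.01`` is the 1% stand-alone benign
    rule, ``bs1_pf=0.0001`` the 0.01% strong-benign rule. Both are strict
    ("greater than"). ``pm2_max_pf`` is the ceiling below which a variant
    counts as absent/ultra-rare for PM2.
    """

    ba1_pf: float = 0.01
    bs1_pf: float = 0.0001
    pm2_max_pf: float = 1e-5
    pp3_min: float = 0.9
    bp4_max: float = 0.1
    bs2_min_obs: int = 5
    ba1_cohorts: frozenset[str] = frozenset({"japanese", "east_asian", "global"})
    bs1_cohorts: frozenset[str] = frozenset({"japanese", "east_asian", "global"})
    pm2_cohorts: frozenset[str] = frozenset({"japanese", "east_asian", "global"})
    well_established_assays: frozenset[str] = frozenset({
        "complementation", "HR_capacity", "drug_sensitivity",
        "saturation_editing", "transcription_activation",
    })
    pp2_genes: frozenset[str] = frozenset({"BRCA1"})
    bp1_genes: frozenset[str] = frozenset({"BRCA2"})
    enabled_codes: tuple[str, ...] = DEFAULT_ENABLED_CODES
    #: feed database assertions into PP5/BP6 (off while the consensus arm
    #: is active, to avoid counting the same assertion in both arms)
    use_db_assertions: bool = False

    def __post_init__(self) -> None:
        for code in self.enabled_codes:
            code_category(code)
            if code not in _EVALUATORS:
                raise ConfigError(f"criterion {code} is not automatable here")

    def restrict_cohorts(self, kinds: Iterable[str]) -> "EngineConfig":
        """A copy whose PF criteria only see the given cohort kinds."""
        kinds = frozenset(kinds)
        return replace(
            self,
            ba1_cohorts=self.ba1_cohorts & kinds,
            bs1_cohorts=self.bs1_cohorts & kinds,
            pm2_cohorts=self.pm2_cohorts & kinds,
        )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "EngineConfig":
        kwargs = {}
        for key, value in data.items():
            if key not in cls.__dataclass_fields__:
                raise ConfigError(f"unknown engine option {key!r}")
            f = cls.__dataclass_fields__[key]
            if isinstance(f.default, frozenset):
                value = frozenset(value)
            elif key == "enabled_codes":
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


@dataclass(frozen=True)
class CriterionCode:
    code: str
    category: str
    triggered: bool
    rationale: str
    strength_override: Optional[str] = None  # e.g. PVS1 downgraded to "PM"

    def __post_init__(self) -> None:
        if self.triggered and not self.rationale:
            raise ValueError(f"{self.code}: triggered codes need a rationale")

    @property
    def effective_category(self) -> str:
        return self.strength_override or self.category


@dataclass(frozen=True)
class CriteriaProfile:
    variant_key: str
    codes: tuple[CriterionCode, ...]

    def __post_init__(self) -> None:
        seen = set()
        for c in self.codes:
            if c.code in seen:
                raise ValueError(f"criterion {c.code} appears twice")
            seen.add(c.code)

    @property
    def counts(self) -> dict[str, int]:
        """Triggered codes per category, after strength overrides."""
        counts = {cat: 0 for cat in CATEGORIES}
        for c in self.codes:
            if c.triggered:
                counts[c.effective_category] += 1
        return counts

    @property
    def triggered_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.codes if c.triggered)

    def describe(self) -> str:
        """Compact report form, e.g. 'PVS1(PM),PM2'."""
        parts = []
        for c in self.codes:
            if not c.triggered:
                continue
            parts.append(
                f"{c.code}({c.strength_override})" if c.strength_override else c.code
            )
        return ",".join(parts)


@dataclass(frozen=True)
class FiveTier:
    value: Tier
    conflict_flag: bool = False

    def __post_init__(self) -> None:
        if self.conflict_flag and self.value is not Tier.VUS:
            raise ValueError("a conflicting combination must resolve to VUS")


@dataclass(frozen=True)
class Classification:
    """A tier call with its provenance and full supporting evidence."""

    variant_key: str
    tier: Tier
    provenance: str  # ACMG | Consensus | Consolidated
    conflict_flag: bool = False
    profile: Optional[CriteriaProfile] = None
    consensus: Optional[object] = None  # ConsensusClassification when consolidated

    def __post_init__(self) -> None:
        if self.provenance == "Consolidated" and (
            self.profile is None or self.consensus is None
        ):
            raise ValueError("a consolidated call must carry both arms")


# ---------------------------------------------------------------------------
# Per-code evaluators
# ---------------------------------------------------------------------------

_TRUNCATING = {
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.CANONICAL_SPLICE,
}


def _pvs1(v: Variant, b: AnnotationBundle, cfg: EngineConfig):
    if v.consequence not in _TRUNCATING:
        return False, "", None
    if v.last_exon_truncation:
        return True, (
            f"null variant ({v.consequence.value}) in the final exon; "
            "possible NMD escape, strength reduced to moderate"
        ), "PM"
    return True, (
        f"null variant ({v.consequence.value}) in a gene where loss of "
        "function is the disease mechanism"
    ), None


def _ps1(v, b, cfg):
    if b.same_residue_known_pathogenic == "same_aa_change":
        return True, "same amino-acid change as an established pathogenic variant", None
    return False, "", None


def _pm5(v, b, cfg):
    if b.same_residue_known_pathogenic == "different_aa_change":
        return True, "novel missense change at a residue with a known pathogenic missense", None
    return False, "", None


def _ps3(v, b, cfg):
    hits = [
        r for r in b.functional
        if r.result == "deleterious" and r.assay_type in cfg.well_established_assays
    ]
    if hits:
        tags = ", ".join(sorted({f"{r.assay_type}[{r.citation_tag}]" for r in hits}))
        return True, f"deleterious result in well-established assay: {tags}", None
    return False, "", None


def _bs3(v, b, cfg):
    if not b.functional:
        return False, "", None
    if all(r.result == "neutral" for r in b.functional) and any(
        r.assay_type in cfg.well_established_assays for r in b.functional
    ):
        tags = ", ".join(sorted({f"{r.assay_type}[{r.citation_tag}]" for r in b.functional}))
        return True, f"no damaging effect in well-established assays: {tags}", None
    return False, "", None


def _pm1(v, b, cfg):
    if v.consequence is Consequence.MISSENSE and b.in_functional_domain is True:
        dom = b.domain_name or "annotated functional domain"
        return True, f"missense in mutational hotspot / functional domain ({dom})", None
    return False, "", None


def _pm2(v, b, cfg):
    top = max_pf(b, cfg.pm2_cohorts)
    if top is None:
        return True, "absent from all population cohorts on file", None
    pf, cohort = top
    if pf < cfg.pm2_max_pf:
        return True, f"extremely rare: max PF {pf:.3g} ({cohort}) < {cfg.pm2_max_pf:g}", None
    return False, "", None


def _pm4(v, b, cfg):
    if v.consequence is Consequence.INFRAME_INDEL and not b.in_repeat_region:
        return True, "protein-length change from in-frame indel outside a repeat region", None
    return False, "", None


def _bp3(v, b, cfg):
    if v.consequence is Consequence.INFRAME_INDEL and b.in_repeat_region:
        return True, "in-frame indel within a repetitive region", None
    return False, "", None


def _pp2(v, b, cfg):
    if v.consequence is Consequence.MISSENSE and v.gene_symbol in cfg.pp2_genes:
        return True, f"missense in {v.gene_symbol}, where missense is an established mechanism", None
    return False, "", None


def _bp1(v, b, cfg):
    if (
        v.consequence is Consequence.MISSENSE
        and v.gene_symbol in cfg.bp1_genes
        and b.in_functional_domain is False
    ):
        return True, f"missense outside annotated functional domains of {v.gene_symbol}", None
    return False, "", None


def _pp3(v, b, cfg):
    frac = b.insilico_deleterious_fraction
    if frac is not None and frac >= cfg.pp3_min:
        return True, f"{frac:.0%} of in-silico predictors call the variant deleterious", None
    return False, "", None


def _bp4(v, b, cfg):
    frac = b.insilico_deleterious_fraction
    if frac is not None and frac <= cfg.bp4_max:
        return True, f"only {frac:.0%} of in-silico predictors call the variant deleterious", None
    return False, "", None


def _pp5(v, b, cfg):
    if not cfg.use_db_assertions:
        return False, "", None
    hits = [
        a for a in b.assertions
        if a.review_status == "expert_panel" and pole(a.classification) == "pathogenic"
    ]
    if hits:
        srcs = ", ".join(sorted(a.source for a in hits))
        return True, f"reputable source reports pathogenic/likely pathogenic ({srcs})", None
    return False, "", None


def _bp6(v, b, cfg):
    if not cfg.use_db_assertions:
        return False, "", None
    hits = [
        a for a in b.assertions
        if a.review_status == "expert_panel" and pole(a.classification) == "benign"
    ]
    if hits:
        srcs = ", ".join(sorted(a.source for a in hits))
        return True, f"reputable source reports benign/likely benign ({srcs})", None
    return False, "", None


def _ba1(v, b, cfg):
    top = max_pf(b, cfg.ba1_cohorts)
    if top is not None and top[0] > cfg.ba1_pf:
        return True, f"PF {top[0]:.4g} in {top[1]} exceeds the {cfg.ba1_pf:.0%} stand-alone rule", None
    return False, "", None


def _bs1(v, b, cfg):
    if _ba1(v, b, cfg)[0]:
        return False, "", None
    top = max_pf(b, cfg.bs1_cohorts)
    if top is not None and top[0] > cfg.bs1_pf:
        return True, (
            f"PF {top[0]:.4g} in {top[1]} is greater than expected for the "
            f"disorder (> {cfg.bs1_pf:.2%})"
        ), None
    return False, "", None


def _bs2(v, b, cfg):
    if b.healthy_adult_observations >= cfg.bs2_min_obs:
        return True, (
            f"observed in {b.healthy_adult_observations} healthy adults "
            f"(>= {cfg.bs2_min_obs})"
        ), None
    return False, "", None


_EVALUATORS: dict[str, Callable] = {
    "PVS1": _pvs1,
    "PS1": _ps1,
    "PS3": _ps3,
    "PM1": _pm1,
    "PM2": _pm2,
    "PM4": _pm4,
    "PM5": _pm5,
    "PP2": _pp2,
    "PP3": _pp3,
    "PP5": _pp5,
    "BA1": _ba1,
    "BS1": _bs1,
    "BS2": _bs2,
    "BS3": _bs3,
    "BP1": _bp1,
    "BP3": _bp3,
    "BP4": _bp4,
    "BP6": _bp6,
}


def evaluate_criteria(
    variant: Variant,
    bundle: AnnotationBundle,
    config: EngineConfig = EngineConfig(),
) -> CriteriaProfile:
    """Evaluate every enabled evidence code for one variant.

    Exactly the codes in ``config.enabled_codes`` appear in the returned
    profile, in that order; each triggered code carries a rationale naming
    the evidence item that fired it.
    """
    if variant.consequence is None:  # pragma: no cover - dataclass requires it
        raise EvaluationError(f"{variant.key}: variant has no consequence class")
    codes = []
    for code in config.enabled_codes:
        triggered, rationale, override = _EVALUATORS[code](variant, bundle, config)
        codes.append(
            CriterionCode(
                code=code,
                category=code_category(code),
                triggered=triggered,
                rationale=rationale,
                strength_override=override if triggered else None,
            )
        )
    return CriteriaProfile(variant_key=variant.key, codes=tuple(codes))


# ---------------------------------------------------------------------------
# Combining rules
# ---------------------------------------------------------------------------


def combine_counts(counts: Mapping[str, int]) -> FiveTier:
    """Combine triggered-code counts per category into a five-tier call.

    Implements the ACMG/AMP combining rules. If both a pathogenic-pole and a
    benign-pole rule set are satisfied the result is VUS with the conflict
    flag raised; the stronger tier wins within a pole.
    """
    n = {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}
    pvs, ps, pm, pp = n["PVS"], n["PS"], n["PM"], n["PP"]
    ba, bs, bp = n["BA"], n["BS"], n["BP"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    path_pole = pathogenic or likely_pathogenic
    benign_pole = benign or likely_benign
    if path_pole and benign_pole:
        return FiveTier(Tier.VUS, conflict_flag=True)
    if pathogenic:
        return FiveTier(Tier.PATHOGENIC)
    if likely_pathogenic:
        return FiveTier(Tier.LIKELY_PATHOGENIC)
    if benign:
        return FiveTier(Tier.BENIGN)
    if likely_benign:
        return FiveTier(Tier.LIKELY_BENIGN)
    return FiveTier(Tier.VUS)


def combine_criteria(profile: CriteriaProfile) -> FiveTier:
    return combine_counts(profile.counts)


def classify_acmg(
    variant: Variant,
    bundle: AnnotationBundle,
    config: EngineConfig = EngineConfig(),
) -> Classification:
    """Evaluate and combine: the ACMG-guided arm of the interpretation."""
    profile = evaluate_criteria(variant, bundle, config)
    result = combine_criteria(profile)
    return Classification(
        variant_key=variant.key,
        tier=result.value,
        provenance="ACMG",
        conflict_flag=result.conflict_flag,
        profile=profile,
    )


def find_pf_boundary(
    predicate: Callable[[float], bool],
    lo: float = 0.0,
    hi: float = 0.05,
    coarse: int = 1000,
    iters: int = 80,
) -> float:
    """Localize the infimum frequency above which ``predicate`` holds.

    A coarse upward sweep over [lo, hi] finds the first activating grid
    point; bisection then narrows the switch point to floating-point
    resolution. Intended for frequency criteria with strict thresholds,
    whose indicator is a step function of PF on the searched interval.
    """
    xs = [lo + (hi - lo) * i / coarse for i in range(coarse + 1)]
    first = next((i for i, x in enumerate(xs) if predicate(x)), None)
    if first is None:
        raise ValueError("predicate never activates on the searched interval")
    if first == 0:
        return lo
    a, b = xs[first - 1], xs[first]
    for _ in range(iters):
        mid = (a + b) / 2
        if predicate(mid):
            b = mid
        else:
            a = mid
    return (a + b) / 2
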