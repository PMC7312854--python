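"""Per-variant evidence storage: population frequencies, functional assays,
database assertions, and annotation context.

The evidence layer is strictly separated from the classification engine: the
engine only ever sees the :class:`AnnotationBundle` handed to it, so curated
content is fully swappable (packaged fixtures, synthetic tables, or a user's
own extracts). Lookup of an unknown variant never fails — it returns a
distinguished all-empty bundle, which is the representation of "not
documented anywhere"; absence of evidence is distinct from negative evidence
throughout.

TSV schemas (tab-separated, one header row):

``frequencies.tsv``
    variant_key, cohort_id, cohort_kind, allele_count, allele_number[, pf]
``functional.tsv``
    variant_key, assay_type, result, hr_impact, citation_tag
``assertions.tsv``
    variant_key, source, classification, review_status
``context.tsv``
    variant_key, insilico_deleterious_fraction, in_functional_domain,
    domain_name, in_repeat_region, same_residue_known_pathogenic,
    healthy_adult_observations
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .tiers import Tier

__all__ = [
    "COHORT_KINDS",
    "ASSAY_TYPES",
    "RESULTS",
    "HR_IMPACTS",
    "SOURCES",
    "REVIEW_STATUSES",
    "KBLoadError",
    "PopulationFrequency",
    "FunctionalRecord",
    "DatabaseAssertion",
    "AnnotationBundle",
    "KnowledgeBase",
    "load_kb",
    "max_pf",
]

COHORT_KINDS = frozenset({"japanese", "east_asian", "global"})
ASSAY_TYPES = frozenset({
    "complementation", "HR_capacity", "drug_sensitivity",
    "transcription_activation", "saturation_editing", "splicing",
    "protein_interaction",
})
RESULTS = frozenset({"deleterious", "neutral", "intermediate"})
HR_IMPACTS = frozenset({
    "complete_deficiency", "partial_deficiency", "proficient",
    "increased_activity", "unknown",
})
SOURCES = frozenset({"ENIGMA", "BIC", "ClinVar", "ARUP"})
REVIEW_STATUSES = frozenset({"expert_panel", "multiple_submitters", "single_submitter"})
SAME_RESIDUE_STATES = frozenset({"same_aa_change", "different_aa_change", "none"})


class KBLoadError(ValueError):
    """Schema or invariant violation while loading evidence tables."""


@dataclass(frozen=True, order=True)
class PopulationFrequency:
    cohort_id: str
    cohort_kind: str
    allele_count: int
    allele_number: int

    def __post_init__(self) -> None:
        if self.cohort_kind not in COHORT_KINDS:
            raise KBLoadError(f"unknown cohort_kind {self.cohort_kind!r}")
        if self.allele_number <= 0:
            raise KBLoadError("allele_number must be positive")
        if not 0 <= self.allele_count <= self.allele_number:
            raise KBLoadError("allele_count must lie in [0, allele_number]")

    @property
    def pf(self) -> float:
        return self.allele_count / self.allele_number


@dataclass(frozen=True, order=True)
class FunctionalRecord:
    assay_type: str
    result: str
    hr_impact: str
    citation_tag: str

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise KBLoadError(f"unknown assay_type {self.assay_type!r}")
        if self.result not in RESULTS:
            raise KBLoadError(f"unknown result {self.result!r}")
        if self.hr_impact not in HR_IMPACTS:
            raise KBLoadError(f"unknown hr_impact {self.hr_impact!r}")
        if self.result == "neutral" and self.hr_impact not in (
            "proficient", "increased_activity", "unknown"
        ):
            raise KBLoadError(
                "a neutral result cannot assert an HR deficiency "
                f"(got hr_impact={self.hr_impact!r})"
            )


@dataclass(frozen=True, order=True)
class DatabaseAssertion:
    source: str
    classification: Tier
    review_status: str

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise KBLoadError(f"unknown source {self.source!r}")
        if self.review_status not in REVIEW_STATUSES:
            raise KBLoadError(f"unknown review_status {self.review_status!r}")


@dataclass(frozen=True)
class AnnotationBundle:
    """All evidence attached to one variant.

    ``in_functional_domain`` is tri-state: True / False are explicit curated
    annotations, None means the domain context was never assessed (and
    neither the domain-hotspot nor the benign-missense-gene criterion can
    fire from it).
    """

    variant_key: str
    frequencies: tuple[PopulationFrequency, ...] = ()
    functional: tuple[FunctionalRecord, ...] = ()
    assertions: tuple[DatabaseAssertion, ...] = ()
    insilico_deleterious_fraction: Optional[float] = None
    in_functional_domain: Optional[bool] = None
    domain_name: Optional[str] = None
    in_repeat_region: bool = False
    same_residue_known_pathogenic: str = "none"
    healthy_adult_observations: int = 0

    def __post_init__(self) -> None:
        if self.insilico_deleterious_fraction is not None and not (
            0.0 <= self.insilico_deleterious_fraction <= 1.0
        ):
            raise KBLoadError("insilico_deleterious_fraction must lie in [0,1]")
        if self.same_residue_known_pathogenic not in SAME_RESIDUE_STATES:
            raise KBLoadError(
                f"unknown same_residue state {self.same_residue_known_pathogenic!r}"
            )
        if self.healthy_adult_observations < 0:
            raise KBLoadError("healthy_adult_observations must be >= 0")
        seen = set()
        for a in self.assertions:
            if a.source in seen:
                raise KBLoadError(f"duplicate assertion source {a.source}")
            seen.add(a.source)

    @classmethod
    def empty(cls, variant_key: str) -> "AnnotationBundle":
        return cls(variant_key=variant_key)

    @property
    def is_empty(self) -> bool:
        return self == AnnotationBundle.empty(self.variant_key)


class KnowledgeBase:
    """Indexed per-variant evidence, keyed by ``GENE:c.<change>``."""

    def __init__(self, bundles: Mapping[str, AnnotationBundle] | None = None):
        self._bundles: dict[str, AnnotationBundle] = dict(
            sorted((bundles or {}).items())
        )

    def bundle(self, variant_key: str) -> AnnotationBundle:
        """Evidence for a variant; the empty bundle if nothing is on file."""
        return self._bundles.get(variant_key, AnnotationBundle.empty(variant_key))

    def keys(self) -> list[str]:
        return list(self._bundles)

    def __len__(self) -> int:
        return len(self._bundles)

    def __contains__(self, key: str) -> bool:
        return key in self._bundles

    def __eq__(self, other) -> bool:
        return isinstance(other, KnowledgeBase) and self._bundles == other._bundles

    @classmethod
    def from_dir(cls, directory) -> "KnowledgeBase":
        """Load whichever of the four evidence tables exist in a directory."""
        d = Path(directory)
        paths = {
            name: (d / f"{name}.tsv" if (d / f"{name}.tsv").exists() else None)
            for name in ("frequencies", "functional", "assertions", "context")
        }
        return load_kb(**paths)


def _read(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KBLoadError(f"{table}: missing columns {missing}")


def _parse_bool(s: str, table: str, row: int, default: Optional[bool]) -> Optional[bool]:
    v = s.strip().lower()
    if v in ("", "na", "."):
        return default
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise KBLoadError(f"{table} row {row}: cannot parse boolean {s!r}")


def load_kb(
    frequencies=None,
    functional=None,
    assertions=None,
    context=None,
) -> KnowledgeBase:
    """Assemble a KnowledgeBase from TSV evidence tables.

    Any table may be omitted. Loading is order-independent: permuting rows
    yields an identical knowledge base. Schema or invariant violations raise
    :class:`KBLoadError` carrying the offending row number (header = row 1).
    """
    freqs: dict[str, list[PopulationFrequency]] = {}
    funcs: dict[str, list[FunctionalRecord]] = {}
    asserts: dict[str, list[DatabaseAssertion]] = {}
    ctx: dict[str, dict] = {}

    if frequencies is not None:
        df = _read(frequencies)
        _require(df, ("variant_key", "cohort_id", "cohort_kind",
                      "allele_count", "allele_number"), "frequencies")
        seen = set()
        for i, row in enumerate(df.itertuples(index=False), start=2):
            key = row.variant_key
            try:
                rec = PopulationFrequency(
                    cohort_id=row.cohort_id,
                    cohort_kind=row.cohort_kind,
                    allele_count=int(row.allele_count),
                    allele_number=int(row.allele_number),
                )
            except (KBLoadError, ValueError) as exc:
                raise KBLoadError(f"frequencies row {i}: {exc}") from None
            stated = getattr(row, "pf", "")
            if stated not in ("", ".", "na"):
                if abs(float(stated) - rec.pf) > 0.5 / rec.allele_number + 1e-12:
                    raise KBLoadError(
                        f"frequencies row {i}: pf={stated} inconsistent with "
                        f"{rec.allele_count}/{rec.allele_number}"
                    )
            if (key, rec.cohort_id) in seen:
                raise KBLoadError(
                    f"frequencies row {i}: duplicate cohort {rec.cohort_id} for {key}"
                )
            seen.add((key, rec.cohort_id))
            freqs.setdefault(key, []).append(rec)

    if functional is not None:
        df = _read(functional)
        _require(df, ("variant_key", "assay_type", "result", "hr_impact"), "functional")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                rec = FunctionalRecord(
                    assay_type=row.assay_type,
                    result=row.result,
                    hr_impact=row.hr_impact,
                    citation_tag=getattr(row, "citation_tag", "") or "",
                )
            except KBLoadError as exc:
                raise KBLoadError(f"functional row {i}: {exc}") from None
            funcs.setdefault(row.variant_key, []).append(rec)

    if assertions is not None:
        df = _read(assertions)
        _require(df, ("variant_key", "source", "classification", "review_status"),
                 "assertions")
        seen = set()
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                rec = DatabaseAssertion(
                    source=row.source,
                    classification=Tier.from_string(row.classification),
                    review_status=row.review_status,
                )
            except (KBLoadError, ValueError) as exc:
                raise KBLoadError(f"assertions row {i}: {exc}") from None
            if (row.variant_key, rec.source) in seen:
                raise KBLoadError(
                    f"assertions row {i}: duplicate source {rec.source} "
                    f"for {row.variant_key}"
                )
            seen.add((row.variant_key, rec.source))
            asserts.setdefault(row.variant_key, []).append(rec)

    if context is not None:
        df = _read(context)
        _require(df, ("variant_key",), "context")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            key = row.variant_key
            if key in ctx:
                raise KBLoadError(f"context row {i}: duplicate variant_key {key}")
            insilico_raw = getattr(row, "insilico_deleterious_fraction", "")
            insilico = (
                None if insilico_raw.strip() in ("", ".", "na")
                else float(insilico_raw)
            )
            ctx[key] = dict(
                insilico_deleterious_fraction=insilico,
                in_functional_domain=_parse_bool(
                    getattr(row, "in_functional_domain", ""), "context", i, None
                ),
                domain_name=(getattr(row, "domain_name", "").strip(". ") or None),
                in_repeat_region=_parse_bool(
                    getattr(row, "in_repeat_region", ""), "context", i, False
                ),
                same_residue_known_pathogenic=(
                    getattr(row, "same_residue_known_pathogenic", "").strip(". ")
                    or "none"
                ),
                healthy_adult_observations=int(
                    getattr(row, "healthy_adult_observations", "").strip(". ") or 0
                ),
            )

    bundles: dict[str, AnnotationBundle] = {}
    for key in sorted(set(freqs) | set(funcs) | set(asserts) | set(ctx)):
        try:
            bundles[key] = AnnotationBundle(
                variant_key=key,
                frequencies=tuple(sorted(freqs.get(key, ()))),
                functional=tuple(sorted(funcs.get(key, ()))),
                assertions=tuple(sorted(asserts.get(key, ()))),
                **ctx.get(key, {}),
            )
        except KBLoadError as exc:
            raise KBLoadError(f"{key}: {exc}") from None
    return KnowledgeBase(bundles)


def max_pf(
    bundle: AnnotationBundle,
    cohort_filter: Iterable[str] = COHORT_KINDS,
) -> Optional[tuple[float, str]]:
    """Highest allele frequency among cohorts of the given kinds.

    Returns ``(pf, cohort_id)`` or None when no matching record exists
    (absence of frequency data, not frequency zero). Ties break toward the
    lexicographically first cohort id for determinism.
    """
    kinds = set(cohort_filter)
    candidates = [f for f in bundle.frequencies if f.cohort_kind in kinds]
    if not candidates:
        return None
    best = max(candidates, key=lambda f: (f.pf, [-ord(c) for c in f.cohort_id]))
    return best.pf, best.cohort_id
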