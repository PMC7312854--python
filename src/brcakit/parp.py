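"""Predicted PARP-inhibitor efficacy from curated functional evidence.

PARP inhibition is synthetically lethal with homologous-recombination (HR)
deficiency, so the predicted efficacy category follows the variant's
functional impact on HR — not its classification tier. Benign variants with
neutral functional evidence predict *resistance*; complete HR deficiency
predicts *response*; hypomorphic variants (partial HR deficiency, or
protein-interaction/splicing defects with retained HR function) and
hypermorphic variants (increased HR activity) predict *low efficacy* and
are flagged for monitoring, since partial function complicates treatment
decisions. Without functional evidence the variant is simply *not covered*.

Because the mapping is driven by functional records only, a variant's tier
and its efficacy category can disagree — e.g. a benign variant with a
hypomorphic interaction defect still maps to low efficacy, and a VUS with
neutral assay results maps to resistance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .acmg import Classification
from .knowledge_base import FunctionalRecord

__all__ = ["EfficacyCategory", "EfficacyBasis", "EfficacyPrediction", "predict_efficacy"]


class EfficacyCategory(str, Enum):
    RESPONSE = "response"
    LOW_EFFICACY = "low_efficacy"
    RESISTANCE = "resistance"
    NOT_COVERED = "not_covered"


class EfficacyBasis(str, Enum):
    COMPLETE_HR_DEFICIENCY = "complete_HR_deficiency"
    PARTIAL_HR_DEFICIENCY = "partial_HR_deficiency"
    HYPOMORPHIC = "hypomorphic"
    HYPERMORPHIC = "hypermorphic"
    NEUTRAL = "neutral"
    NO_FUNCTIONAL_EVIDENCE = "no_functional_evidence"


@dataclass(frozen=True)
class EfficacyPrediction:
    category: EfficacyCategory
    basis: EfficacyBasis
    evidence_tags: tuple[str, ...] = ()
    monitor_flag: bool = False

    def __post_init__(self) -> None:
        not_covered = self.category is EfficacyCategory.NOT_COVERED
        no_evidence = self.basis is EfficacyBasis.NO_FUNCTIONAL_EVIDENCE
        if not_covered != no_evidence:
            raise ValueError("not_covered iff no informative functional evidence")
        if self.monitor_flag and self.category is not EfficacyCategory.LOW_EFFICACY:
            raise ValueError("only low-efficacy predictions carry the monitor flag")


_HYPOMORPHIC_ASSAYS = {"protein_interaction", "splicing"}
_RETAINED = {"proficient", "unknown"}


def _tags(records) -> tuple[str, ...]:
    return tuple(sorted({r.citation_tag for r in records if r.citation_tag}))


def predict_efficacy(
    cls: Classification,
    functional: Sequence[FunctionalRecord],
) -> EfficacyPrediction:
    """Map functional evidence to a predicted PARP-inhibitor efficacy category.

    Decision ladder (first matching rung wins; duplicated records are
    collapsed first, so the prediction is idempotent):

    1. no functional records -> not_covered;
    2. partial HR deficiency, or a hypomorphic protein-interaction/splicing
       defect with retained HR function -> low_efficacy, monitored;
    3. increased HR activity (hypermorphic) -> low_efficacy, monitored;
    4. all records neutral -> resistance;
    5. deleterious with complete HR deficiency -> response.

    Partial/hypermorphic evidence deliberately outranks complete-deficiency
    evidence so that mixed profiles are flagged rather than called
    responders. Records that reach no rung (e.g. a lone deleterious result
    with unknown HR impact) carry no interpretable HR signal and fall back
    to not_covered. Contradictory records — complete deficiency and
    proficiency from the same assay type — emit a warning. The tier in
    ``cls`` is never consulted for the category or basis; it only rides
    along in reports.
    """
    records = tuple(sorted(set(functional)))
    if not records:
        return EfficacyPrediction(
            EfficacyCategory.NOT_COVERED, EfficacyBasis.NO_FUNCTIONAL_EVIDENCE
        )

    by_assay: dict[str, set[str]] = {}
    for r in records:
        by_assay.setdefault(r.assay_type, set()).add(r.hr_impact)
    for assay, impacts in by_assay.items():
        if "complete_deficiency" in impacts and "proficient" in impacts:
            warnings.warn(
                f"{cls.variant_key}: conflicting {assay} records "
                "(complete deficiency vs proficient)",
                stacklevel=2,
            )

    partial = [r for r in records if r.hr_impact == "partial_deficiency"]
    if partial:
        return EfficacyPrediction(
            EfficacyCategory.LOW_EFFICACY,
            EfficacyBasis.PARTIAL_HR_DEFICIENCY,
            _tags(partial),
            monitor_flag=True,
        )
    hypomorphic = [
        r for r in records
        if r.assay_type in _HYPOMORPHIC_ASSAYS
        and r.result in ("deleterious", "intermediate")
        and r.hr_impact in _RETAINED
    ]
    if hypomorphic:
        return EfficacyPrediction(
            EfficacyCategory.LOW_EFFICACY,
            EfficacyBasis.HYPOMORPHIC,
            _tags(hypomorphic),
            monitor_flag=True,
        )
    hypermorphic = [r for r in records if r.hr_impact == "increased_activity"]
    if hypermorphic:
        return EfficacyPrediction(
            EfficacyCategory.LOW_EFFICACY,
            EfficacyBasis.HYPERMORPHIC,
            _tags(hypermorphic),
            monitor_flag=True,
        )
    if all(r.result == "neutral" for r in records):
        return EfficacyPrediction(
            EfficacyCategory.RESISTANCE, EfficacyBasis.NEUTRAL, _tags(records)
        )
    complete = [
        r for r in records
        if r.result == "deleterious" and r.hr_impact == "complete_deficiency"
    ]
    if complete:
        return EfficacyPrediction(
            EfficacyCategory.RESPONSE,
            EfficacyBasis.COMPLETE_HR_DEFICIENCY,
            _tags(complete),
        )
    # records exist but none speaks to HR functionality
    return EfficacyPrediction(
        EfficacyCategory.NOT_COVERED, EfficacyBasis.NO_FUNCTIONAL_EVIDENCE
    )
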