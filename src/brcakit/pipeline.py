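"""Orchestration of the consolidated interpretation and report shaping.

One variant flows: evidence lookup -> ACMG evidence-code evaluation and
combining -> database consensus -> consolidation -> report row. The report
is a TSV with a frozen column order (diffable across runs) plus a JSON
sidecar carrying every triggered criterion with its rationale — rationales
are a first-class output, not debug information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .acmg import Classification, EngineConfig, classify_acmg
from .consensus import ConsensusClassification, consolidate, db_consensus
from .knowledge_base import KnowledgeBase
from .parp import EfficacyPrediction, predict_efficacy
from .tiers import Tier
from .variant_model import Variant

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "classification_frame",
    "rationale_records",
    "efficacy_frame",
]

#: Frozen column order of the classification report.
REPORT_COLUMNS = [
    "variant_key", "gene", "chrom", "g_pos", "g_ref", "g_alt",
    "hgvs_c", "hgvs_p", "rsid", "consequence",
    "acmg_tier", "triggered_codes", "consensus", "consensus_sources",
    "tier", "provenance", "conflict_flag",
]

EFFICACY_COLUMNS = [
    "variant_key", "tier", "category", "basis", "monitor_flag", "evidence_tags",
]


@dataclass(frozen=True)
class PipelineResult:
    variant: Variant
    acmg: Classification
    consensus: Optional[ConsensusClassification]
    final: Classification


def run_pipeline(
    variants: Sequence[Variant],
    kb: KnowledgeBase,
    config: EngineConfig = EngineConfig(),
    consolidation: bool = True,
) -> list[PipelineResult]:
    """Classify variants in deterministic genomic order.

    With ``consolidation`` off, the final call is the ACMG arm alone
    (the "ACMG-guided" mode); otherwise the database consensus is computed
    from the bundle's assertions and merged in.
    """
    results = []
    for v in sorted(variants, key=lambda x: x.sort_key):
        bundle = kb.bundle(v.key)
        acmg_cls = classify_acmg(v, bundle, config)
        if consolidation:
            cons = db_consensus(bundle.assertions)
            final = consolidate(acmg_cls, cons)
        else:
            cons, final = None, acmg_cls
        results.append(PipelineResult(v, acmg_cls, cons, final))
    return results


def classification_frame(results: Sequence[PipelineResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        v = r.variant
        rows.append({
            "variant_key": v.key,
            "gene": v.gene_symbol,
            "chrom": v.chrom,
            "g_pos": v.g_pos,
            "g_ref": v.g_ref or "",
            "g_alt": v.g_alt or "",
            "hgvs_c": v.hgvs_c,
            "hgvs_p": v.hgvs_p or "",
            "rsid": v.rsid or "",
            "consequence": v.consequence.value,
            "acmg_tier": r.acmg.tier.label,
            "triggered_codes": r.acmg.profile.describe() if r.acmg.profile else "",
            "consensus": r.consensus.label if r.consensus else "",
            "consensus_sources": (
                ",".join(r.consensus.contributing_sources) if r.consensus else ""
            ),
            "tier": r.final.tier.label,
            "provenance": r.final.provenance,
            "conflict_flag": str(r.final.conflict_flag).lower(),
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def rationale_records(results: Sequence[PipelineResult]) -> list[dict]:
    """Structured rationales for the JSON sidecar: every evaluated code with
    its triggered state, strength, and the evidence item that fired it."""
    out = []
    for r in results:
        profile = r.acmg.profile
        out.append({
            "variant_key": r.variant.key,
            "tier": r.final.tier.label,
            "provenance": r.final.provenance,
            "conflict_flag": r.final.conflict_flag,
            "consensus": r.consensus.label if r.consensus else None,
            "consensus_basis": r.consensus.basis if r.consensus else None,
            "criteria": [
                {
                    "code": c.code,
                    "category": c.effective_category,
                    "triggered": c.triggered,
                    "rationale": c.rationale,
                }
                for c in (profile.codes if profile else ())
            ],
        })
    return out


def efficacy_frame(
    tiers: dict[str, Tier],
    kb: KnowledgeBase,
) -> pd.DataFrame:
    """Efficacy report for already-classified variants, joined on key."""
    rows = []
    for key in tiers:
        bundle = kb.bundle(key)
        cls = Classification(variant_key=key, tier=tiers[key], provenance="ACMG")
        pred: EfficacyPrediction = predict_efficacy(cls, bundle.functional)
        rows.append({
            "variant_key": key,
            "tier": tiers[key].label,
            "category": pred.category.value,
            "basis": pred.basis.value,
            "monitor_flag": str(pred.monitor_flag).lower(),
            "evidence_tags": ",".join(pred.evidence_tags),
        })
    return pd.DataFrame(rows, columns=EFFICACY_COLUMNS)
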