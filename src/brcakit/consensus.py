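"""Reputable-database consensus and consolidation with the ACMG arm.

The consensus arm summarizes assertions from ENIGMA, BIC, ClinVar, and ARUP
into a single value: a five-tier call, NotDocumented (no source reports the
variant — true for a large share of clinically observed BRCA1/2 alleles),
or Conflicting. An expert-panel assertion wins outright; otherwise
non-expert sources must agree at the decision-pole level.

Consolidation merges the two independent arms. The ACMG arm is total (every
variant gets a call), so consolidation never yields NotDocumented; the
consensus arm's main contribution is rescuing ACMG VUS calls toward a
definitive tier, and pole-level opposition is never silently resolved — it
surfaces as a flagged VUS.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .acmg import Classification, CriteriaProfile
from .knowledge_base import DatabaseAssertion
from .tiers import Tier, pole

__all__ = [
    "ConsensusClassification",
    "ConsensusInputError",
    "db_consensus",
    "consolidate",
]

NOT_DOCUMENTED = "not_documented"
CONFLICTING = "conflicting"
CLASSIFIED = "classified"


class ConsensusInputError(ValueError):
    """Invalid assertion set (e.g. duplicate source)."""


@dataclass(frozen=True)
class ConsensusClassification:
    value: Optional[Tier]  # None unless status == "classified"
    status: str  # classified | not_documented | conflicting
    contributing_sources: tuple[str, ...] = ()
    basis: str = ""

    def __post_init__(self) -> None:
        if (self.status == NOT_DOCUMENTED) != (not self.contributing_sources):
            raise ValueError("NotDocumented iff no contributing sources")
        if (self.status == CLASSIFIED) != (self.value is not None):
            raise ValueError("a classified consensus must carry a tier")

    @property
    def label(self) -> str:
        if self.status == NOT_DOCUMENTED:
            return "NotDocumented"
        if self.status == CONFLICTING:
            return "Conflicting"
        return self.value.label

    @classmethod
    def not_documented(cls) -> "ConsensusClassification":
        return cls(None, NOT_DOCUMENTED, (), "no reputable source reports this variant")


def db_consensus(assertions: Sequence[DatabaseAssertion]) -> ConsensusClassification:
    """Consensus of reputable-database assertions.

    Precedence: an expert-panel assertion wins outright; otherwise all
    remaining sources must agree at the decision-pole level (P/LP vs VUS vs
    B/LB), in which case the most common tier wins, ties resolving to the
    less extreme tier (LP over P, LB over B). Anything else is Conflicting.
    """
    seen = set()
    for a in assertions:
        if a.source in seen:
            raise ConsensusInputError(f"duplicate assertion source {a.source}")
        seen.add(a.source)

    if not assertions:
        return ConsensusClassification.not_documented()

    expert = [a for a in assertions if a.review_status == "expert_panel"]
    if expert:
        tiers = {a.classification for a in expert}
        sources = tuple(sorted(a.source for a in expert))
        if len(tiers) == 1:
            (tier,) = tiers
            return ConsensusClassification(
                tier, CLASSIFIED, sources,
                f"expert-panel assertion ({', '.join(sources)})",
            )
        return ConsensusClassification(
            None, CONFLICTING, sources, "expert panels disagree"
        )

    sources = tuple(sorted(a.source for a in assertions))
    poles = {pole(a.classification) for a in assertions}
    if len(poles) > 1:
        return ConsensusClassification(
            None, CONFLICTING, sources, "sources disagree at the decision-pole level"
        )
    tally = Counter(a.classification for a in assertions)
    top_count = max(tally.values())
    # tie-break toward the less extreme tier (closer to VUS)
    tier = min(
        (t for t, c in tally.items() if c == top_count),
        key=lambda t: abs(int(t) - int(Tier.VUS)),
    )
    return ConsensusClassification(
        tier, CLASSIFIED, sources,
        f"{tally[tier]}/{len(assertions)} sources agree within the pole",
    )


def consolidate(
    acmg: Classification, consensus: ConsensusClassification
) -> Classification:
    """Merge the ACMG-guided call with the database consensus.

    Precedence: (a) NotDocumented/Conflicting consensus leaves the ACMG tier
    standing; (b) an ACMG VUS adopts a definitive consensus tier (the VUS
    reclassification pathway); (c) same pole -> the more confident tier;
    (d) opposite poles -> VUS with the conflict flag.
    """
    if acmg.provenance != "ACMG":
        raise ValueError("consolidate expects the ACMG arm as first argument")

    if consensus.status != CLASSIFIED:
        tier, flag = acmg.tier, acmg.conflict_flag
    else:
        ct = consensus.value
        if acmg.tier is Tier.VUS:
            tier, flag = ct, False
        elif ct is Tier.VUS:
            tier, flag = acmg.tier, acmg.conflict_flag
        elif pole(acmg.tier) == pole(ct):
            # the more confident tier within the pole (P over LP, B over LB)
            tier = max((acmg.tier, ct), key=lambda t: abs(int(t) - int(Tier.VUS)))
            flag = False
        else:
            tier, flag = Tier.VUS, True

    return Classification(
        variant_key=acmg.variant_key,
        tier=tier,
        provenance="Consolidated",
        conflict_flag=flag,
        profile=acmg.profile,
        consensus=consensus,
    )
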