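"""The five-tier germline classification scale.

Tiers are ordered Benign < Likely benign < VUS < Likely pathogenic <
Pathogenic so that "moving toward a pole" is a plain integer comparison.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Optional

__all__ = ["Tier", "pole"]


class Tier(IntEnum):
    BENIGN = 0
    LIKELY_BENIGN = 1
    VUS = 2
    LIKELY_PATHOGENIC = 3
    PATHOGENIC = 4

    @property
    def label(self) -> str:
        return _LABELS[self]

    @property
    def short(self) -> str:
        return _SHORT[self]

    @classmethod
    def from_string(cls, s: str) -> "Tier":
        key = s.strip().lower().replace("-", " ").replace("_", " ")
        try:
            return _PARSE[key]
        except KeyError:
            raise ValueError(f"unrecognized tier {s!r}") from None


_LABELS = {
    Tier.BENIGN: "Benign",
    Tier.LIKELY_BENIGN: "Likely benign",
    Tier.VUS: "VUS",
    Tier.LIKELY_PATHOGENIC: "Likely pathogenic",
    Tier.PATHOGENIC: "Pathogenic",
}

_SHORT = {
    Tier.BENIGN: "B",
    Tier.LIKELY_BENIGN: "LB",
    Tier.VUS: "VUS",
    Tier.LIKELY_PATHOGENIC: "LP",
    Tier.PATHOGENIC: "P",
}

_PARSE = {}
for _t, _l in _LABELS.items():
    _PARSE[_l.lower()] = _t
for _t, _s in _SHORT.items():
    _PARSE[_s.lower()] = _t
_PARSE["uncertain significance"] = Tier.VUS
_PARSE["variant of unknown significance"] = Tier.VUS
_PARSE["likelybenign"] = Tier.LIKELY_BENIGN
_PARSE["likelypathogenic"] = Tier.LIKELY_PATHOGENIC


def pole(tier: Tier) -> Optional[str]:
    """Decision pole of a tier: 'pathogenic', 'benign', or None for VUS."""
    if tier >= Tier.LIKELY_PATHOGENIC:
        return "pathogenic"
    if tier <= Tier.LIKELY_BENIGN:
        return "benign"
    return None
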