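"""Concordance analytics between two classification sets.

Given two maps variant -> tier (e.g. a published comparator study vs this
package's calls), builds the cross-tabulated classification matrix, overall
and per-cluster concordance rates under the 3- or 5-tier system, and flags
discordances of clinical decision impact (disagreements involving the
pathogenic/likely-pathogenic pole, i.e. those that would change patient
management).

Convention: per-cluster denominators use side A, the reference/comparator
side — "concordance within the pathogenic subset" means the subset defined
by the comparator's labels. The opposite convention changes every
per-cluster figure, so side order matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .tiers import Tier, pole

__all__ = [
    "ComparisonError",
    "ComparisonResult",
    "map_tier",
    "compare",
    "decision_impact",
    "read_classification_set",
]

THREE_TIER_LABELS = ("pathogenic", "VUS", "benign")
FIVE_TIER_LABELS = tuple(t.label for t in sorted(Tier, reverse=True))


class ComparisonError(ValueError):
    """The two sets cannot be compared (e.g. no shared variants)."""


def map_tier(cls: Tier, system: str = "five") -> str:
    """Project a five-tier value onto the chosen tier system.

    ``five`` is the identity (label form); ``three`` pools P/LP into
    'pathogenic' and B/LB into 'benign', keeping VUS as its own cluster.
    """
    if system == "five":
        return cls.label
    if system == "three":
        return pole(cls) or "VUS"
    raise ComparisonError(f"unknown tier system {system!r}")


def _coerce(value, side: str, key: str) -> Tier:
    if isinstance(value, Tier):
        return value
    try:
        return Tier.from_string(str(value))
    except ValueError:
        warnings.warn(
            f"{side}[{key}]: undocumented/conflicting value {value!r} treated as VUS",
            stacklevel=3,
        )
        return Tier.VUS


@dataclass(frozen=True)
class ComparisonResult:
    system: str
    matrix: pd.DataFrame  # rows = side A, columns = side B
    n_total: int
    overall_concordance: float
    per_cluster_concordance: dict[str, float]
    discordant_pairs: tuple[tuple[str, Tier, Tier], ...]
    decision_impact_variants: tuple[str, ...]
    only_in_a: tuple[str, ...] = ()
    only_in_b: tuple[str, ...] = ()

    def transpose(self) -> "ComparisonResult":
        """The same comparison with the sides swapped."""
        labels = list(self.matrix.index)
        per_cluster = {}
        mt = self.matrix.T
        for lab in labels:
            denom = mt.loc[lab].sum()
            if denom:
                per_cluster[lab] = mt.loc[lab, lab] / denom
        return ComparisonResult(
            system=self.system,
            matrix=mt,
            n_total=self.n_total,
            overall_concordance=self.overall_concordance,
            per_cluster_concordance=per_cluster,
            discordant_pairs=tuple((k, tb, ta) for k, ta, tb in self.discordant_pairs),
            decision_impact_variants=self.decision_impact_variants,
            only_in_a=self.only_in_b,
            only_in_b=self.only_in_a,
        )


def compare(
    set_a: Mapping[str, Tier],
    set_b: Mapping[str, Tier],
    system: str = "five",
) -> ComparisonResult:
    """Cross-tabulate two classification sets on their shared variants.

    Keys present on one side only are reported (``only_in_a``/``only_in_b``)
    and excluded from all rates. Per-cluster concordance for cluster c is
    |A=c and B=c| / |A=c|, with side A as the reference. Discordant pairs
    keep the original five-tier values regardless of the chosen system.
    """
    shared = sorted(set(set_a) & set(set_b))
    if not shared:
        raise ComparisonError("the two classification sets share no variants")
    labels = list(FIVE_TIER_LABELS if system == "five" else THREE_TIER_LABELS)
    if system not in ("five", "three"):
        raise ComparisonError(f"unknown tier system {system!r}")

    a5 = {k: _coerce(set_a[k], "A", k) for k in shared}
    b5 = {k: _coerce(set_b[k], "B", k) for k in shared}
    a_lab = {k: map_tier(a5[k], system) for k in shared}
    b_lab = {k: map_tier(b5[k], system) for k in shared}

    matrix = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for k in shared:
        matrix.loc[a_lab[k], b_lab[k]] += 1

    n_total = len(shared)
    diagonal = sum(matrix.loc[lab, lab] for lab in labels)
    per_cluster = {}
    for lab in labels:
        denom = matrix.loc[lab].sum()
        if denom:
            per_cluster[lab] = matrix.loc[lab, lab] / denom

    discordant = tuple(
        (k, a5[k], b5[k]) for k in shared if a_lab[k] != b_lab[k]
    )
    impact = tuple(
        k for k, ta, tb in discordant
        if (pole(ta) == "pathogenic") != (pole(tb) == "pathogenic")
    )
    return ComparisonResult(
        system=system,
        matrix=matrix,
        n_total=n_total,
        overall_concordance=diagonal / n_total,
        per_cluster_concordance=per_cluster,
        discordant_pairs=discordant,
        decision_impact_variants=impact,
        only_in_a=tuple(sorted(set(set_a) - set(set_b))),
        only_in_b=tuple(sorted(set(set_b) - set(set_a))),
    )


def decision_impact(result: ComparisonResult) -> list[str]:
    """Discordant variants where exactly one side calls the P/LP pole.

    These are the disagreements that would change patient management.
    Requires a five-tier comparison so pole membership is unambiguous.
    """
    if result.system != "five":
        raise ComparisonError("decision impact is defined on the five-tier system")
    return [
        k for k, ta, tb in result.discordant_pairs
        if (pole(ta) == "pathogenic") != (pole(tb) == "pathogenic")
    ]


def read_classification_set(path) -> dict[str, Tier]:
    """Read a TSV with columns variant_key, tier into a comparison-ready map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "variant_key" not in df.columns or "tier" not in df.columns:
        raise ComparisonError("classification set needs 'variant_key' and 'tier' columns")
    out: dict[str, Tier] = {}
    for row in df.itertuples(index=False):
        out[row.variant_key] = _coerce(row.tier, "set", row.variant_key)
    return out
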