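"""Independent brute-force oracle for the ACMG combining rules.

The guideline's clause list is enumerated literally, one predicate per
published clause, kept deliberately separate from the package's composed
boolean implementation so the two can disagree.
"""

from brcakit.tiers import Tier

# Pathogenic: (i) 1 PVS + (>=1 PS | >=2 PM | 1 PM + 1 PP | >=2 PP);
# (ii) >=2 PS; (iii) 1 PS + (>=3 PM | 2 PM + >=2 PP | 1 PM + >=4 PP)
PATHOGENIC_CLAUSES = [
    lambda n: n["PVS"] >= 1 and n["PS"] >= 1,
    lambda n: n["PVS"] >= 1 and n["PM"] >= 2,
    lambda n: n["PVS"] >= 1 and n["PM"] >= 1 and n["PP"] >= 1,
    lambda n: n["PVS"] >= 1 and n["PP"] >= 2,
    lambda n: n["PS"] >= 2,
    lambda n: n["PS"] == 1 and n["PM"] >= 3,
    lambda n: n["PS"] == 1 and n["PM"] >= 2 and n["PP"] >= 2,
    lambda n: n["PS"] == 1 and n["PM"] >= 1 and n["PP"] >= 4,
]

# Likely pathogenic: 1 PVS + 1 PM; 1 PS + 1-2 PM; 1 PS + >=2 PP;
# >=3 PM; 2 PM + >=2 PP; 1 PM + >=4 PP
LIKELY_PATHOGENIC_CLAUSES = [
    lambda n: n["PVS"] >= 1 and n["PM"] == 1,
    lambda n: n["PS"] == 1 and n["PM"] in (1, 2),
    lambda n: n["PS"] == 1 and n["PP"] >= 2,
    lambda n: n["PM"] >= 3,
    lambda n: n["PM"] == 2 and n["PP"] >= 2,
    lambda n: n["PM"] == 1 and n["PP"] >= 4,
]

BENIGN_CLAUSES = [
    lambda n: n["BA"] >= 1,
    lambda n: n["BS"] >= 2,
]

LIKELY_BENIGN_CLAUSES = [
    lambda n: n["BS"] == 1 and n["BP"] >= 1,
    lambda n: n["BP"] >= 2,
]


def oracle_combine(counts):
    """Return (tier, conflict_flag) for a category-count vector."""
    n = {k: counts.get(k, 0) for k in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")}
    pathogenic = any(c(n) for c in PATHOGENIC_CLAUSES)
    likely_pathogenic = any(c(n) for c in LIKELY_PATHOGENIC_CLAUSES)
    benign = any(c(n) for c in BENIGN_CLAUSES)
    likely_benign = any(c(n) for c in LIKELY_BENIGN_CLAUSES)
    if (pathogenic or likely_pathogenic) and (benign or likely_benign):
        return Tier.VUS, True
    if pathogenic:
        return Tier.PATHOGENIC, False
    if likely_pathogenic:
        return Tier.LIKELY_PATHOGENIC, False
    if benign:
        return Tier.BENIGN, False
    if likely_benign:
        return Tier.LIKELY_BENIGN, False
    return Tier.VUS, False


#: Count bounds used for exhaustive enumeration.
BOUNDS = {"PVS": 1, "PS": 4, "PM": 6, "PP": 5, "BA": 1, "BS": 4, "BP": 7}


def all_count_vectors():
    import itertools

    cats = list(BOUNDS)
    for combo in itertools.product(*(range(BOUNDS[c] + 1) for c in cats)):
        yield dict(zip(cats, combo))
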