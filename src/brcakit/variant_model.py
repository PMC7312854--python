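"""Variant identity, HGVS parsing, and coordinate mapping for BRCA1/2.

The two genes are interpreted against fixed RefSeq transcript models
(BRCA1 NM_007294.3 on the minus strand of chr17, BRCA2 NM_000059.3 on the
plus strand of chr13), shipped as a GRCh37 JSON asset with this package.
Coding (c.) positions are mapped to genomic (g.) positions and back purely
from the exon structure; protein consequences are *classified* from supplied
HGVS p. strings, never recomputed from genome sequence, so no reference
FASTA is required anywhere.

Coordinates are 1-based inclusive throughout (HGVS/VCF convention).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from functools import cached_property
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "HgvsParseError",
    "CoordinateError",
    "ConsistencyError",
    "Consequence",
    "TranscriptModel",
    "CdnaChange",
    "Variant",
    "load_transcript_models",
    "parse_cdna",
    "map_c_to_g",
    "map_g_to_c",
    "classify_consequence",
    "build_variant",
    "read_variant_table",
    "read_vcf",
    "write_vcf",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: chromosome -> gene symbol (GRCh37, chr prefix stripped)
CHROM_TO_GENE = {"17": "BRCA1", "13": "BRCA2"}

#: GRCh37 chromosome lengths, used only for VCF header contig lines.
_CHROM_LENGTHS = {"13": 115169878, "17": 81195210}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class HgvsParseError(ValueError):
    """Malformed or unsupported HGVS expression."""


class CoordinateError(ValueError):
    """Position outside the transcript model."""


class ConsistencyError(ValueError):
    """Contradictory c. / p. pair."""


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    CANONICAL_SPLICE = "canonical_splice"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


@dataclass(frozen=True)
class CodingSegment:
    """One exon's coding slice, in transcript order.

    ``c_start..c_end`` are CDS coordinates; ``g_start..g_end`` the matching
    genomic interval (always ascending, regardless of strand).
    """

    c_start: int
    c_end: int
    g_start: int
    g_end: int


@dataclass(frozen=True)
class TranscriptModel:
    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # ascending genomic, 1-based inclusive
    cds_g_start: int
    cds_g_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exs, exs[1:]):
            if e1 >= s2:
                raise ValueError("exons overlap or are unordered")

    @cached_property
    def coding_segments(self) -> tuple[CodingSegment, ...]:
        """Coding slices of each exon, ordered 5'->3' along the transcript."""
        exs = sorted(self.exons)
        ordered = exs if self.strand == "+" else list(reversed(exs))
        segs: list[CodingSegment] = []
        c = 1
        for gs, ge in ordered:
            lo = max(gs, self.cds_g_start)
            hi = min(ge, self.cds_g_end)
            if lo > hi:
                continue
            length = hi - lo + 1
            segs.append(CodingSegment(c, c + length - 1, lo, hi))
            c += length
        return tuple(segs)

    @property
    def cds_length(self) -> int:
        return self.coding_segments[-1].c_end

    @property
    def last_exon_c_start(self) -> int:
        """First CDS position that lies in the transcript's final exon."""
        return self.coding_segments[-1].c_start

    @property
    def g_span(self) -> tuple[int, int]:
        exs = sorted(self.exons)
        return exs[0][0], exs[-1][1]

    def c_to_g(self, c: int) -> int:
        for seg in self.coding_segments:
            if seg.c_start <= c <= seg.c_end:
                off = c - seg.c_start
                return seg.g_start + off if self.strand == "+" else seg.g_end - off
        raise CoordinateError(
            f"c.{c} outside the CDS of {self.transcript_id} (1..{self.cds_length})"
        )

    def g_to_c(self, g: int) -> int:
        for seg in self.coding_segments:
            if seg.g_start <= g <= seg.g_end:
                if self.strand == "+":
                    return seg.c_start + (g - seg.g_start)
                return seg.c_start + (seg.g_end - g)
        raise CoordinateError(
            f"g.{g} is intronic or outside the coding exons of {self.transcript_id}"
        )

    def in_last_exon(self, c: int) -> bool:
        return self.coding_segments[-1].c_start <= c <= self.cds_length


def load_transcript_models() -> dict[str, TranscriptModel]:
    """Load the packaged GRCh37 transcript models for BRCA1 and BRCA2."""
    text = (resources.files("brcakit") / "data" / "transcripts_grch37.json").read_text()
    raw = json.loads(text)
    models = {}
    for gene, d in raw.items():
        models[gene] = TranscriptModel(
            gene_symbol=d["gene_symbol"],
            transcript_id=d["transcript_id"],
            chrom=d["chrom"],
            strand=d["strand"],
            exons=tuple((int(a), int(b)) for a, b in d["exons"]),
            cds_g_start=int(d["cds_g_start"]),
            cds_g_end=int(d["cds_g_end"]),
        )
    return models


# ---------------------------------------------------------------------------
# HGVS c. parsing
# ---------------------------------------------------------------------------

_C_SUB = re.compile(r"^c\.(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_C_DELDUP = re.compile(r"^c\.(\d+)([+-]\d+)?(?:_(\d+)([+-]\d+)?)?(delins|del|dup)([ACGT]*)$")
_C_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


@dataclass(frozen=True)
class CdnaChange:
    kind: str  # sub | del | dup | ins | delins
    start: int
    end: int
    offset: int  # intronic offset at the start position, 0 if exonic
    ref: Optional[str]
    alt: Optional[str]

    @property
    def ref_span(self) -> int:
        """Number of reference bases affected (0 for pure insertions)."""
        return 0 if self.kind == "ins" else self.end - self.start + 1

    @property
    def frame_shift(self) -> int:
        """Net change in coding length; nonzero %3 means frameshifting."""
        if self.kind == "sub":
            return 0
        if self.kind == "del":
            return -self.ref_span
        if self.kind == "dup":
            return self.ref_span
        if self.kind == "ins":
            return len(self.alt or "")
        return len(self.alt or "") - self.ref_span  # delins


def _normalize_c(hgvs_c: str) -> str:
    s = hgvs_c.strip()
    if ":" in s:  # tolerate "NM_007294.3:c.4957G>T"
        s = s.rsplit(":", 1)[1]
    if not s.startswith("c."):
        s = "c." + s
    return s


def parse_cdna(hgvs_c: str) -> CdnaChange:
    """Parse a coding HGVS expression (substitutions and small indels)."""
    s = _normalize_c(hgvs_c)
    m = _C_SUB.match(s)
    if m:
        pos, off, ref, alt = m.groups()
        if ref == alt:
            raise HgvsParseError(f"{hgvs_c!r}: ref and alt are identical")
        return CdnaChange("sub", int(pos), int(pos), int(off or 0), ref, alt)
    m = _C_DELDUP.match(s)
    if m:
        p1, off1, p2, off2, kind, seq = m.groups()
        start, end = int(p1), int(p2 or p1)
        if end < start:
            raise HgvsParseError(f"{hgvs_c!r}: end before start")
        if kind == "delins" and not seq:
            raise HgvsParseError(f"{hgvs_c!r}: delins requires an inserted sequence")
        ref = seq if kind in ("del", "dup") and seq else None
        alt = seq if kind == "delins" else None
        return CdnaChange(kind, start, end, int(off1 or 0), ref, alt)
    m = _C_INS.match(s)
    if m:
        p1, p2, seq = m.groups()
        return CdnaChange("ins", int(p1), int(p2), 0, None, seq)
    raise HgvsParseError(f"cannot parse HGVS c. expression {hgvs_c!r}")


def map_c_to_g(
    transcript: TranscriptModel, hgvs_c: str
) -> tuple[int, Optional[str], Optional[str]]:
    """Map a coding HGVS change to GRCh37 genomic coordinates.

    For substitutions, ref/alt are reverse-complemented on the minus strand.
    Deletions/duplications with an explicit sequence return
    ``(leftmost_g, deleted_seq, "")`` / ``(leftmost_g, "", dup_seq)``;
    without a sequence the bases are None (no reference genome is consulted).
    Intronic positions raise :class:`CoordinateError`.
    """
    ch = parse_cdna(hgvs_c)
    if ch.offset:
        raise CoordinateError(f"{hgvs_c!r} is intronic; only exonic changes map")
    minus = transcript.strand == "-"
    if ch.kind == "sub":
        g = transcript.c_to_g(ch.start)
        ref, alt = ch.ref, ch.alt
        if minus:
            ref, alt = revcomp(ref), revcomp(alt)
        return g, ref, alt
    g1 = transcript.c_to_g(ch.start)
    g2 = transcript.c_to_g(ch.end)
    g_lo = min(g1, g2)
    seq = ch.ref if ch.kind in ("del", "dup") else ch.alt
    if seq is not None and minus:
        seq = revcomp(seq)
    if ch.kind == "del":
        return g_lo, seq, "" if seq is not None else None
    if ch.kind == "dup":
        return g_lo, "" if seq is not None else None, seq
    return g_lo, None, seq  # ins / delins: ref unknown without genome sequence


def map_g_to_c(
    transcript: TranscriptModel, g_pos: int, g_ref: str, g_alt: str
) -> str:
    """Inverse of :func:`map_c_to_g` for single-nucleotide substitutions."""
    if len(g_ref) != 1 or len(g_alt) != 1 or g_ref == g_alt:
        raise HgvsParseError("map_g_to_c handles single-base substitutions only")
    c = transcript.g_to_c(g_pos)
    ref, alt = g_ref.upper(), g_alt.upper()
    if transcript.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    return f"c.{c}{ref}>{alt}"


# ---------------------------------------------------------------------------
# Protein consequence classification
# ---------------------------------------------------------------------------

_AA3 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}

_P_SUB = re.compile(r"^([A-Z][a-z]{2}|[A-Z\*])(\d+)([A-Z][a-z]{2}|[A-Z\*=])$")
_P_RES = re.compile(r"(\d+)")


def _aa1(token: str) -> str:
    if token in _AA3:
        return _AA3[token]
    if len(token) == 1:
        return token
    raise HgvsParseError(f"unknown amino-acid token {token!r}")


def _normalize_p(hgvs_p: str) -> str:
    s = hgvs_p.strip()
    if ":" in s:
        s = s.rsplit(":", 1)[1]
    if s.startswith("p."):
        s = s[2:]
    return s.strip("()")


def _p_implies_coding_change(p: str) -> bool:
    if "=" in p:
        return False
    return bool(_P_SUB.match(p)) or any(t in p for t in ("fs", "del", "dup", "ins", "*", "Ter"))


def classify_consequence(
    hgvs_c: Optional[str],
    hgvs_p: Optional[str],
    transcript: TranscriptModel,
) -> tuple[Consequence, bool]:
    """Classify a variant's consequence from its HGVS strings.

    Returns ``(consequence, last_exon_truncation)``. The second flag is True
    only for truncating consequences (frameshift / nonsense) whose first
    affected CDS position lies in the transcript's final exon — such
    truncations may escape nonsense-mediated decay.

    The classification is a pure function of the string grammar and the
    last-exon boundary; no sequence is consulted.
    """
    if not hgvs_c and not hgvs_p:
        raise HgvsParseError("need at least one of hgvs_c / hgvs_p")

    cd: Optional[CdnaChange] = None
    if hgvs_c:
        cd = parse_cdna(hgvs_c)
        if cd.offset != 0:
            if abs(cd.offset) <= 2:
                if hgvs_p and _p_implies_coding_change(_normalize_p(hgvs_p)):
                    raise ConsistencyError(
                        f"{hgvs_c!r} is a canonical splice-site change but "
                        f"{hgvs_p!r} asserts a protein change"
                    )
                return Consequence.CANONICAL_SPLICE, False
            return Consequence.OTHER, False

    def _truncation_start() -> Optional[int]:
        if cd is not None:
            return cd.start
        if hgvs_p:
            m = _P_RES.search(_normalize_p(hgvs_p))
            if m:
                return 3 * int(m.group(1)) - 2
        return None

    def _last_exon(cons: Consequence) -> bool:
        c0 = _truncation_start()
        return c0 is not None and transcript.in_last_exon(c0)

    if hgvs_p:
        p = _normalize_p(hgvs_p)
        if "fs" in p:
            return Consequence.FRAMESHIFT, _last_exon(Consequence.FRAMESHIFT)
        if p == "=" or p.endswith("="):
            return Consequence.SYNONYMOUS, False
        m = _P_SUB.match(p)
        if m:
            ref, _res, alt = m.groups()
            if alt == "=":
                return Consequence.SYNONYMOUS, False
            r1, a1 = _aa1(ref), _aa1(alt)
            if a1 == "*":
                return Consequence.NONSENSE, _last_exon(Consequence.NONSENSE)
            if r1 == a1:
                return Consequence.SYNONYMOUS, False
            if cd is not None and cd.kind != "sub" and cd.frame_shift % 3 != 0:
                raise ConsistencyError(
                    f"{hgvs_c!r} shifts the frame but {hgvs_p!r} is a substitution"
                )
            return Consequence.MISSENSE, False
        if any(t in p for t in ("del", "dup", "ins")):
            if cd is not None and cd.kind != "sub":
                if cd.frame_shift % 3 == 0:
                    return Consequence.INFRAME_INDEL, False
                return Consequence.FRAMESHIFT, _last_exon(Consequence.FRAMESHIFT)
            return Consequence.INFRAME_INDEL, False
        return Consequence.OTHER, False

    # c.-only path
    assert cd is not None
    if cd.kind == "sub":
        return Consequence.OTHER, False  # missense vs synonymous undecidable
    if cd.frame_shift % 3 == 0:
        return Consequence.INFRAME_INDEL, False
    return Consequence.FRAMESHIFT, _last_exon(Consequence.FRAMESHIFT)


# ---------------------------------------------------------------------------
# Variant container and readers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """One biallelic BRCA1/2 allele with genomic and transcript identity."""

    gene_symbol: str
    chrom: str
    g_pos: int
    g_ref: Optional[str]
    g_alt: Optional[str]
    hgvs_g: str
    hgvs_c: str
    hgvs_p: Optional[str]
    rsid: Optional[str]
    consequence: Consequence
    last_exon_truncation: bool

    def __post_init__(self) -> None:
        if self.g_ref is not None and self.g_alt is not None and self.g_ref == self.g_alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> str:
        """Canonical lookup key: gene + normalized c. expression."""
        return f"{self.gene_symbol}:{_normalize_c(self.hgvs_c)}"

    @property
    def sort_key(self) -> tuple[int, int, str]:
        return int(self.chrom), self.g_pos, self.g_alt or ""


def build_variant(
    gene_symbol: str,
    hgvs_c: str,
    hgvs_p: Optional[str] = None,
    rsid: Optional[str] = None,
    models: Optional[Mapping[str, TranscriptModel]] = None,
) -> Variant:
    """Construct a Variant from gene + HGVS strings against the packaged models."""
    models = models or load_transcript_models()
    if gene_symbol not in models:
        raise CoordinateError(f"no transcript model for gene {gene_symbol!r}")
    tm = models[gene_symbol]
    hgvs_c = _normalize_c(hgvs_c)
    cons, last_exon = classify_consequence(hgvs_c, hgvs_p, tm)
    cd = parse_cdna(hgvs_c)
    if cd.offset != 0:
        g_anchor = tm.c_to_g(cd.start)
        g_pos = g_anchor + cd.offset if tm.strand == "+" else g_anchor - cd.offset
        g_ref = g_alt = None
        if cd.kind == "sub":
            r, a = (revcomp(cd.ref), revcomp(cd.alt)) if tm.strand == "-" else (cd.ref, cd.alt)
            g_ref, g_alt = r, a
            hgvs_g = f"g.{g_pos}{r}>{a}"
        else:
            hgvs_g = f"g.{g_pos}{cd.kind}"
    elif cd.kind == "sub":
        g_pos, g_ref, g_alt = map_c_to_g(tm, hgvs_c)
        hgvs_g = f"g.{g_pos}{g_ref}>{g_alt}"
    else:
        g1, g2 = tm.c_to_g(cd.start), tm.c_to_g(cd.end)
        g_lo, g_hi = min(g1, g2), max(g1, g2)
        g_pos, g_ref, g_alt = g_lo, None, None
        span = f"{g_lo}" if g_lo == g_hi else f"{g_lo}_{g_hi}"
        hgvs_g = f"g.{span}{cd.kind}" + (cd.alt or "")
    return Variant(
        gene_symbol=gene_symbol,
        chrom=tm.chrom,
        g_pos=g_pos,
        g_ref=g_ref,
        g_alt=g_alt,
        hgvs_g=hgvs_g,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p or None,
        rsid=rsid or None,
        consequence=cons,
        last_exon_truncation=last_exon,
    )


def read_variant_table(
    path,
    models: Optional[Mapping[str, TranscriptModel]] = None,
) -> tuple[list[Variant], list[tuple[int, str]]]:
    """Read a TSV with columns gene, hgvs_c[, hgvs_p, rsid].

    Returns (variants, skipped) where skipped holds (row_number, reason)
    for rows that failed to parse; extra columns are ignored.
    """
    import pandas as pd

    models = models or load_transcript_models()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene" not in df.columns or "hgvs_c" not in df.columns:
        raise HgvsParseError("variant table needs 'gene' and 'hgvs_c' columns")
    variants: list[Variant] = []
    skipped: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            variants.append(
                build_variant(
                    getattr(row, "gene"),
                    getattr(row, "hgvs_c"),
                    getattr(row, "hgvs_p", "") or None,
                    getattr(row, "rsid", "") or None,
                    models,
                )
            )
        except (ValueError, KeyError) as exc:
            skipped.append((i, str(exc)))
    return variants, skipped


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_vcf(
    path,
    models: Optional[Mapping[str, TranscriptModel]] = None,
) -> tuple[list[Variant], list[tuple[str, str]]]:
    """Read a VCF 4.x file; multi-allelic records are split into biallelic
    variants. Optional INFO keys GENE/HGVSC/HGVSP and the ID column (rsid)
    are used when present; otherwise substitutions are mapped from the
    genomic coordinates.

    Returns (variants, skipped) with (record_id, reason) for skipped records.
    """
    import pysam

    models = models or load_transcript_models()
    by_chrom = {models[g].chrom: models[g] for g in models}
    variants: list[Variant] = []
    skipped: list[tuple[str, str]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            chrom = _norm_chrom(rec.chrom)
            label = f"{rec.chrom}:{rec.pos}"
            tm = by_chrom.get(chrom)
            if tm is None:
                skipped.append((label, f"chromosome {rec.chrom} is not BRCA1/2"))
                continue
            lo, hi = tm.g_span
            if not (lo <= rec.pos <= hi):
                skipped.append((label, "position outside the transcript span"))
                continue
            info = dict(rec.info)
            for alt in rec.alts or ():
                try:
                    hgvs_c = info.get("HGVSC")
                    hgvs_p = info.get("HGVSP")
                    if hgvs_c:
                        v = build_variant(
                            tm.gene_symbol, str(hgvs_c), hgvs_p and str(hgvs_p),
                            rec.id, models,
                        )
                        # keep the VCF's own alleles (indel anchors etc.)
                        v = Variant(
                            v.gene_symbol, v.chrom, rec.pos, rec.ref, alt,
                            v.hgvs_g, v.hgvs_c, v.hgvs_p, v.rsid,
                            v.consequence, v.last_exon_truncation,
                        )
                    else:
                        hgvs_c = map_g_to_c(tm, rec.pos, rec.ref, alt)
                        cons, last_exon = classify_consequence(hgvs_c, None, tm)
                        v = Variant(
                            tm.gene_symbol, tm.chrom, rec.pos, rec.ref, alt,
                            f"g.{rec.pos}{rec.ref}>{alt}", hgvs_c, None, rec.id,
                            cons, last_exon,
                        )
                    variants.append(v)
                except (ValueError, KeyError) as exc:
                    skipped.append((label, str(exc)))
    return variants, skipped


def write_vcf(path, variants: Sequence[Variant]) -> None:
    """Write variants as an uncompressed VCF 4.2 file (sorted by coordinate)."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in sorted(_CHROM_LENGTHS):
        header.contigs.add(chrom, length=_CHROM_LENGTHS[chrom])
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("HGVSC", 1, "String", "Transcript-level HGVS")
    header.info.add("HGVSP", 1, "String", "Protein-level HGVS")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: x.sort_key):
            ref = v.g_ref if v.g_ref else "N"
            alt = v.g_alt if v.g_alt else "<DEL>"
            rec = out.new_record(
                contig=v.chrom, start=v.g_pos - 1, alleles=(ref, alt), id=v.rsid
            )
            rec.info["GENE"] = v.gene_symbol
            rec.info["HGVSC"] = v.hgvs_c
            if v.hgvs_p:
                rec.info["HGVSP"] = v.hgvs_p
            out.write(rec)
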