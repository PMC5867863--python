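"""Class-code comparison of assembled transcripts against a reference.

Each query transcript receives exactly one code describing its
structural relation to the reference annotation, evaluated against
every reference transcript whose span intersects the query and
resolved by a most-specific-first precedence:

    "="  identical ordered intron chain, same strand
    "c"  exon chain contained in a reference transcript, compatible
         intron chain, same strand
    "j"  shares at least one exact intron (splice junction pair) with a
         same-strand reference transcript
    "e"  single-exon query with same-strand exonic overlap
    "o"  multi-exon query with same-strand exonic overlap but no shared
         junction
    "i"  query span entirely within one intron of a reference
         transcript (the strand relation is recorded separately)
    "x"  exonic overlap with the reference on the opposite strand only
    "u"  intergenic: no span intersection with any reference transcript

Unstranded queries (strand ".") are evaluated in both orientations and
keep the more specific verdict; they can never be called "x".
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from lncweanflow.annotation_io import Annotation, TranscriptModel

logger = logging.getLogger(__name__)

CODE_PRECEDENCE = ["=", "c", "j", "e", "o", "i", "x", "u"]
_RANK = {c: i for i, c in enumerate(CODE_PRECEDENCE)}

#: codes that count as matching a known transcript (known/novel call)
KNOWN_CODES = {"=", "c", "j"}
#: codes the discovery cascade retains as lncRNA candidates
RETAINED_CODES = {"i", "u", "x"}


@dataclass(frozen=True)
class ClassCode:
    """Comparison verdict for one query transcript.

    ``ref_transcript_id`` names the best-matching reference transcript;
    it is ``None`` for "u" (no overlap) and "i" (the relation is to an
    intron, not a transcript structure — the strand relation to the
    enclosing transcript is kept in ``strand_relation``).
    """

    code: str
    ref_transcript_id: str | None = None
    strand_relation: str | None = None  # same | opposite | unknown

    def __post_init__(self):
        if self.code not in CODE_PRECEDENCE and self.code != "s":
            raise ValueError(f"unknown class code {self.code!r}")
        if self.code in ("u", "i") and self.ref_transcript_id is not None:
            raise ValueError(f'code "{self.code}" carries no ref_transcript_id')


def _same_strand(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def _exonic_overlap(q: TranscriptModel, r: TranscriptModel) -> bool:
    return any(qe.start <= re_.end and re_.start <= qe.end for qe in q.exons for re_ in r.exons)


def _contained(q: TranscriptModel, r: TranscriptModel) -> bool:
    """Exon-resolution containment with compatible intron chain."""
    qs, qe = q.span
    rs, re_ = r.span
    if qs < rs or qe > re_:
        return False
    for ex in q.exons:
        if not any(rx.start <= ex.start and ex.end <= rx.end for rx in r.exons):
            return False
    qi = q.introns
    if not qi:
        return True
    ri = r.introns
    # query introns must appear as a contiguous run of the reference chain
    for off in range(len(ri) - len(qi) + 1):
        if ri[off : off + len(qi)] == qi:
            return True
    return False


def _within_intron(q: TranscriptModel, r: TranscriptModel) -> bool:
    qs, qe = q.span
    return any(s <= qs and qe <= e for s, e in r.introns)


def _relation_rank(q: TranscriptModel, r: TranscriptModel) -> tuple[str | None, str]:
    """Most specific relation of q to one reference transcript.

    Returns (code or None, strand_relation).
    """
    if q.chrom != r.chrom:
        return None, "unknown"
    qs, qe = q.span
    rs, re_ = r.span
    if qe < rs or re_ < qs:
        return None, "unknown"
    same = _same_strand(q.strand, r.strand)
    relation = "unknown" if "." in (q.strand, r.strand) else ("same" if same else "opposite")
    if same:
        if q.introns and q.introns == r.introns:
            return "=", relation
        if not q.introns and not r.introns and _exonic_overlap(q, r):
            return "=", relation
        if _contained(q, r):
            return "c", relation
        if q.introns and set(q.introns) & set(r.introns):
            return "j", relation
        if _exonic_overlap(q, r):
            return ("e" if q.n_exons == 1 else "o"), relation
        if _within_intron(q, r):
            return "i", relation
        return None, relation
    # opposite strand
    if _within_intron(q, r):
        return "i", relation
    if _exonic_overlap(q, r):
        return "x", relation
    return None, relation


def assign_class_code(query: TranscriptModel, reference: Annotation) -> ClassCode:
    """Assign the single most specific class code for ``query``.

    Deterministic and independent of reference ordering: candidates are
    ranked by code precedence, then by reference transcript id.
    """
    if not query.exons:
        raise ValueError(f"query {query.transcript_id} has no exons")
    qs, qe = query.span
    if query.chrom not in reference.chromosomes():
        logger.warning(
            "query %s on chromosome %s absent from reference; calling it intergenic",
            query.transcript_id,
            query.chrom,
        )
        return ClassCode("u")
    candidates: list[tuple[int, str, str, str]] = []
    for r in reference.overlapping_transcripts(query.chrom, qs, qe):
        code, relation = _relation_rank(query, r)
        if code is not None:
            candidates.append((_RANK[code], code, r.transcript_id, relation))
    if not candidates:
        return ClassCode("u")
    rank, code, ref_id, relation = min(candidates, key=lambda c: (c[0], c[2]))
    if code in ("u", "i"):
        return ClassCode(code, None, relation)
    return ClassCode(code, ref_id, relation)


def compare_set(queries: Annotation, reference: Annotation) -> dict[str, ClassCode]:
    """Class code for every query transcript; logs per-code counts."""
    out = {t.transcript_id: assign_class_code(t, reference) for t in queries.transcripts()}
    counts = Counter(cc.code for cc in out.values())
    logger.info("class code summary: %s", dict(sorted(counts.items())))
    return out


def codes_to_table(codes: dict[str, ClassCode]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": list(codes),
            "class_code": [codes[t].code for t in codes],
            "ref_id": [codes[t].ref_transcript_id or "" for t in codes],
            "strand_relation": [codes[t].strand_relation or "" for t in codes],
        }
    )
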