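"""The lncRNA discovery cascade and survivor characterization.

Cascade order is fixed: mature length > 200 bp, then class code in
{"i", "u", "x"} against the protein-coding + other-ncRNA reference,
then the coding-potential gate, then known/novel assignment against a
known-lncRNA reference ("=", "c" or "j" means known), then positional
classification into 11 mutually exclusive genomic-location classes.
Every input transcript leaves the cascade with a complete filter
trace; filters after the first failure are recorded "not_evaluated".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from lncweanflow.annotation_io import Annotation, GeneModel, TranscriptModel
from lncweanflow.coding import (
    CodingPotential,
    GateThresholds,
    LogisticCombiner,
    gate_failures,
    score_transcript,
)
from lncweanflow.compare import KNOWN_CODES, RETAINED_CODES, ClassCode, assign_class_code

logger = logging.getLogger(__name__)

FILTER_ORDER = ("length", "class_code", "coding_gate")

POSITIONAL_CLASSES = (
    "containing_gene",
    "sense_exonic",
    "antisense_exonic",
    "sense_intronic",
    "antisense_intronic",
    "bidirectional_promoter",
    "intergenic_upstream_1kb",
    "intergenic_downstream_1kb",
    "intergenic_same",
    "intergenic_divergent",
    "intergenic_convergent",
)

LENGTH_BINS = ((200, 999), (1000, 2499), (2500, 4999), (5000, 9999), (10000, None))


@dataclass
class LncRNACandidate:
    """One assembled transcript's passage through the cascade."""

    transcript: TranscriptModel
    filter_trace: list[tuple[str, str]] = field(default_factory=list)
    class_code_vs_mrna: ClassCode | None = None
    class_code_vs_known_lnc: ClassCode | None = None
    coding: CodingPotential | None = None
    known: bool | None = None
    positional_class: str | None = None

    @property
    def retained(self) -> bool:
        return all(v == "pass" for _, v in self.filter_trace) and bool(self.filter_trace)


def discover(
    assembled: Annotation,
    reference: Annotation,
    known_lnc: Annotation,
    seqs: dict[str, str],
    external_scores: dict[str, dict[str, float]] | None = None,
    blast: dict[str, float] | None = None,
    min_length: int = 201,
    thresholds: GateThresholds = GateThresholds(),
    coding_table=None,
    noncoding_table=None,
    combiner: LogisticCombiner | None = None,
) -> list[LncRNACandidate]:
    """Run the full cascade over every assembled transcript.

    ``external_scores`` may carry "cnci" and/or "cpat" maps of
    transcript id to score; when present they govern the gate,
    otherwise the built-in combiner (``combiner`` plus the two hexamer
    tables) supplies the combined probability. A survivor candidate
    with no sequence fails the coding gate with reason "no_sequence".
    The comparison reference is restricted to protein-coding and
    other-ncRNA biotypes before class codes are assigned.
    """
    external_scores = external_scores or {}
    cnci_scores = external_scores.get("cnci", {})
    cpat_scores = external_scores.get("cpat", {})
    blast = blast or {}
    compare_ref = reference.subset({"protein_coding", "other_ncRNA"})
    mrna_ref = reference.subset({"protein_coding"})
    use_builtin = combiner is not None and coding_table is not None
    candidates = []
    for tx in assembled.transcripts():
        cand = LncRNACandidate(tx)
        candidates.append(cand)

        if tx.length < min_length:
            cand.filter_trace.append(("length", "fail"))
            cand.filter_trace.extend((f, "not_evaluated") for f in FILTER_ORDER[1:])
            continue
        cand.filter_trace.append(("length", "pass"))

        cand.class_code_vs_mrna = assign_class_code(tx, compare_ref)
        if cand.class_code_vs_mrna.code not in RETAINED_CODES:
            cand.filter_trace.append(("class_code", "fail"))
            cand.filter_trace.extend((f, "not_evaluated") for f in FILTER_ORDER[2:])
            continue
        cand.filter_trace.append(("class_code", "pass"))

        seq = seqs.get(tx.transcript_id)
        has_external = tx.transcript_id in cnci_scores or tx.transcript_id in cpat_scores
        if seq is None and not has_external:
            logger.warning("no sequence for %s; failing coding gate", tx.transcript_id)
            cand.filter_trace.append(("coding_gate", "fail:no_sequence"))
            continue
        cand.coding = _gather_coding_evidence(
            tx, seq, cnci_scores, cpat_scores, blast,
            coding_table, noncoding_table, combiner if use_builtin else None,
        )
        failures = gate_failures(cand.coding, thresholds)
        if failures:
            cand.filter_trace.append(("coding_gate", "fail:" + ",".join(failures)))
            continue
        cand.filter_trace.append(("coding_gate", "pass"))

        cand.class_code_vs_known_lnc = assign_class_code(tx, known_lnc)
        cand.known = cand.class_code_vs_known_lnc.code in KNOWN_CODES
        cand.positional_class = positional_classify(tx, mrna_ref)
    n_kept = sum(c.retained for c in candidates)
    logger.info("cascade: %d/%d transcripts retained as lncRNA", n_kept, len(candidates))
    return candidates


def _gather_coding_evidence(
    tx: TranscriptModel,
    seq: str | None,
    cnci_scores,
    cpat_scores,
    blast,
    coding_table,
    noncoding_table,
    combiner: LogisticCombiner | None,
) -> CodingPotential:
    strand = "both" if tx.strand == "." else "+"
    if seq is not None and combiner is not None:
        cp = score_transcript(
            tx.transcript_id, seq, coding_table, noncoding_table, combiner, strand
        )
    elif seq is not None:
        from lncweanflow.coding import find_longest_orf

        cp = CodingPotential(tx.transcript_id, orf=find_longest_orf(seq, strand))
    else:
        cp = CodingPotential(tx.transcript_id)
    cp.cnci_score = cnci_scores.get(tx.transcript_id)
    cp.cpat_score = cpat_scores.get(tx.transcript_id)
    cp.min_evalue = blast.get(tx.transcript_id)
    return cp


def _orientation(left_strand: str, right_strand: str) -> str:
    """Orientation class for two disjoint neighbors, left/right on the chromosome."""
    if "." in (left_strand, right_strand) or left_strand == right_strand:
        return "intergenic_same"
    if left_strand == "-" and right_strand == "+":
        return "intergenic_divergent"  # 5' ends face each other
    return "intergenic_convergent"  # 3' ends face each other


def _nearest_gene(tx: TranscriptModel, reference: Annotation) -> tuple[GeneModel | None, int]:
    s, e = tx.span
    # widening window queries before falling back to a chromosome scan
    for pad in (1_000, 50_000, 1_000_000):
        hits = reference.query(tx.chrom, max(1, s - pad), e + pad)
        if hits:
            break
    else:
        hits = [g for g in reference.genes.values() if g.chrom == tx.chrom]
    best, best_d = None, -1
    for g in hits:
        gs, ge = g.span
        d = 0 if (s <= ge and gs <= e) else (gs - e if gs > e else s - ge)
        if best is None or d < best_d or (d == best_d and g.gene_id < best.gene_id):
            best, best_d = g, d
    return best, best_d


def positional_classify(tx: TranscriptModel, reference: Annotation) -> str:
    """One of 11 genomic-location classes relative to protein-coding genes.

    Overlap classes take precedence (gene contained in the lncRNA,
    exonic overlap sense then antisense, intronic sense then
    antisense); disjoint placements are split at a 1 kb gap into
    near-gene classes (divergent head-to-head pairs under 1 kb are
    "bidirectional_promoter"; otherwise upstream/downstream of the
    lncRNA by its own strand) and >1 kb intergenic classes named for
    the orientation relative to the nearest gene (same strand,
    divergent, convergent). Distances are span-to-span.
    """
    s, e = tx.span
    overlapping = reference.query(tx.chrom, s, e)
    if overlapping:
        for g in overlapping:
            gs, ge = g.span
            if s <= gs and ge <= e:
                return "containing_gene"
        sense_exon = antisense_exon = sense_intron = antisense_intron = False
        for g in overlapping:
            for rt in g.transcripts:
                same = tx.strand == "." or rt.strand == "." or tx.strand == rt.strand
                exon_hit = any(
                    qe.start <= rx.end and rx.start <= qe.end
                    for qe in tx.exons
                    for rx in rt.exons
                )
                intron_hit = any(i0 <= s and e <= i1 for i0, i1 in rt.introns)
                if exon_hit:
                    sense_exon |= same
                    antisense_exon |= not same
                elif intron_hit:
                    sense_intron |= same
                    antisense_intron |= not same
        if sense_exon:
            return "sense_exonic"
        if antisense_exon:
            return "antisense_exonic"
        if sense_intron:
            return "sense_intronic"
        if antisense_intron:
            return "antisense_intronic"
        # span overlap falling between transcripts of a gene: treat as intronic
        same_any = any(
            tx.strand in (".", g.strand) or g.strand == "." for g in overlapping
        )
        return "sense_intronic" if same_any else "antisense_intronic"

    gene, gap = _nearest_gene(tx, reference)
    if gene is None:
        return "intergenic_same"  # no protein-coding neighbor on the chromosome
    gs, ge = gene.span
    gene_is_right = gs > e
    left_strand, right_strand = (
        (tx.strand, gene.strand) if gene_is_right else (gene.strand, tx.strand)
    )
    if gap <= 1_000:
        if gap < 1_000 and _orientation(left_strand, right_strand) == "intergenic_divergent":
            return "bidirectional_promoter"
        # upstream/downstream of the lncRNA, judged by the lncRNA's strand
        if tx.strand == "-":
            upstream_side_is_right = True
        else:  # "+" or unstranded: upstream is the left side
            upstream_side_is_right = False
        gene_upstream = gene_is_right == upstream_side_is_right
        return "intergenic_upstream_1kb" if gene_upstream else "intergenic_downstream_1kb"
    return _orientation(left_strand, right_strand)


def characterize(candidates: list[LncRNACandidate]) -> dict[str, pd.Series]:
    """Descriptive summaries of the retained set.

    Returns length-bin counts (bins partition the retained
    transcripts), transcripts-per-gene counts, exons-per-transcript
    counts, per-chromosome transcript counts and per-positional-class
    counts.
    """
    kept = [c for c in candidates if c.retained]
    if not kept:
        return {
            "length_bins": pd.Series(dtype=int),
            "transcripts_per_gene": pd.Series(dtype=int),
            "exons_per_transcript": pd.Series(dtype=int),
            "per_chromosome": pd.Series(dtype=int),
            "positional_classes": pd.Series(dtype=int),
        }
    bin_labels = [
        f"{lo}-{hi}" if hi is not None else f">{lo - 1}" for lo, hi in LENGTH_BINS
    ]
    bin_counts = {label: 0 for label in bin_labels}
    for c in kept:
        n = c.transcript.length
        for (lo, hi), label in zip(LENGTH_BINS, bin_labels):
            if n >= lo and (hi is None or n <= hi):
                bin_counts[label] += 1
                break
    per_gene = pd.Series([c.transcript.gene_id for c in kept]).value_counts()
    return {
        "length_bins": pd.Series(bin_counts),
        "transcripts_per_gene": per_gene.value_counts().sort_index(),
        "exons_per_transcript": pd.Series(
            [c.transcript.n_exons for c in kept]
        ).value_counts().sort_index(),
        "per_chromosome": pd.Series([c.transcript.chrom for c in kept]).value_counts().sort_index(),
        "positional_classes": pd.Series(
            [c.positional_class for c in kept]
        ).value_counts().sort_index(),
    }


def candidate_table(candidates: list[LncRNACandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        trace = ";".join(f"{name}={verdict}" for name, verdict in c.filter_trace)
        rows.append(
            {
                "transcript_id": c.transcript.transcript_id,
                "gene_id": c.transcript.gene_id,
                "chrom": c.transcript.chrom,
                "length": c.transcript.length,
                "class_code": c.class_code_vs_mrna.code if c.class_code_vs_mrna else "",
                "retained": c.retained,
                "known": "" if c.known is None else c.known,
                "positional_class": c.positional_class or "",
                "filter_trace": trace,
            }
        )
    return pd.DataFrame(rows)


def retained_annotation(candidates: list[LncRNACandidate]) -> Annotation:
    """GTF-writable Annotation of the retained lncRNA transcripts."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for c in candidates:
        if c.retained:
            by_gene.setdefault(c.transcript.gene_id, []).append(c.transcript)
    ann = Annotation()
    for gid, txs in by_gene.items():
        ann.add_gene(GeneModel(gid, txs[0].chrom, txs[0].strand, txs, "known_lncRNA"))
    return ann
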