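"""Transcript models and GTF/FASTA input-output.

Coordinates are GTF-native throughout: 1-based, inclusive on both ends.
BED export converts to 0-based half-open at the boundary and nowhere
else. Chromosome names are compared by exact string match; no "chr"
prefix normalization is performed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}

# Ensembl-dialect biotypes treated as non-coding RNA species other than lncRNA
OTHER_NCRNA_BIOTYPES = {
    "tRNA",
    "rRNA",
    "snRNA",
    "snoRNA",
    "miRNA",
    "misc_RNA",
}


class GTFParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class Exon:
    """A stranded genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"exon start {self.start} < 1")
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Exon") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass
class TranscriptModel:
    """An exon chain on one chromosome and strand.

    ``biotype`` is one of ``protein_coding``, ``known_lncRNA``,
    ``other_ncRNA`` or ``unknown``. Strand ``.`` marks unstranded
    single-exon assemblies; downstream comparisons evaluate both
    orientations for them.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]
    biotype: str = "unknown"

    def __post_init__(self):
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = sorted(self.exons)
        for prev, cur in zip(exons, exons[1:]):
            if cur.chrom != exons[0].chrom:
                raise ValueError(f"transcript {self.transcript_id} spans chromosomes")
            if cur.start <= prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
                )
        if exons[0].chrom != self.chrom:
            raise ValueError(f"transcript {self.transcript_id} exons not on {self.chrom}")
        self.exons = exons

    @property
    def length(self) -> int:
        """Mature transcript length: sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        return [
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    biotype: str = "unknown"

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(f"transcript {t.transcript_id} gene_id mismatch")
            if t.chrom != self.chrom:
                raise ValueError(f"transcript {t.transcript_id} chrom mismatch")

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )


class Annotation:
    """A queryable set of gene models with a per-chromosome interval index."""

    def __init__(self, genes: Iterable[GeneModel] = ()):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.add_gene(g)

    def add_gene(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        start, end = gene.span
        # IntervalTree is half-open; store [start, end+1)
        self._trees.setdefault(gene.chrom, IntervalTree()).addi(start, end + 1, gene.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self.genes.values():
            yield from g.transcripts

    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def query(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose spans intersect [start, end] (1-based inclusive)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end + 1)
        return [self.genes[iv.data] for iv in sorted(hits, key=lambda iv: (iv.begin, iv.data))]

    def overlapping_transcripts(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        out = []
        for g in self.query(chrom, start, end):
            for t in g.transcripts:
                s, e = t.span
                if s <= end and start <= e:
                    out.append(t)
        return out

    def subset(self, biotypes: set[str]) -> "Annotation":
        """New Annotation keeping only genes whose biotype is in ``biotypes``."""
        return Annotation(g for g in self.genes.values() if g.biotype in biotypes)

    def chromosomes(self) -> list[str]:
        return sorted(self._trees)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def _resolve_biotype(attrs: dict[str, str], dialect: str) -> str:
    if dialect != "ensembl":
        return "unknown"
    raw = attrs.get("transcript_biotype") or attrs.get("gene_biotype")
    if raw is None:
        return "unknown"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lncRNA", "lincRNA", "known_lncRNA"):
        return "known_lncRNA"
    if raw in OTHER_NCRNA_BIOTYPES:
        return "other_ncRNA"
    return "unknown"


def read_gtf(path, dialect: str = "ensembl") -> Annotation:
    """Read a 9-column GTF into an :class:`Annotation`.

    Only ``exon`` features are material: transcripts are assembled from
    their exon rows, so GTFs with or without explicit ``transcript``
    rows load identically. Exon rows lacking a ``transcript_id`` are
    rejected records (logged, skipped). Malformed lines raise
    :class:`GTFParseError` with the line number.
    """
    if dialect not in ("ensembl", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(f"expected 9 tab-separated columns, got {len(fields)}", lineno)
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_text = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
            if strand not in VALID_STRANDS:
                raise GTFParseError(f"invalid strand {strand!r}", lineno)
            attrs = _parse_attributes(attr_text)
            tid = attrs.get("transcript_id")
            if not tid:
                logger.warning("GTF line %d: exon without transcript_id, record skipped", lineno)
                continue
            rec = per_tx.get(tid)
            if rec is None:
                rec = {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "biotype": _resolve_biotype(attrs, dialect),
                }
                per_tx[tid] = rec
                order.append(tid)
            try:
                rec["exons"].append(Exon(chrom, start, end))
            except ValueError as exc:
                raise GTFParseError(str(exc), lineno)

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in order:
        rec = per_tx[tid]
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=_merge_adjacent(rec["exons"]),
            biotype=rec["biotype"],
        )
        if tx.gene_id not in genes:
            genes[tx.gene_id] = []
            gene_order.append(tx.gene_id)
        genes[tx.gene_id].append(tx)

    ann = Annotation()
    for gid in gene_order:
        txs = genes[gid]
        biotypes = {t.biotype for t in txs}
        biotype = txs[0].biotype if len(biotypes) == 1 else "unknown"
        ann.add_gene(GeneModel(gid, txs[0].chrom, txs[0].strand, txs, biotype))
    return ann


def _merge_adjacent(exons: list[Exon]) -> list[Exon]:
    """Sort and merge book-ended or overlapping exon records."""
    exons = sorted(exons)
    merged = [exons[0]]
    for e in exons[1:]:
        last = merged[-1]
        if e.start <= last.end + 1:
            merged[-1] = Exon(last.chrom, last.start, max(last.end, e.end))
        else:
            merged.append(e)
    return merged


def write_gtf(annotation: Annotation, path) -> None:
    """Write an Annotation as GTF; inverse of :func:`read_gtf`.

    Emits one ``transcript`` row and one ``exon`` row per exon, with
    gene/transcript ids and a ``transcript_biotype`` attribute so the
    round trip preserves every modeled field.
    """
    biotype_out = {
        "protein_coding": "protein_coding",
        "known_lncRNA": "lncRNA",
        "other_ncRNA": "misc_RNA",
        "unknown": None,
    }
    with open(path, "w") as fh:
        fh.write("##provider: lncweanflow\n")
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                bt = biotype_out[t.biotype]
                if bt is not None:
                    attrs += f' transcript_biotype "{bt}";'
                s, e = t.span
                fh.write(
                    f"{t.chrom}\tlncweanflow\ttranscript\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
                for x in t.exons:
                    fh.write(
                        f"{t.chrom}\tlncweanflow\texon\t{x.start}\t{x.end}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


def write_bed6(annotation: Annotation, path) -> None:
    """Export transcript spans as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            for t in sorted(annotation.genes[gid].transcripts, key=lambda t: t.transcript_id):
                s, e = t.span
                strand = t.strand if t.strand != "." else "."
                fh.write(f"{t.chrom}\t{s - 1}\t{e}\t{t.transcript_id}\t0\t{strand}\n")


_DNA = set("ACGTN")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into ``{record_id: uppercase DNA sequence}``.

    Duplicate ids and non-ACGTN symbols are errors; the error names the
    offending record.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"record {record.id!r}: non-DNA symbols {sorted(bad)}")
        seqs[record.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
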