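"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates a two-tissue, two-timepoint weaning study:
multi-exon gene models on toy chromosomes with assembled transcripts
constructed to satisfy each class-code definition exactly; coding and
noncoding sequence composition (codon-usage bias, ORF content) for the
coding-potential stage; and negative-binomial count matrices with
planted two-group log2 fold changes and planted distance-constrained
lncRNA-mRNA correlations via a shared latent Gaussian factor on the
log-mean scale. Every planted structure is recorded in a manifest so
tests can compare recovered against planted truth.

All randomness flows through one ``numpy.random.Generator``; the same
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from lncweanflow.annotation_io import Annotation, Exon, GeneModel, TranscriptModel
from lncweanflow.coding import find_longest_orf, hexamer_index
from lncweanflow.expression import CountMatrix

RETAINED_PLANT_CODES = ("i", "u", "x")
DISCARDED_PLANT_CODES = ("=", "c", "j", "e", "o")


@dataclass
class SimulationConfig:
    """Study-shaped defaults for every simulated input.

    Group sizes mirror the emulated design: 16 pre- and 16 post-weaning
    rumen samples, 8 and 8 for ileum. Counts are NB with dispersion
    ``dispersion`` around log-normal means; planted DE features shift
    the post-weaning group mean by ``2**de_log2fc``. Planted cis pairs
    share a latent factor on the log2-mean scale scaled so the two
    log-mean profiles correlate at ``cis_rho``.
    """

    seed: int = 1
    # --- annotation geometry ---
    n_chromosomes: int = 3
    # 40 kb slots leave intergenic placements >1 kb from, yet within the
    # 50 kb co-expression window of, neighboring slots' genes
    slot_size: int = 40_000
    class_code_block_sizes: Mapping[str, int] = field(
        default_factory=lambda: {c: 5 for c in ("=", "c", "j", "e", "o", "i", "u", "x")}
    )
    n_short: int = 4  # planted <=200 bp transcripts (fail the length filter)
    n_coding_contaminants: int = 6  # "u"-placed transcripts with a >=100 aa ORF
    n_blast_hits: int = 3  # contaminants that also get a strong homology hit
    n_known_lnc: int = 3  # retained transcripts replicated in the known-lncRNA set
    n_other_ncrna: int = 2  # queries overlapping an other-ncRNA reference gene
    # --- sequence composition ---
    noncoding_base_freqs: tuple = (0.30, 0.20, 0.20, 0.30)  # A, C, G, T
    noncoding_max_peptide: int = 60  # ORFs in noncoding sequences broken above this
    train_corpus_per_class: int = 250
    train_len_range: tuple = (300, 1500)
    # --- count model ---
    group_sizes: Mapping[str, tuple] = field(
        default_factory=lambda: {"rumen": (16, 16), "ileum": (8, 8)}
    )
    mu_log2_mean: float = 7.0
    mu_log2_sd: float = 1.5
    dispersion: float = 0.1
    libsize_sd: float = 0.15
    de_fraction: float = 0.10
    de_log2fc: float = 1.0
    # --- planted cis co-expression ---
    cis_rho: float = 0.8
    cis_signal_sd_log2: float = 3.0
    cis_base_log2: float = 8.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# sequence synthesis

_BASES = np.array(list("ACGT"))
# GC-leaning codon usage for synthetic coding frames; stop codons excluded
_STOPS = {"TAA", "TAG", "TGA"}
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _ALL_CODONS if c not in _STOPS]
_CODON_WEIGHTS = np.array(
    [2.0 + 3.0 * (c.count("G") + c.count("C")) for c in _SENSE_CODONS]
)
_CODON_WEIGHTS = _CODON_WEIGHTS / _CODON_WEIGHTS.sum()


def _random_bases(rng: np.random.Generator, n: int, freqs) -> str:
    return "".join(rng.choice(_BASES, size=n, p=np.asarray(freqs)))


def _break_long_orfs(seq: str, max_peptide: int, strand: str = "+") -> str | None:
    """Knock out start codons until no ORF exceeds ``max_peptide`` aa.

    Each offending ORF's ATG becomes ATC. On the edited strand this can
    create no new ATG or stop codon; the rare case where a minus-strand
    edit seeds a new plus-strand ORF (the complement writes a G) is
    handled by the iteration budget — the caller redraws on ``None``.
    """
    from lncweanflow.coding import revcomp

    for _ in range(100):
        orf = find_longest_orf(seq, strand)
        if orf.peptide_len <= max_peptide:
            return seq
        scan = seq if orf.strand == "+" else revcomp(seq)
        scan = scan[: orf.start_offset] + "ATC" + scan[orf.start_offset + 3 :]
        seq = scan if orf.strand == "+" else revcomp(scan)
    return None


def synthesize_noncoding(rng: np.random.Generator, length: int, max_peptide: int = 60) -> str:
    """Random-composition sequence guaranteed to lack long ORFs (both strands)."""
    for _ in range(50):
        seq = _break_long_orfs(
            _random_bases(rng, length, (0.30, 0.20, 0.20, 0.30)), max_peptide, "both"
        )
        if seq is not None:
            return seq
    raise RuntimeError("could not synthesize an ORF-free sequence")  # pragma: no cover


def synthesize_coding(rng: np.random.Generator, length: int, peptide_len: int) -> str:
    """Noncoding background with an embedded biased-codon ORF of ``peptide_len`` aa."""
    orf_nt = 3 * (peptide_len + 1) + 3  # ATG + codons + stop
    if orf_nt > length:
        raise ValueError(f"length {length} too short for a {peptide_len} aa ORF")
    background = synthesize_noncoding(rng, length, max_peptide=min(50, peptide_len - 1))
    offset = int(rng.integers(0, length - orf_nt + 1))
    codons = rng.choice(_SENSE_CODONS, size=peptide_len, p=_CODON_WEIGHTS)
    orf = "ATG" + "".join(codons) + "TAA"
    return background[:offset] + orf + background[offset + len(orf) :]


def training_corpus(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Labeled (sequence, is_coding) examples for the logistic combiner.

    Coding ORF lengths overlap the noncoding range so the classes are
    not linearly separable on ORF length alone and the fit stays
    regular.
    """
    out: list[tuple[str, int]] = []
    lo, hi = cfg.train_len_range
    for _ in range(cfg.train_corpus_per_class):
        n = int(rng.integers(lo, hi + 1))
        out.append((synthesize_noncoding(rng, n, max_peptide=80), 0))
        n = int(rng.integers(max(lo, 420), hi + 1))
        pep = int(rng.integers(50, max(51, n // 3 - 3)))
        out.append((synthesize_coding(rng, n, pep), 1))
    return out


def hexamer_table_from_seqs(seqs) -> np.ndarray:
    """Empirical hexamer distribution (add-one smoothing, sums to 1)."""
    counts = np.ones(4096)
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - 5):
            hexamer = seq[i : i + 6]
            if "N" not in hexamer:
                counts[hexamer_index(hexamer)] += 1
    return counts / counts.sum()


def sample_hexamer_markov(table, length: int, rng: np.random.Generator) -> str:
    """Sample a sequence from the 5th-order Markov model a hexamer table implies."""
    table = np.asarray(table, dtype=float)
    first = int(rng.choice(4096, p=table / table.sum()))
    digits = []
    v = first
    for _ in range(6):
        digits.append(v % 4)
        v //= 4
    seq = [int(d) for d in reversed(digits)]
    # conditional distribution of the next base given the previous 5
    while len(seq) < length:
        prefix = 0
        for d in seq[-5:]:
            prefix = prefix * 4 + d
        probs = table[prefix * 4 : prefix * 4 + 4]
        total = probs.sum()
        if total <= 0:
            probs, total = np.ones(4), 4.0
        seq.append(int(rng.choice(4, p=probs / total)))
    return "".join("ACGT"[d] for d in seq[:length])


# ---------------------------------------------------------------------------
# annotation simulation


@dataclass
class AnnotationManifest:
    """Planted truth for every assembled transcript."""

    planted_codes: dict  # transcript_id -> intended class code (vs coding reference)
    coding_labels: dict  # transcript_id -> bool (sequence carries a long ORF)
    expected_outcome: dict  # transcript_id -> retained | fail:length | fail:class_code | fail:coding_gate
    known_ids: list  # retained transcripts replicated in the known-lncRNA reference
    counts: dict  # gene/transcript/exon tallies per emitted annotation

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticAnnotation:
    reference: Annotation  # protein-coding + other-ncRNA reference
    known_lnc: Annotation
    assembled: Annotation
    sequences: dict  # transcript_id -> DNA sequence (assembled set)
    blast_hits: dict  # transcript_id -> min e-value (contaminant homology)
    manifest: AnnotationManifest


def _reference_gene(gene_id, tx_id, chrom, start, strand, biotype, rng) -> GeneModel:
    """A 4-exon reference gene beginning at ``start``."""
    exon_lens = [int(rng.integers(250, 400)) for _ in range(4)]
    intron_lens = [int(rng.integers(800, 1500)) for _ in range(3)]
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(Exon(chrom, pos, pos + el - 1))
        if i < 3:
            pos = pos + el + intron_lens[i]
    tx = TranscriptModel(tx_id, gene_id, chrom, strand, exons, biotype)
    return GeneModel(gene_id, chrom, strand, [tx], biotype)


def _query_exons_for_code(
    code: str, ref: TranscriptModel | None, chrom: str, slot_start: int, rng
) -> tuple[list[Exon], str]:
    """Exon chain and strand constructed to satisfy one class-code definition."""
    if code == "u":  # empty slot: intergenic
        start = slot_start + 5_000
        return [Exon(chrom, start, start + 599)], ("+" if rng.random() < 0.5 else "-")
    e = ref.exons
    ints = ref.introns
    if code == "=":
        return list(e), ref.strand
    if code == "c":  # exons 2..3 of the reference: contained, contiguous introns
        return [e[1], e[2]], ref.strand
    if code == "j":  # shares intron 1, second exon runs into intron 2
        ext_end = min(e[2].start - 2, e[1].end + 300)
        return [e[0], Exon(chrom, e[1].start, ext_end)], ref.strand
    if code == "e":  # single exon across the exon1/intron1 boundary
        return [Exon(chrom, e[0].start + 50, e[0].end + 400)], ref.strand
    if code == "o":  # two exons, junction inside intron 1: no shared junction
        mid = e[0].end + (e[1].start - e[0].end) // 2
        return [
            Exon(chrom, e[0].start + 20, mid - 150),
            Exon(chrom, mid, e[1].end - 30),
        ], ref.strand
    if code == "i":  # wholly inside intron 2, same strand
        s0, s1 = ints[1]
        start = s0 + 60
        return [Exon(chrom, start, min(s1 - 60, start + 420))], ref.strand
    if code == "x":  # overlaps exon 3 on the opposite strand
        flipped = "-" if ref.strand == "+" else "+"
        return [Exon(chrom, e[2].start - 100, e[2].end + 100)], flipped
    raise ValueError(f"no construction for code {code!r}")


def simulate_annotation(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> SyntheticAnnotation:
    """Reference, known-lncRNA and assembled annotations plus sequences.

    One genomic slot per planted transcript keeps constructions
    independent; codes "i", "u" and "x" are the cascade's survivors
    unless the transcript is a planted coding contaminant or planted
    short.
    """
    rng = cfg.rng() if rng is None else rng
    reference = Annotation()
    known_lnc = Annotation()
    assembled = Annotation()
    sequences: dict[str, str] = {}
    blast_hits: dict[str, float] = {}
    planted_codes: dict[str, str] = {}
    coding_labels: dict[str, bool] = {}
    expected: dict[str, str] = {}
    known_ids: list[str] = []

    slot_counter = 0
    tx_counter = 0
    ref_counter = 0

    def next_slot() -> tuple[str, int]:
        nonlocal slot_counter
        chrom = f"chr{slot_counter % cfg.n_chromosomes + 1}"
        start = 10_000 + (slot_counter // cfg.n_chromosomes) * cfg.slot_size
        slot_counter += 1
        return chrom, start

    def new_ids() -> tuple[str, str]:
        nonlocal tx_counter
        tx_counter += 1
        return f"XLOC_{tx_counter:06d}", f"TCONS_{tx_counter:08d}"

    def add_query(exons, strand, code, coding: bool, outcome: str) -> str:
        gid, tid = new_ids()
        tx = TranscriptModel(tid, gid, exons[0].chrom, strand, exons, "unknown")
        assembled.add_gene(GeneModel(gid, tx.chrom, strand, [tx], "unknown"))
        planted_codes[tid] = code
        coding_labels[tid] = coding
        expected[tid] = outcome
        if coding:
            sequences[tid] = synthesize_coding(rng, tx.length, max(100, tx.length // 3 - 5))
        else:
            sequences[tid] = synthesize_noncoding(rng, tx.length, cfg.noncoding_max_peptide)
        return tid

    # class-code blocks against fresh protein-coding reference genes
    for code, block in cfg.class_code_block_sizes.items():
        for _ in range(block):
            chrom, start = next_slot()
            ref_tx = None
            if code != "u":
                ref_counter += 1
                strand = "+" if rng.random() < 0.5 else "-"
                gene = _reference_gene(
                    f"ENSBTAG{ref_counter:08d}",
                    f"ENSBTAT{ref_counter:08d}",
                    chrom,
                    start + 2_000,
                    strand,
                    "protein_coding",
                    rng,
                )
                reference.add_gene(gene)
                ref_tx = gene.transcripts[0]
            exons, strand = _query_exons_for_code(code, ref_tx, chrom, start, rng)
            outcome = "retained" if code in RETAINED_PLANT_CODES else "fail:class_code"
            add_query(exons, strand, code, coding=False, outcome=outcome)

    # queries overlapping an other-ncRNA reference gene: removed at class code
    for _ in range(cfg.n_other_ncrna):
        chrom, start = next_slot()
        ref_counter += 1
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _reference_gene(
            f"ENSBTAG{ref_counter:08d}",
            f"ENSBTAT{ref_counter:08d}",
            chrom,
            start + 2_000,
            strand,
            "other_ncRNA",
            rng,
        )
        reference.add_gene(gene)
        exons, qstrand = _query_exons_for_code("e", gene.transcripts[0], chrom, start, rng)
        add_query(exons, qstrand, "e", coding=False, outcome="fail:class_code")

    # planted short transcripts (length filter) in empty slots
    for _ in range(cfg.n_short):
        chrom, start = next_slot()
        s = start + 4_000
        gid, tid = new_ids()
        tx = TranscriptModel(tid, gid, chrom, "+", [Exon(chrom, s, s + 149)], "unknown")
        assembled.add_gene(GeneModel(gid, chrom, "+", [tx], "unknown"))
        planted_codes[tid] = "u"
        coding_labels[tid] = False
        expected[tid] = "fail:length"
        sequences[tid] = synthesize_noncoding(rng, tx.length, cfg.noncoding_max_peptide)

    # coding contaminants: intergenic placement, long-ORF sequence
    for k in range(cfg.n_coding_contaminants):
        chrom, start = next_slot()
        s = start + 6_000
        tid = add_query(
            [Exon(chrom, s, s + 899)],
            "+" if rng.random() < 0.5 else "-",
            "u",
            coding=True,
            outcome="fail:coding_gate",
        )
        if k < cfg.n_blast_hits:
            blast_hits[tid] = 10.0 ** float(rng.uniform(-30, -8))

    # known-lncRNA reference: replicate the exon chains of a few survivors
    survivors = [t for t, o in expected.items() if o == "retained"]
    for j, tid in enumerate(survivors[: cfg.n_known_lnc]):
        tx = next(t for t in assembled.transcripts() if t.transcript_id == tid)
        kid = f"NONBTAG{j + 1:06d}"
        ktx = TranscriptModel(f"{kid}.1", kid, tx.chrom, tx.strand, list(tx.exons), "known_lncRNA")
        known_lnc.add_gene(GeneModel(kid, tx.chrom, tx.strand, [ktx], "known_lncRNA"))
        known_ids.append(tid)

    counts = {
        "reference": {
            "genes": len(reference),
            "transcripts": reference.n_transcripts(),
            "exons": sum(t.n_exons for t in reference.transcripts()),
        },
        "known_lnc": {
            "genes": len(known_lnc),
            "transcripts": known_lnc.n_transcripts(),
            "exons": sum(t.n_exons for t in known_lnc.transcripts()),
        },
        "assembled": {
            "genes": len(assembled),
            "transcripts": assembled.n_transcripts(),
            "exons": sum(t.n_exons for t in assembled.transcripts()),
        },
    }
    manifest = AnnotationManifest(planted_codes, coding_labels, expected, known_ids, counts)
    return SyntheticAnnotation(reference, known_lnc, assembled, sequences, blast_hits, manifest)


# ---------------------------------------------------------------------------
# count simulation


@dataclass
class CountsManifest:
    log2fc: dict  # feature_id -> planted log2FC (0 for null features)
    de_features: list
    cis_pairs: list  # (lncrna_id, mrna_id, rho)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, variance mu + alpha mu^2); Poisson in the alpha -> 0 limit."""
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu * alpha)
    return rng.poisson(lam)


def simulate_nb_matrix(
    rng: np.random.Generator,
    n_features: int,
    group_sizes: tuple[int, int],
    mu: float,
    alpha: float,
    log2fc: float = 0.0,
    de_fraction: float = 1.0,
    libsize_sd: float = 0.0,
    prefix: str = "G",
    tissue: str = "rumen",
) -> CountMatrix:
    """Flat-mean NB matrix with a balanced differential block.

    Features sit at mean ``mu``; the first ``de_fraction`` of them form
    the DE block, whose first half shifts the D96 group mean by
    ``2**log2fc`` and whose second half by ``2**-log2fc``. Balanced
    planting keeps the median-of-ratios size factors anchored on the
    null behavior — a shift planted in every feature in one direction
    is indistinguishable from a library-size change and normalization
    absorbs it.
    """
    na, nb = group_sizes
    n = na + nb
    sizes = np.exp(rng.normal(0.0, libsize_sd, size=n)) if libsize_sd > 0 else np.ones(n)
    n_de = int(round(de_fraction * n_features)) if log2fc else 0
    n_up = (n_de + 1) // 2
    mu_mat = np.full((n_features, n), float(mu))
    mu_mat[:n_up, na:] = mu * 2.0**log2fc
    mu_mat[n_up:n_de, na:] = mu * 2.0**-log2fc
    counts = _nb_draw(rng, mu_mat * sizes, alpha)
    samples = [f"{tissue}_D33_{i + 1}" for i in range(na)] + [
        f"{tissue}_D96_{i + 1}" for i in range(nb)
    ]
    sheet = pd.DataFrame(
        {"tissue": tissue, "timepoint": ["D33"] * na + ["D96"] * nb}, index=samples
    )
    sheet.index.name = "sample_id"
    features = [f"{prefix}{i + 1:06d}" for i in range(n_features)]
    return CountMatrix(pd.DataFrame(counts, index=features, columns=samples), sheet)


def simulate_counts(
    cfg: SimulationConfig,
    mrna_ids,
    lnc_ids,
    tissue: str = "rumen",
    rng: np.random.Generator | None = None,
    cis_pairs=None,
) -> tuple[CountMatrix, CountsManifest]:
    """Study-shaped count matrix with planted DE and planted cis pairs.

    A fraction ``de_fraction`` of features (half up, half down) get a
    two-group shift of ``de_log2fc``. Each requested cis pair (lncRNA
    id, mRNA id) shares a latent per-sample factor on the log2-mean
    scale with correlation ``cis_rho``; cis features are kept non-DE so
    the two plants do not interfere.
    """
    rng = cfg.rng() if rng is None else rng
    mrna_ids, lnc_ids = list(mrna_ids), list(lnc_ids)
    features = mrna_ids + lnc_ids
    na, nb = cfg.group_sizes[tissue]
    n = na + nb
    cis_pairs = list(cis_pairs or [])
    cis_members = {f for pair in cis_pairs for f in pair}

    sizes = np.exp(rng.normal(0.0, cfg.libsize_sd, size=n))
    base_log2 = rng.normal(cfg.mu_log2_mean, cfg.mu_log2_sd, size=len(features))
    log2fc = {f: 0.0 for f in features}
    eligible = [f for f in features if f not in cis_members]
    n_de = int(round(cfg.de_fraction * len(eligible)))
    de_features = list(rng.choice(eligible, size=n_de, replace=False)) if n_de else []
    for j, f in enumerate(de_features):
        log2fc[f] = cfg.de_log2fc if j % 2 == 0 else -cfg.de_log2fc

    index = {f: i for i, f in enumerate(features)}
    log2_mu = np.tile(base_log2[:, None], (1, n))
    for f in features:
        if log2fc[f]:
            log2_mu[index[f], na:] += log2fc[f]

    sig = cfg.cis_signal_sd_log2
    a = sig * np.sqrt(cfg.cis_rho)
    b = sig * np.sqrt(1.0 - cfg.cis_rho)
    for lnc, mrna in cis_pairs:
        factor = rng.normal(0.0, 1.0, size=n)
        for f in (lnc, mrna):
            noise = rng.normal(0.0, 1.0, size=n)
            log2_mu[index[f]] = cfg.cis_base_log2 + a * factor + b * noise
    mu = np.power(2.0, log2_mu) * sizes
    counts = _nb_draw(rng, mu, cfg.dispersion)
    samples = [f"{tissue}_D33_{i + 1}" for i in range(na)] + [
        f"{tissue}_D96_{i + 1}" for i in range(nb)
    ]
    sheet = pd.DataFrame(
        {"tissue": tissue, "timepoint": ["D33"] * na + ["D96"] * nb}, index=samples
    )
    sheet.index.name = "sample_id"
    cm = CountMatrix(pd.DataFrame(counts, index=features, columns=samples), sheet)
    manifest = CountsManifest(
        log2fc=log2fc,
        de_features=de_features,
        cis_pairs=[(l, m, cfg.cis_rho) for l, m in cis_pairs],
    )
    return cm, manifest


def simulate_gene_sets(
    rng: np.random.Generator,
    universe,
    favored,
    n_sets: int = 8,
    set_size: int = 20,
    bias: float = 0.7,
):
    """Synthetic gene-set collection with one set enriched for ``favored``.

    The first set draws ``bias`` of its members from the favored list
    (e.g. planted DE genes); the rest are uniform draws from the
    universe.
    """
    from lncweanflow.enrichment import GeneSetCollection

    universe = list(universe)
    favored = [f for f in favored if f in set(universe)]
    sets: dict[str, set] = {}
    for k in range(n_sets):
        size = min(set_size, len(universe))
        if k == 0 and favored:
            n_fav = min(len(favored), int(round(bias * size)))
            members = set(rng.choice(favored, size=n_fav, replace=False))
            rest = [u for u in universe if u not in members]
            members |= set(rng.choice(rest, size=size - n_fav, replace=False))
        else:
            members = set(rng.choice(universe, size=size, replace=False))
        sets[f"SET_{k + 1:03d}"] = members
    return GeneSetCollection(sets, set(universe))


def simulate_cis_expression(
    cfg: SimulationConfig,
    n_planted: int,
    n_null: int,
    n_samples: int,
    rng: np.random.Generator | None = None,
) -> tuple[list, pd.DataFrame, pd.DataFrame, set]:
    """Pure count-level cis benchmark: planted correlated pairs among nulls.

    Returns (candidate pairs with zero distance, lncRNA expression
    frame, mRNA expression frame, set of planted pair keys). Each pair
    uses its own lncRNA and mRNA feature, so nulls are independent.
    """
    rng = cfg.rng() if rng is None else rng
    total = n_planted + n_null
    samples = [f"s{i + 1}" for i in range(n_samples)]
    lnc_ids = [f"LNC{i + 1:05d}" for i in range(total)]
    mrna_ids = [f"MRNA{i + 1:05d}" for i in range(total)]
    sig = cfg.cis_signal_sd_log2
    a = sig * np.sqrt(cfg.cis_rho)
    b = sig * np.sqrt(1.0 - cfg.cis_rho)
    lnc_log2 = np.empty((total, n_samples))
    mrna_log2 = np.empty((total, n_samples))
    for i in range(total):
        if i < n_planted:
            factor = rng.normal(0.0, 1.0, size=n_samples)
            lnc_log2[i] = cfg.cis_base_log2 + a * factor + b * rng.normal(0, 1, n_samples)
            mrna_log2[i] = cfg.cis_base_log2 + a * factor + b * rng.normal(0, 1, n_samples)
        else:
            lnc_log2[i] = cfg.cis_base_log2 + sig * rng.normal(0, 1, n_samples)
            mrna_log2[i] = cfg.cis_base_log2 + sig * rng.normal(0, 1, n_samples)
    lnc_counts = _nb_draw(rng, np.power(2.0, lnc_log2), cfg.dispersion)
    mrna_counts = _nb_draw(rng, np.power(2.0, mrna_log2), cfg.dispersion)
    pairs = [(lnc_ids[i], mrna_ids[i], 0) for i in range(total)]
    planted = {(lnc_ids[i], mrna_ids[i]) for i in range(n_planted)}
    lnc_expr = pd.DataFrame(lnc_counts.astype(float), index=lnc_ids, columns=samples)
    mrna_expr = pd.DataFrame(mrna_counts.astype(float), index=mrna_ids, columns=samples)
    return pairs, lnc_expr, mrna_expr, planted
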