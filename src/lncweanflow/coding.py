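"""Coding-potential scoring and the coding-filter gate.

A transcript survives the gate only if every available piece of coding
evidence says "noncoding": externally computed CNCI score < 0, CPAT
probability < 0.5 (or, when no external tables are supplied, the
built-in logistic combiner's probability < 0.5), no protein homology
hit with e-value < 1e-5, and no open reading frame able to encode a
peptide of 100 or more amino acids. ORFs without an in-frame stop
codon are counted open-ended, to the end of the sequence.

The built-in scorer mirrors the classic alignment-free feature set:
longest-ORF length and coverage, the Fickett TESTCODE composition
statistic, and a hexamer usage log-likelihood ratio, combined by
logistic regression trained on labeled example sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ORF:
    """Longest open reading frame of a transcript sequence.

    ``peptide_len`` counts codons from the initial ATG (included) up to
    but excluding the stop codon; for open-ended ORFs it counts whole
    codons to the end of the sequence. ``start_offset`` is 0-based on
    the scanned strand.
    """

    frame: int = 0
    strand: str = "+"
    start_offset: int = 0
    peptide_len: int = 0
    has_stop: bool = False


def find_longest_orf(seq: str, strand: str = "+") -> ORF:
    """Longest ATG-initiated ORF.

    ``strand`` is "+" (sense only, the default for stranded assembled
    transcripts), "-" or "both" (unstranded: best of the two). Ties are
    broken toward the smaller start offset, and toward "+" across
    strands.
    """
    seq = seq.upper()
    if strand == "both":
        fwd = find_longest_orf(seq, "+")
        rev = find_longest_orf(seq, "-")
        return rev if rev.peptide_len > fwd.peptide_len else fwd
    if strand == "-":
        best = find_longest_orf(revcomp(seq), "+")
        return ORF(best.frame, "-", best.start_offset, best.peptide_len, best.has_stop)
    best = ORF()
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG" and open_start is None:
                open_start = pos
            elif codon in STOP_CODONS and open_start is not None:
                plen = (pos - open_start) // 3
                if plen > best.peptide_len or (
                    plen == best.peptide_len and plen and open_start < best.start_offset
                ):
                    best = ORF(frame, "+", open_start, plen, True)
                open_start = None
        if open_start is not None:  # open-ended ORF
            plen = (n - open_start) // 3
            if plen > best.peptide_len or (
                plen == best.peptide_len and plen and open_start < best.start_offset
            ):
                best = ORF(frame, "+", open_start, plen, False)
    return best


# Fickett (TESTCODE) lookup tables: probability that a sequence with the
# given position asymmetry / base content is coding, and the weight of
# each parameter, as published for the classic statistic.
_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.52, 0.41, 0.31, 0.17],
    "T": [0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.30, 0.33, 0.29, 0.29, 0.17],
    "G": [0.21, 0.40, 0.47, 0.46, 0.52, 0.58, 0.54, 0.61, 0.33, 0.29],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.09, 0.09],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic from the published lookup tables.

    Combines, for each base, its positional asymmetry across the three
    codon-frame positions and its overall content. Deterministic;
    requires at least 6 nt.
    """
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError(f"sequence too short for Fickett statistic ({len(seq)} nt)")
    score = 0.0
    total = max(1, len(seq))
    for base in "ACGT":
        counts = [seq[i::3].count(base) for i in range(3)]
        position_value = max(counts) / (min(counts) + 1.0)
        score += _lookup(position_value, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        content = seq.count(base) / total
        score += _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def fickett_score_range() -> tuple[float, float]:
    """Attainable [min, max] of the statistic given the lookup tables."""
    lo = sum(min(_POSITION_PROB[b]) * _POSITION_WEIGHT[b] for b in "ACGT") + sum(
        min(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in "ACGT"
    )
    hi = sum(max(_POSITION_PROB[b]) * _POSITION_WEIGHT[b] for b in "ACGT") + sum(
        max(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in "ACGT"
    )
    return lo, hi


HEXAMER_PSEUDOCOUNT = 1e-9


def _as_hexamer_array(table) -> np.ndarray:
    if isinstance(table, dict):
        arr = np.zeros(4096)
        for hexamer, p in table.items():
            arr[hexamer_index(hexamer)] = p
    else:
        arr = np.asarray(table, dtype=float)
        if arr.shape != (4096,):
            raise ValueError(f"hexamer table must have 4096 entries, got {arr.shape}")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"hexamer table not normalized (sum={arr.sum()!r})")
    return arr


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def hexamer_index(hexamer: str) -> int:
    idx = 0
    for base in hexamer:
        idx = idx * 4 + _BASE_INDEX[base]
    return idx


def hexamer_llr(seq: str, coding_table, noncoding_table) -> float:
    """Mean per-hexamer log-likelihood ratio, coding vs noncoding.

    Slides a 6-mer window one base at a time; hexamers containing N are
    skipped. Returns 0 for sequences shorter than 6 nt, and exactly 0
    when the two tables are identical.
    """
    coding = _as_hexamer_array(coding_table)
    noncoding = _as_hexamer_array(noncoding_table)
    seq = seq.upper()
    if len(seq) < 6:
        return 0.0
    total = 0.0
    count = 0
    for i in range(len(seq) - 5):
        hexamer = seq[i : i + 6]
        if "N" in hexamer:
            continue
        j = hexamer_index(hexamer)
        total += math.log(
            (coding[j] + HEXAMER_PSEUDOCOUNT) / (noncoding[j] + HEXAMER_PSEUDOCOUNT)
        )
        count += 1
    return total / count if count else 0.0


FEATURE_NAMES = ("peptide_len", "orf_coverage", "fickett", "hexamer_llr")
_COEF_CAP = 30.0


@dataclass
class LogisticCombiner:
    """Fitted logistic model over the four coding-potential features."""

    coef: np.ndarray  # intercept followed by one weight per feature

    def score(self, features) -> float:
        """Probability that a transcript with these features is coding."""
        x = np.concatenate([[1.0], np.asarray(features, dtype=float)])
        return float(1.0 / (1.0 + np.exp(-np.clip(x @ self.coef, -700, 700))))


def fit_logistic_combiner(labeled) -> LogisticCombiner:
    """Maximum-likelihood logistic fit (IRLS, <=100 iterations, tol 1e-8).

    ``labeled`` is an iterable of ``(features, label)`` with label 1 for
    coding. Under (near-)perfect separation the unpenalized likelihood
    has no maximum; the fit then falls back to a light L2 penalty and
    the coefficients are capped, with a warning logged.
    """
    import warnings

    import statsmodels.api as sm

    rows = [(np.asarray(f, dtype=float), int(y)) for f, y in labeled]
    if not rows:
        raise ValueError("no training examples")
    y = np.array([lab for _, lab in rows])
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least one example per class")
    X = sm.add_constant(np.vstack([f for f, _ in rows]), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    coef = np.asarray(result.params, dtype=float)
    if np.any(np.abs(coef) > _COEF_CAP) or not np.all(np.isfinite(coef)):
        logger.warning(
            "logistic combiner: separation detected; refitting with an L2 penalty "
            "and capping coefficients"
        )
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(X[:, 1:], y)
        coef = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        coef = np.clip(coef, -_COEF_CAP, _COEF_CAP)
    return LogisticCombiner(coef)


@dataclass
class CodingPotential:
    """All coding evidence gathered for one transcript."""

    transcript_id: str
    orf: ORF = field(default_factory=ORF)
    fickett: float = 0.0
    hexamer_llr: float = 0.0
    combined_prob: float = 0.0
    cnci_score: float | None = None
    cpat_score: float | None = None
    min_evalue: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.combined_prob <= 1.0:
            raise ValueError(f"combined_prob {self.combined_prob} outside [0, 1]")


@dataclass(frozen=True)
class GateThresholds:
    """Cutoffs of the coding-filter gate (defaults are the pipeline's)."""

    cnci: float = 0.0  # discard if CNCI score >= this
    cpat: float = 0.5  # discard if CPAT/combined probability >= this
    evalue: float = 1e-5  # discard if any homology hit below this e-value
    peptide: int = 100  # discard if longest ORF peptide >= this many aa


def gate_failures(cp: CodingPotential, thresholds: GateThresholds = GateThresholds()) -> list[str]:
    """Names of the coding-evidence criteria ``cp`` fails; empty = retain."""
    failures = []
    if cp.cnci_score is not None and cp.cnci_score >= thresholds.cnci:
        failures.append("cnci")
    if cp.cpat_score is not None:
        if cp.cpat_score >= thresholds.cpat:
            failures.append("cpat")
    elif cp.combined_prob >= thresholds.cpat:
        failures.append("combined_prob")
    if cp.min_evalue is not None and cp.min_evalue < thresholds.evalue:
        failures.append("homology")
    if cp.orf.peptide_len >= thresholds.peptide:
        failures.append("orf")
    return failures


def coding_gate(cp: CodingPotential, thresholds: GateThresholds = GateThresholds()) -> str:
    """Apply the conjunction gate: ``retain_noncoding`` or ``discard_coding``."""
    return "discard_coding" if gate_failures(cp, thresholds) else "retain_noncoding"


def score_transcript(
    transcript_id: str,
    seq: str,
    coding_table,
    noncoding_table,
    combiner: LogisticCombiner,
    strand: str = "+",
) -> CodingPotential:
    """Compute all built-in features and the combined probability."""
    orf = find_longest_orf(seq, strand)
    fick = fickett_score(seq) if len(seq) >= 6 else 0.0
    llr = hexamer_llr(seq, coding_table, noncoding_table)
    coverage = 3.0 * orf.peptide_len / len(seq) if seq else 0.0
    prob = combiner.score((orf.peptide_len, coverage, fick, llr))
    return CodingPotential(
        transcript_id=transcript_id,
        orf=orf,
        fickett=fick,
        hexamer_llr=llr,
        combined_prob=prob,
    )


def read_blast_tab(path) -> dict[str, float]:
    """Minimum e-value per query id from 12-column tabular BLAST output."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            qid = fields[0]
            try:
                evalue = float(fields[10])
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric e-value {fields[10]!r}")
            if qid not in out or evalue < out[qid]:
                out[qid] = evalue
    return out


def read_score_table(path, score_column: str) -> dict[str, float]:
    """Read an external (transcript_id, score) TSV such as CNCI/CPAT output."""
    df = pd.read_csv(path, sep="\t")
    if score_column not in df.columns:
        raise ValueError(f"column {score_column!r} absent from {path}")
    id_col = df.columns[0]
    return dict(zip(df[id_col].astype(str), df[score_column].astype(float)))
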