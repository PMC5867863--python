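"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives the expected answer from first principles
(exhaustive scans, definitional formulas), deliberately avoiding the
package's own code paths it is used to check.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# longest ORF: scan every ATG in every frame

STOPS = {"TAA", "TAG", "TGA"}
_RC = str.maketrans("ACGTN", "TGCAN")


def orf_brute_force(seq: str):
    """(peptide_len, start_offset) of the longest ORF on the + strand."""
    seq = seq.upper()
    best_len, best_start = 0, 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        plen = 0
        stopped = False
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if codon in STOPS and j > i:
                stopped = True
                break
            plen += 1
            j += 3
        # plen counted codons including ATG; open-ended counts to end
        if plen > best_len:
            best_len, best_start = plen, i
    return best_len, best_start


# ---------------------------------------------------------------------------
# BH step-up, definitional

def bh_brute_force(pvals):
    """q_(k) = min_{j>=k} p_(j) m / j capped at 1, mapped back to input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, pvals[idx] * m / rank)
        out[idx] = running_min
    return out


# ---------------------------------------------------------------------------
# hypergeometric upper tail by enumeration

def hypergeom_brute_force(k: int, N: int, K: int, n: int) -> float:
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ) / total


# ---------------------------------------------------------------------------
# windowed candidate pairs by all-pairs scan

def pairs_brute_force(lnc_spans, mrna_spans, window):
    """lnc_spans/mrna_spans: {id: (chrom, start, end)}; returns {(l, m): distance}."""
    out = {}
    for lid, (lc, ls, le) in lnc_spans.items():
        for mid, (mc, ms, me) in mrna_spans.items():
            if lc != mc:
                continue
            if ms <= le + window and ls - window <= me:
                if ms <= le and ls <= me:
                    d = 0
                elif ms > le:
                    d = ms - le
                else:
                    d = ls - me
                out[(lid, mid)] = d
    return out


# ---------------------------------------------------------------------------
# expression filter by double loop

def expression_filter_brute_force(counts, factors, min_count, min_fraction):
    """counts: list of rows; factors: per-sample; returns retained row indices."""
    n_samples = len(factors)
    needed = math.ceil(min_fraction * n_samples)
    kept = []
    for i, row in enumerate(counts):
        n_over = sum(1 for j in range(n_samples) if row[j] / factors[j] > min_count)
        if n_over >= needed:
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# class code over all reference transcripts, definitional

def _introns(exons):
    return [(a[1] + 1, b[0] - 1) for a, b in zip(exons, exons[1:])]


def _exon_overlap(qexons, rexons):
    return any(qs <= re and rs <= qe for qs, qe in qexons for rs, re in rexons)


def _relation(qexons, qstrand, rexons, rstrand):
    """Most specific code of a query vs one reference transcript, or None."""
    qs, qe = qexons[0][0], qexons[-1][1]
    rs, re = rexons[0][0], rexons[-1][1]
    if qe < rs or re < qs:
        return None
    qi, ri = _introns(qexons), _introns(rexons)
    same = qstrand == "." or rstrand == "." or qstrand == rstrand
    if same:
        if qi and qi == ri:
            return "="
        if not qi and not ri and _exon_overlap(qexons, rexons):
            return "="
        contained = (
            qs >= rs
            and qe <= re
            and all(any(rx[0] <= ex[0] and ex[1] <= rx[1] for rx in rexons) for ex in qexons)
            and (
                not qi
                or any(ri[o : o + len(qi)] == qi for o in range(len(ri) - len(qi) + 1))
            )
        )
        if contained:
            return "c"
        if qi and set(qi) & set(ri):
            return "j"
        if _exon_overlap(qexons, rexons):
            return "e" if len(qexons) == 1 else "o"
        if any(i0 <= qs and qe <= i1 for i0, i1 in ri):
            return "i"
        return None
    if any(i0 <= qs and qe <= i1 for i0, i1 in ri):
        return "i"
    if _exon_overlap(qexons, rexons):
        return "x"
    return None


CODE_ORDER = ["=", "c", "j", "e", "o", "i", "x", "u"]


def class_code_brute_force(qexons, qstrand, qchrom, reference):
    """reference: list of (chrom, strand, exons, transcript_id); exhaustive scan."""
    best = None
    for chrom, strand, exons, tid in reference:
        if chrom != qchrom:
            continue
        code = _relation(qexons, qstrand, exons, strand)
        if code is None:
            continue
        key = (CODE_ORDER.index(code), tid)
        if best is None or key < best[0]:
            best = (key, code)
    return "u" if best is None else best[1]
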