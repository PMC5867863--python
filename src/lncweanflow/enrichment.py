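"""Hypergeometric over-representation of a gene list against gene sets.

Two significance regimes are supported, mirroring the common practice
of BH-corrected GO enrichment and uncorrected pathway enrichment:
``correction="bh"`` adjusts across sets, ``correction="none"`` reports
raw p-values only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from lncweanflow.de import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(f"gene set {name!r} has members outside the universe: {sorted(stray)[:5]}")


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int  # k
    set_size: int  # K
    query_size: int  # n
    universe_size: int  # N
    p: float
    p_bh: float


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query, collection: GeneSetCollection, correction: str = "bh"
) -> list[EnrichmentResult]:
    """Over-representation p-value per set for the query gene list.

    Query genes outside the universe are dropped with a warning; an
    effectively empty query is an error. With ``correction="none"``
    the ``p_bh`` field simply repeats the raw p.
    """
    if correction not in ("bh", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    query = set(query)
    stray = query - collection.universe
    if stray:
        logger.warning("%d query genes outside the universe dropped", len(stray))
        query -= stray
    if not query:
        raise ValueError("query is empty (after dropping genes outside the universe)")
    N, n = len(collection.universe), len(query)
    raw: list[tuple[str, int, int, float]] = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        k = len(query & members)
        raw.append((name, k, len(members), hypergeom_pvalue(k, N, len(members), n)))
    p_adj = bh_adjust([r[3] for r in raw]) if correction == "bh" else [r[3] for r in raw]
    return [
        EnrichmentResult(name, k, K, n, N, p, float(q))
        for (name, k, K, p), q in zip(raw, p_adj)
    ]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p": [r.p for r in results],
            "p.BH": [r.p_bh for r in results],
        }
    )


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file; the universe defaults to the union of all sets."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _description, *genes = fields
            sets[name] = {g for g in genes if g}
    uni = set(universe) if universe is not None else set().union(*sets.values()) if sets else set()
    if universe is not None:
        sets = {n: m & uni for n, m in sets.items()}
        sets = {n: m for n, m in sets.items() if m}
    return GeneSetCollection(sets, uni)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")
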