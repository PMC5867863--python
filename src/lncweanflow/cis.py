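"""Windowed lncRNA-mRNA cis-target co-expression.

Candidate pairs are protein-coding genes whose span intersects the
lncRNA gene span extended by 50 kb on each side (boundary inclusive,
either strand, same chromosome). Each pair is scored by Pearson
correlation of expression across all samples of the tissue, two-sided
t test on n-2 degrees of freedom, and Benjamini-Hochberg correction
across all tested pairs of the tissue; pairs with adjusted p < 0.05
are called cis targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lncweanflow.annotation_io import Annotation
from lncweanflow.de import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 50_000


@dataclass
class CisPair:
    lncrna_id: str
    mrna_gene_id: str
    distance_bp: int
    r: float
    p: float
    p_bh: float
    is_cis_target: bool


def span_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between two spans in bp; 0 when they overlap or touch."""
    if a[0] <= b[1] and b[0] <= a[1]:
        return 0
    return b[0] - a[1] if b[0] > a[1] else a[0] - b[1]


def find_candidate_pairs(
    lncrnas: Annotation, mrnas: Annotation, window: int = DEFAULT_WINDOW
) -> list[tuple[str, str, int]]:
    """(lncrna_gene_id, mrna_gene_id, distance) for all in-window pairs."""
    pairs = []
    for lnc_id in sorted(lncrnas.genes):
        lnc = lncrnas.genes[lnc_id]
        s, e = lnc.span
        for gene in mrnas.query(lnc.chrom, max(1, s - window), e + window):
            pairs.append((lnc_id, gene.gene_id, span_distance(lnc.span, gene.span)))
    return pairs


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p from the t distribution (df n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant_expression")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def call_cis_targets(
    pairs,
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    fdr: float = 0.05,
    expr_scale: str = "log2p1",
) -> list[CisPair]:
    """Test candidate pairs and call cis targets at BH-adjusted p < fdr.

    ``lnc_expr``/``mrna_expr`` are normalized-count frames (features x
    samples, identical sample columns, both timepoints pooled).
    ``expr_scale`` "log2p1" correlates log2(normalized count + 1)
    (variance stabilized, the default); "raw" correlates the counts as
    given. Pairs whose members are missing from the expression frames
    or constant are dropped with a logged reason.
    """
    if expr_scale not in ("log2p1", "raw"):
        raise ValueError(f"unknown expr_scale {expr_scale!r}")
    if list(lnc_expr.columns) != list(mrna_expr.columns):
        raise ValueError("expression frames must share identical sample columns")

    def transform(v: np.ndarray) -> np.ndarray:
        return np.log2(v + 1.0) if expr_scale == "log2p1" else v

    tested: list[tuple[str, str, int, float, float]] = []
    for lnc_id, gene_id, distance in pairs:
        if lnc_id not in lnc_expr.index or gene_id not in mrna_expr.index:
            logger.info("pair (%s, %s) dropped: unexpressed feature", lnc_id, gene_id)
            continue
        x = transform(lnc_expr.loc[lnc_id].to_numpy(dtype=float))
        y = transform(mrna_expr.loc[gene_id].to_numpy(dtype=float))
        try:
            r, p = pearson_test(x, y)
        except ValueError:
            logger.info("pair (%s, %s) dropped: constant_expression", lnc_id, gene_id)
            continue
        tested.append((lnc_id, gene_id, distance, r, p))
    if not tested:
        return []
    p_bh = bh_adjust([t[4] for t in tested])
    return [
        CisPair(lnc, gene, dist, r, p, float(q), bool(q < fdr))
        for (lnc, gene, dist, r, p), q in zip(tested, p_bh)
    ]


def cis_table(results: list[CisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [c.lncrna_id for c in results],
            "mrna_gene_id": [c.mrna_gene_id for c in results],
            "distance_bp": [c.distance_bp for c in results],
            "Cor": [c.r for c in results],
            "p": [c.p for c in results],
            "p.BH": [c.p_bh for c in results],
            "is_cis_target": [c.is_cis_target for c in results],
        }
    )


def degree_summaries(results: list[CisPair]) -> tuple[pd.Series, pd.Series]:
    """Per-lncRNA target counts and per-gene lncRNA counts (significant pairs)."""
    sig = [c for c in results if c.is_cis_target]
    by_lnc = pd.Series([c.lncrna_id for c in sig]).value_counts() if sig else pd.Series(dtype=int)
    by_gene = (
        pd.Series([c.mrna_gene_id for c in sig]).value_counts() if sig else pd.Series(dtype=int)
    )
    return by_lnc, by_gene


def edge_list(results: list[CisPair]) -> pd.DataFrame:
    """(source, interaction, target) rows for network-visualization import."""
    sig = [c for c in results if c.is_cis_target]
    return pd.DataFrame(
        {
            "source": [c.lncrna_id for c in sig],
            "interaction": ["cis" for _ in sig],
            "target": [c.mrna_gene_id for c in sig],
        }
    )
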