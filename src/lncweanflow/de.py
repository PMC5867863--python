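"""Two-group negative-binomial Wald differential expression.

A deliberately transparent NB test for a two-timepoint design
(pre-weaning D33 vs post-weaning D96): per-feature method-of-moments
dispersion on normalized counts, group means on the normalized scale
(pseudocount 0.5 when a group mean is zero), a Wald statistic
log2FC / SE with the standard error from the NB variance function
Var(K) = mu + alpha * mu^2 at the fitted means, and a two-sided
p-value from a Student-t reference on n_a + n_b - 2 degrees of freedom
(the finite-sample account of the moment-estimated dispersion; a
normal reference is measurably anti-conservative at n = 16 + 16),
corrected by Benjamini-Hochberg. There is no dispersion
shrinkage, independent filtering or outlier handling; those are
documented simplifications relative to full DESeq2-style machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncweanflow.expression import CountMatrix, SizeFactors

LOG2 = math.log(2.0)
PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    feature_id: str
    baseMean: float
    log2FC: float
    dispersion: float
    p: float
    p_bh: float
    significant: bool


def _group_masks(groups, group_a: str, group_b: str) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(groups)
    mask_a, mask_b = labels == group_a, labels == group_b
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"both groups {group_a!r}/{group_b!r} must be non-empty")
    return mask_a, mask_b


def estimate_dispersion(counts_i, sf, groups, group_a: str = "D33", group_b: str = "D96") -> float:
    """Method-of-moments NB dispersion for one feature.

    alpha = max(0, (pooled within-group variance - mean) / mean^2) on
    normalized counts; the grand mean supplies the mean term. Raises
    for an all-zero feature (alpha undefined).
    """
    q = np.asarray(counts_i, dtype=float) / np.asarray(sf, dtype=float)
    mask_a, mask_b = _group_masks(groups, group_a, group_b)
    m = q.mean()
    if m == 0:
        raise ValueError("zero mean: dispersion undefined")
    va = q[mask_a].var(ddof=1) if mask_a.sum() > 1 else 0.0
    vb = q[mask_b].var(ddof=1) if mask_b.sum() > 1 else 0.0
    dfa, dfb = mask_a.sum() - 1, mask_b.sum() - 1
    pooled_var = (dfa * va + dfb * vb) / max(1, dfa + dfb)
    return max(0.0, (pooled_var - m) / m**2)


def nb_wald_test(
    counts_i, sf, groups, alpha_i: float, group_a: str = "D33", group_b: str = "D96"
) -> tuple[float, float, float]:
    """(baseMean, log2FC, p) for one feature.

    log2FC is group_b over group_a (D96 vs D33). A zero group mean is
    replaced by the pseudocount before taking the ratio.
    """
    q = np.asarray(counts_i, dtype=float) / np.asarray(sf, dtype=float)
    mask_a, mask_b = _group_masks(groups, group_a, group_b)
    base_mean = float(q.mean())
    ma = max(float(q[mask_a].mean()), PSEUDOCOUNT) if q[mask_a].mean() == 0 else float(q[mask_a].mean())
    mb = max(float(q[mask_b].mean()), PSEUDOCOUNT) if q[mask_b].mean() == 0 else float(q[mask_b].mean())
    log2fc = math.log2(mb / ma)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    var_log = (1.0 / ma + alpha_i) / na + (1.0 / mb + alpha_i) / nb
    se = math.sqrt(var_log) / LOG2
    if se == 0:
        return base_mean, log2fc, 1.0
    z = log2fc / se
    df = max(1, na + nb - 2)
    p = float(2.0 * stats.t.sf(abs(z), df))
    return base_mean, log2fc, min(1.0, p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fc_from_log2fc(log2fc: float) -> float:
    """Signed fold change: sign(log2FC) * 2^|log2FC|; 1.0 at log2FC 0.

    Down-regulation is reported as a negative fold change, matching the
    paired log2FC / FC reporting convention.
    """
    if not math.isfinite(log2fc):
        raise ValueError("log2FC must be finite")
    if log2fc == 0:
        return 1.0
    return math.copysign(2.0 ** abs(log2fc), log2fc)


def run_de(
    cm: CountMatrix,
    sf: SizeFactors,
    feature_ids=None,
    group_a: str = "D33",
    group_b: str = "D96",
    sig_level: float = 0.05,
) -> pd.DataFrame:
    """Per-feature NB Wald DE table with BH correction.

    Vectorized over features; all-zero features are skipped with reason
    recorded in the ``skipped`` attribute of the returned frame. The
    frame has columns feature_id, baseMean, log2FC, FC, dispersion, p,
    p.BH, significant.
    """
    counts = cm.counts if feature_ids is None else cm.counts.loc[feature_ids]
    q = counts.to_numpy(dtype=float) / sf.factors.to_numpy()
    labels = cm.groups().to_numpy()
    mask_a, mask_b = _group_masks(labels, group_a, group_b)
    na, nb = int(mask_a.sum()), int(mask_b.sum())

    grand_mean = q.mean(axis=1)
    nonzero = grand_mean > 0
    qa, qb = q[:, mask_a], q[:, mask_b]
    va = qa.var(axis=1, ddof=1) if na > 1 else np.zeros(len(q))
    vb = qb.var(axis=1, ddof=1) if nb > 1 else np.zeros(len(q))
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / max(1, na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.maximum(0.0, (pooled_var - grand_mean) / grand_mean**2)
    ma = np.where(qa.mean(axis=1) == 0, PSEUDOCOUNT, qa.mean(axis=1))
    mb = np.where(qb.mean(axis=1) == 0, PSEUDOCOUNT, qb.mean(axis=1))
    log2fc = np.log2(mb / ma)
    var_log = (1.0 / ma + alpha) / na + (1.0 / mb + alpha) / nb
    se = np.sqrt(var_log) / LOG2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(z), max(1, na + nb - 2)))

    kept = counts.index[nonzero]
    p_kept = p[nonzero]
    p_bh = bh_adjust(p_kept)
    table = pd.DataFrame(
        {
            "feature_id": kept,
            "baseMean": grand_mean[nonzero],
            "log2FC": log2fc[nonzero],
            "FC": [fc_from_log2fc(x) for x in log2fc[nonzero]],
            "dispersion": alpha[nonzero],
            "p": p_kept,
            "p.BH": p_bh,
            "significant": p_bh < sig_level,
        }
    ).reset_index(drop=True)
    table.attrs["skipped"] = [
        (f, "zero_mean") for f in counts.index[~nonzero]
    ]
    return table
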