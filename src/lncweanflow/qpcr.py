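"""Relative qPCR quantification by the 2^-ddCt method.

Each sample's target cycle threshold is normalized to a housekeeping
gene (dCt), centered on the mean dCt of the reference condition
(ddCt), and expressed as a relative quantity RQ = 2^-ddCt. The
condition fold change is the mean RQ of the test condition, and group
comparison uses the pooled-variance two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DdctResult:
    per_sample: pd.DataFrame  # sample_id, condition, dCt, ddCt, RQ
    fold_change: float  # mean RQ of the test condition
    reference_condition: str
    test_condition: str


def read_ct_table(path) -> pd.DataFrame:
    """TSV with columns sample_id, gene, condition, and Ct replicate columns.

    Replicate columns (any column starting with ``ct``, case
    insensitive) are collapsed by their mean into a single ``Ct``
    column.
    """
    df = pd.read_csv(path, sep="\t")
    ct_cols = [c for c in df.columns if c.lower().startswith("ct")]
    if not ct_cols:
        raise ValueError("no Ct columns found (names must start with 'Ct')")
    out = df[["sample_id", "gene", "condition"]].copy()
    out["Ct"] = df[ct_cols].mean(axis=1)
    if (out["Ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return out


def ddct(
    ct: pd.DataFrame,
    target: str,
    housekeeper: str,
    reference_condition: str,
) -> DdctResult:
    """2^-ddCt relative quantification of ``target`` against ``housekeeper``.

    ``ct`` needs columns sample_id, gene, condition, Ct (triplicates
    already collapsed; see :func:`read_ct_table`). Every sample must
    carry both the target and the housekeeper.
    """
    tgt = ct[ct["gene"] == target].set_index("sample_id")
    hk = ct[ct["gene"] == housekeeper].set_index("sample_id")
    missing = set(tgt.index) - set(hk.index)
    if missing:
        raise ValueError(f"housekeeper {housekeeper!r} missing for samples {sorted(missing)}")
    if tgt.empty:
        raise ValueError(f"no Ct rows for target {target!r}")
    dct = tgt["Ct"] - hk.loc[tgt.index, "Ct"]
    condition = tgt["condition"]
    conditions = sorted(condition.unique())
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref_mean = dct[condition == reference_condition].mean()
    ddct_values = dct - ref_mean
    rq = np.power(2.0, -ddct_values)
    others = [c for c in conditions if c != reference_condition]
    if len(others) != 1:
        raise ValueError(f"expected exactly one test condition, got {others}")
    test_condition = others[0]
    per_sample = pd.DataFrame(
        {
            "sample_id": tgt.index,
            "condition": condition.to_numpy(),
            "dCt": dct.to_numpy(),
            "ddCt": ddct_values.to_numpy(),
            "RQ": rq.to_numpy(),
        }
    )
    fold_change = float(rq[condition == test_condition].mean())
    return DdctResult(per_sample, fold_change, reference_condition, test_condition)


def two_sample_t(rq_group_a, rq_group_b) -> tuple[float, float]:
    """Pooled-variance (homogeneous) two-sided two-sample t-test."""
    a = np.asarray(rq_group_a, dtype=float)
    b = np.asarray(rq_group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
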