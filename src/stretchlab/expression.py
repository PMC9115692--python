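"""Relative gene expression by the 2^-ddCt method.

Cycle thresholds (Ct) of a target gene are normalized to a housekeeping
reference gene (dCt = Ct_target - Ct_reference) and to a control group
(ddCt = dCt_sample - dCt_control); fold change is 2^-ddCt.  Replicates are
folded against the control-group mean dCt and summarized by the geometric
mean with a log2-space standard deviation (the error model for Ct values is
additive in cycles, hence lognormal in fold-change space).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CtRecord", "ddct_fold_change", "fold_change_table"]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference Ct (cycles) plus group label."""

    ct_target: float
    ct_reference: float
    group: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ValueError("Ct values must be finite")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(sample: CtRecord, control: CtRecord) -> float:
    """Fold change 2^-(dCt_sample - dCt_control); always positive."""
    return 2.0 ** -(sample.dct - control.dct)


def fold_change_table(
    ct: pd.DataFrame, control_group: str = "control"
) -> pd.DataFrame:
    """Per-gene fold changes of each group against the control group.

    ``ct`` needs columns ``group, gene, ct_target, ct_reference`` (one row
    per replicate).  Each replicate's dCt is compared with the
    control-group mean dCt for the same gene; the output has one row per
    (group, gene) with ``fold_change`` (geometric mean over replicates),
    ``log2_fold_change`` and ``log2_sd``.
    """
    required = {"group", "gene", "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    if not np.isfinite(ct[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    if control_group not in set(ct["group"]):
        raise ValueError(f"control group {control_group!r} not present")

    work = ct.assign(dct=ct["ct_target"] - ct["ct_reference"])
    control_mean = (
        work[work["group"] == control_group].groupby("gene")["dct"].mean()
    )
    rows = []
    for (group, gene), sub in work.groupby(["group", "gene"], sort=False):
        if gene not in control_mean.index:
            raise ValueError(f"gene {gene!r} absent from the control group")
        log2fc = -(sub["dct"].to_numpy() - control_mean[gene])
        rows.append(
            {
                "group": group,
                "gene": gene,
                "n_replicates": len(sub),
                "fold_change": float(2.0 ** np.mean(log2fc)),
                "log2_fold_change": float(np.mean(log2fc)),
                "log2_sd": float(np.std(log2fc, ddof=1)) if len(sub) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
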