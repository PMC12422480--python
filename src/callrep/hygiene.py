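"""Outlier neutralization for automatically extracted acoustic parameters.

Automatic extraction on noisy field recordings occasionally produces wild
values (e.g. a dominant-frequency jump onto a cicada band).  Rather than
dropping whole calls, each feature column is screened independently: values
whose absolute z-score — computed once from the raw column mean and SD —
exceeds a threshold (default 3.29, the two-sided 0.1% normal point) are
replaced by the raw column median.  A single pass; z-scores are not
recomputed after replacement.  The rule is global (no grouping by call type
or caller) and is applied to all 31 columns, MDS coordinates included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HygieneConfig", "HygieneReport", "replace_outliers"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HygieneConfig:
    z_threshold: float = 3.29
    replacement: str = "median"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.replacement != "median":
            raise ValueError("only median replacement is supported")


@dataclass
class HygieneReport:
    z_threshold: float
    n_values_replaced: int = 0
    n_calls_affected: int = 0
    per_parameter: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "z_threshold": self.z_threshold,
            "n_values_replaced": self.n_values_replaced,
            "n_calls_affected": self.n_calls_affected,
            "per_parameter": dict(self.per_parameter),
        }


def replace_outliers(
    table: pd.DataFrame, cfg: HygieneConfig = HygieneConfig()
) -> tuple[pd.DataFrame, HygieneReport]:
    """Median-replace extreme values per feature column; returns (table, report).

    Non-numeric columns (call_id, labels) pass through untouched.  A
    zero-variance column yields no replacements (its z-score is undefined).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 calls for outlier screening")
    out = table.copy()
    report = HygieneReport(z_threshold=cfg.z_threshold)
    affected = np.zeros(len(table), dtype=bool)
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            continue
        x = table[col].to_numpy(dtype=np.float64)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("column %r has zero variance; skipped", col)
            continue
        z = (x - x.mean()) / sd
        mask = np.abs(z) > cfg.z_threshold
        k = int(mask.sum())
        if k:
            out.loc[mask, col] = np.median(x)
            report.per_parameter[col] = k
            report.n_values_replaced += k
            affected |= mask
    report.n_calls_affected = int(affected.sum())
    return out, report
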