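"""Group statistics for condition comparisons.

The assay compares read-outs between the two tumor-chamber conditions with
the classical two-tailed unpaired Student's t-test (equal-variance pooled
form) at the 0.05 significance level; Welch's correction is available
behind a flag for unequal variances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["GroupSummary", "compare_groups", "summarize_groups"]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one metric in one condition and window."""

    metric: str
    condition: str
    window: str
    n: int
    mean: float
    sd: float

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n) if self.n > 0 else float("nan")


def compare_groups(
    values_a, values_b, *, welch: bool = False, alpha: float = ALPHA
) -> dict:
    """Two-sided unpaired two-sample t-test.

    Equal-variance (Student) form by default; ``welch=True`` drops the
    pooled-variance assumption. Returns t, p, df and a significance flag at
    ``alpha``; groups with fewer than 2 values yield missing results with a
    warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        logger.warning("compare_groups needs >= 2 values per group")
        return {"t": float("nan"), "p": float("nan"), "df": float("nan"), "significant": False}
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = len(a) + len(b) - 2 if not welch else float(res.df)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": float(df),
        "significant": bool(res.pvalue <= alpha),
    }


def summarize_groups(
    metrics: pd.DataFrame,
    value_col: str,
    *,
    by: tuple[str, ...] = ("side", "window"),
    condition_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """n / mean / sd / sem of one metric column grouped by side and window.

    ``condition_labels`` maps side -> condition name (e.g. {'left': 'NT',
    'right': 'RI'}) for reporting.
    """
    rows = []
    for keys, grp in metrics.groupby(list(by), dropna=False):
        vals = grp[value_col].dropna().to_numpy(dtype=float)
        keyd = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        side = keyd.get("side")
        condition = (condition_labels or {}).get(side, side)
        rows.append(
            {
                "metric": value_col,
                "condition": condition,
                **keyd,
                "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "sem": float(vals.std(ddof=1) / math.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
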