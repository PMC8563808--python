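"""Small shared statistical helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

__all__ = ["RmAnovaResult", "two_condition_rmanova", "round_half_up"]


@dataclass
class RmAnovaResult:
    """Two-condition repeated-measures ANOVA: F with df (1, n - 1)."""

    F: float
    df: tuple[int, int]
    p: float
    n: int


def two_condition_rmanova(a, b, warn_label: str = "pairs") -> RmAnovaResult:
    """Repeated-measures ANOVA over two within-subject conditions.

    Incomplete pairs are dropped listwise. For two conditions the F statistic
    equals the squared paired t statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < len(a):
        import warnings

        warnings.warn(f"dropping {len(a) - int(ok.sum())} incomplete {warn_label}", stacklevel=2)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    if np.allclose(a, b):
        return RmAnovaResult(F=0.0, df=(1, n - 1), p=1.0, n=n)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "condition": np.tile(["a", "b"], n),
            "value": np.column_stack([a, b]).ravel(),
        }
    )
    res = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return RmAnovaResult(
        F=float(row["F Value"]),
        df=(int(row["Num DF"]), int(row["Den DF"])),
        p=float(row["Pr > F"]),
        n=n,
    )


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at the given decimal place (reporting rule)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)
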