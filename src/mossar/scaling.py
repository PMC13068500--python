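"""Scale dependence of model performance and predictor importance.

Ordinary least squares of a per-scale quantity (BRT R² or a predictor's
relative-importance percentage) on log10 of subplot area, with a two-sided
t-test on the slope (df = n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ScaleRegression", "regress_vs_scale", "regress_table"]


@dataclass
class ScaleRegression:
    quantity: str
    slope: float  # per log10(m²)
    intercept: float
    p_slope: float
    r2: float
    n: int


def regress_vs_scale(values, areas, quantity: str = "value") -> ScaleRegression:
    """OLS of per-scale values on log10(area in m²)."""
    values = np.asarray(values, float)
    areas = np.asarray(areas, float)
    if len(values) != len(areas):
        raise ValueError("values and areas must have equal length")
    if len(np.unique(areas)) < 3:
        raise ValueError("need >= 3 distinct areas")
    if (areas <= 0).any():
        raise ValueError("areas must be positive")
    x = np.log10(areas)
    res = stats.linregress(x, values)
    if np.isnan(res.pvalue):  # constant values: zero slope, no evidence
        p = 1.0
    else:
        p = float(res.pvalue)
    return ScaleRegression(
        quantity=quantity,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_slope=p,
        r2=float(res.rvalue**2) if not np.isnan(res.rvalue) else 0.0,
        n=len(values),
    )


def regress_table(per_scale: pd.DataFrame, areas) -> pd.DataFrame:
    """Apply the scale regression to every column of a scales × quantities frame."""
    rows = []
    for col in per_scale.columns:
        reg = regress_vs_scale(per_scale[col].to_numpy(), areas, quantity=col)
        rows.append(
            {"quantity": reg.quantity, "slope": reg.slope, "intercept": reg.intercept,
             "p_slope": reg.p_slope, "r2": reg.r2, "n": reg.n}
        )
    return pd.DataFrame(rows).set_index("quantity")
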