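"""Correlation screening of network properties against adaptability.

Across subjects, every (network property, feature method) cell gets a
Pearson correlation with a two-sided p-value, and a significance flag
under the conjunctive rule  p < alpha  AND  |r| > r_min.  The default
r_min of 0.273 is the critical r of the two-sided 5% t-test computed
with df = 50 (the value quoted alongside a 50-subject cohort); the
conventional df = n-2 gives 0.279 at n = 50, and p-values here always
use df = n-2.  No multiple-testing correction is applied by default; an
optional Benjamini-Hochberg FDR column is available as a clearly
labelled extension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pearson", "critical_r", "screen", "DEFAULT_R_MIN"]

#: Default |r| gate of the conjunctive significance rule.
DEFAULT_R_MIN: float = 0.273


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform
    ``t = r sqrt(n-2) / sqrt(1-r^2)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("constant input; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def critical_r(alpha: float = 0.05, df: int = 50) -> float:
    """Smallest |r| reaching two-sided significance ``alpha`` at ``df``
    degrees of freedom: ``t_crit / sqrt(t_crit^2 + df)``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def screen(
    properties: pd.DataFrame,
    scores: pd.DataFrame,
    alpha: float = 0.05,
    r_min: float = DEFAULT_R_MIN,
    add_fdr: bool = False,
) -> pd.DataFrame:
    """Full r/p/significance grid: properties x methods.

    ``properties`` (subjects x network properties) and ``scores``
    (subjects x methods) must share their subject index.  Returns a tidy
    frame with one row per (property, method): columns ``r``, ``p`` and
    ``significant`` (p < alpha and |r| > r_min — negative correlations
    can be significant).  With ``add_fdr``, a ``p_fdr`` column
    (Benjamini-Hochberg across the whole grid, an extension to the base
    rule) is appended.
    """
    if not properties.index.equals(scores.index):
        raise ValueError("properties and scores must be indexed by the same subjects")
    rows = []
    for prop in properties.columns:
        for method in scores.columns:
            r, p = pearson(properties[prop], scores[method])
            rows.append(
                {
                    "property": prop,
                    "method": method,
                    "r": r,
                    "p": p,
                    "significant": bool(p < alpha and abs(r) > r_min),
                }
            )
    table = pd.DataFrame(rows)
    if add_fdr:
        from statsmodels.stats.multitest import multipletests

        table["p_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
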