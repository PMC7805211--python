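"""Shared statistical helpers: normality-gated correlation."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import DataError


def correlate(x, y, alpha: float = 0.05, method: str = "auto") -> tuple[float, float, str]:
    """Correlation with a Shapiro–Wilk normality gate.

    With ``method='auto'`` both vectors are Shapiro–Wilk tested; Pearson is
    used only when both pass at p > ``alpha``, otherwise Spearman.  Returns
    (coefficient, p, method_used).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("correlate requires equal-length 1-D vectors")
    if x.size < 4:
        raise DataError("correlate requires n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("correlation undefined for a constant vector")
    if method == "auto":
        px = stats.shapiro(x).pvalue
        py = stats.shapiro(y).pvalue
        method = "pearson" if (px > alpha and py > alpha) else "spearman"
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise DataError(f"unknown correlation method '{method}'")
    return float(r.statistic), float(r.pvalue), method
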