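"""Agreement statistics for method comparison."""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr

from .errors import InputError


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient, 2|A∩B| / (|A| + |B|).

    Defined as 1 when both masks are empty (perfect agreement on nothing).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InputError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def bland_altman(x, y) -> tuple[float, float]:
    """Bland–Altman bias of x versus y: (mean, sample SD) of x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("sequences must have equal length")
    if x.size < 2:
        raise InputError("need at least 2 paired observations")
    d = x - y
    return float(d.mean()), float(d.std(ddof=1))


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient (linear-regression R)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need >= 3 paired observations of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance in an input sequence")
    return float(pearsonr(x, y).statistic)
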