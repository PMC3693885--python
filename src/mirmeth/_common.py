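"""Small shared numerics used across pipeline stages."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

#: pseudo-floor applied to expression signals before taking the natural log;
#: processed array signals can be <= 0 after background correction.
LOG_EPSILON = 1e-8

#: clamp for normal-quantile scores derived from P-values.
Z_CLAMP = 8.0

#: smallest P-value ever reported; keeps every P in (0, 1].
P_FLOOR = 1e-300


def safe_log(x: np.ndarray, epsilon: float = LOG_EPSILON) -> np.ndarray:
    """Natural log with a pseudo-floor at ``epsilon``."""
    return np.log(np.maximum(np.asarray(x, dtype=float), epsilon))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P-values.

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    adjusted = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum() > 0:
        adjusted[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adjusted


def clip_pvalue(p):
    """Clip P-values into (0, 1] without disturbing NaN."""
    return np.clip(p, P_FLOOR, 1.0)
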