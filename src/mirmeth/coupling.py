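"""Coupling between miRNA-mediated regulation and targeting-specific methylation.

Two directional P-value tables — one from the mRNA layer, one from
methylation, same region pair — are compared across miRNAs in two ways:

* **mean-rank correlation ρ**: within each subject the P-values are ranked
  across miRNAs (average ranks for ties, rescaled to (0, 1] so subjects with
  missing miRNAs stay comparable), the per-miRNA ranks are averaged over
  subjects, and the two per-miRNA profiles are Spearman-correlated;
* **per-subject correlations ρ_j and their RMS Δρ**: Spearman between the two
  tables' columns, subject by subject, summarised by the root mean square.
  Δρ can exceed |mean ρ_j| when positive and negative per-subject
  correlations cancel in the mean, which is exactly the situation the RMS is
  meant to expose.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .targeting import DirectionalPValueTable

logger = logging.getLogger(__name__)


@dataclass
class CorrelationSummary:
    """Mean-rank ρ, per-subject ρ_j, and Δρ = RMS(ρ_j) for one region pair."""

    region_pair: tuple[str, str]
    direction: str
    rho_mean_rank: float
    rho_per_subject: pd.Series
    delta_rho: float
    p_value: float
    m_used: int
    n_subjects: int
    rho_degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "region_ell": self.region_pair[0],
            "region_ellprime": self.region_pair[1],
            "direction": self.direction,
            "rho_mean_rank": self.rho_mean_rank,
            "delta_rho": self.delta_rho,
            "p_value": self.p_value,
            "m_used": self.m_used,
            "n_subjects": self.n_subjects,
        }


def mean_rank_profile(table: DirectionalPValueTable, direction: str) -> pd.Series:
    """Per-miRNA mean of within-subject P-value ranks, rescaled to (0, 1].

    Within each subject column the non-missing P-values are ranked ascending
    with average ranks for ties, divided by the number of non-missing entries,
    and the rescaled ranks are averaged over subjects per miRNA. miRNAs
    missing in every subject yield NaN.
    """
    frame = table.direction(direction)
    ranks = np.full(frame.shape, np.nan)
    values = frame.to_numpy()
    for j in range(values.shape[1]):
        col = values[:, j]
        ok = np.isfinite(col)
        if ok.sum() == 0:
            continue
        ranks[ok, j] = stats.rankdata(col[ok]) / ok.sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        profile = np.nanmean(ranks, axis=1)
    return pd.Series(profile, index=frame.index, name=f"mean_rank_{direction}")


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson on average ranks.

    Returns NaN with a warning when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spearman: constant input vector; correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def correlation_pvalue(rho: float, m: int) -> float:
    """Two-sided P for a Spearman ρ over ``m`` pairs via the t approximation
    t = ρ·√((m−2)/(1−ρ²)) with m−2 degrees of freedom.

    |ρ| = 1 returns exactly 0.0 (degenerate; flagged by callers).
    """
    if m < 4:
        raise ValueError("need m >= 4")
    if not np.isfinite(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((m - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=m - 2))


def coupling_correlation(
    mrna_table: DirectionalPValueTable,
    methyl_table: DirectionalPValueTable,
    direction: str = "greater",
) -> CorrelationSummary:
    """Mean-rank ρ, per-subject ρ_j and Δρ between the two layers' tables."""
    if set(mrna_table.mirna_ids) != set(methyl_table.mirna_ids):
        raise ValueError("tables must share the same miRNA set")
    if mrna_table.subject_ids != methyl_table.subject_ids:
        raise ValueError("tables must share the same subjects")
    if tuple(mrna_table.region_pair) != tuple(methyl_table.region_pair):
        raise ValueError("tables must refer to the same region pair")

    methyl = DirectionalPValueTable(
        layer=methyl_table.layer,
        region_pair=methyl_table.region_pair,
        p_less=methyl_table.p_less.loc[mrna_table.mirna_ids],
        p_greater=methyl_table.p_greater.loc[mrna_table.mirna_ids],
        method=methyl_table.method,
    )
    prof_x = mean_rank_profile(mrna_table, direction)
    prof_y = mean_rank_profile(methyl, direction)
    ok = prof_x.notna() & prof_y.notna()
    m_used = int(ok.sum())
    rho = spearman(prof_x[ok], prof_y[ok])
    degenerate = np.isfinite(rho) and abs(rho) >= 1.0

    px = mrna_table.direction(direction).to_numpy()
    py = methyl.direction(direction).to_numpy()
    rho_j = []
    for j in range(px.shape[1]):
        both = np.isfinite(px[:, j]) & np.isfinite(py[:, j])
        if both.sum() >= 3 and np.ptp(px[both, j]) > 0 and np.ptp(py[both, j]) > 0:
            rho_j.append(float(stats.spearmanr(px[both, j], py[both, j]).statistic))
        else:
            rho_j.append(float("nan"))
    rho_j = pd.Series(rho_j, index=mrna_table.subject_ids, name="rho_j")
    delta_rho = float(np.sqrt(np.nanmean(np.square(rho_j.to_numpy()))))

    return CorrelationSummary(
        region_pair=tuple(mrna_table.region_pair),
        direction=direction,
        rho_mean_rank=rho,
        rho_per_subject=rho_j,
        delta_rho=delta_rho,
        p_value=correlation_pvalue(rho, m_used) if m_used >= 4 else float("nan"),
        m_used=m_used,
        n_subjects=len(mrna_table.subject_ids),
        rho_degenerate=bool(degenerate),
    )
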