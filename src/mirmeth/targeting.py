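"""Directional per-miRNA, per-subject target-set statistics.

For a region pair (l, l') and one subject, every gene carries a paired
difference Δ_g — the natural-log expression ratio for expression layers, or
the plain beta difference for methylation. For each miRNA m the genes split
into its targets and all remaining genes, and two one-sided P-values are
computed: P_greater (targets' Δ stochastically greater than non-targets',
i.e. targets upregulated / hypermethylated in l) and P_less (the opposite
tail). Stacked over miRNAs and subjects these form the directional P-value
table that the coupling and regression stages consume.

The default test is the Wilcoxon rank-sum with tie and continuity
corrections, switching to the exact null distribution when the smaller group
has at most 10 members; a Welch t alternative is exposed as well. The
rank-sum path ranks each subject's Δ vector once and computes every miRNA's
statistic from target rank sums, so a full table costs one ranking per
subject plus a masked matrix product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._common import LOG_EPSILON, bh_adjust, clip_pvalue, safe_log
from .io import EXPRESSION_LAYERS, LAYER_METHYLATION, AlignedStudy

logger = logging.getLogger(__name__)

METHODS = ("auto", "ranksum_exact", "ranksum_normal", "ttest")
#: smaller-group size at or below which "auto" uses the exact rank-sum null
EXACT_GROUP_CUTOFF = 10


@dataclass
class DirectionalPValueTable:
    """P_less / P_greater matrices (miRNA × subject) for one layer and region pair."""

    layer: str
    region_pair: tuple[str, str]
    p_less: pd.DataFrame
    p_greater: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        if not (
            self.p_less.index.equals(self.p_greater.index)
            and self.p_less.columns.equals(self.p_greater.columns)
        ):
            raise ValueError("p_less and p_greater must share index and columns")
        for frame in (self.p_less, self.p_greater):
            arr = frame.to_numpy()
            finite = arr[np.isfinite(arr)]
            if ((finite <= 0) | (finite > 1)).any():
                raise ValueError("P-values must lie in (0, 1]")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.p_less.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.p_less.columns)

    def direction(self, which: str) -> pd.DataFrame:
        if which not in ("less", "greater"):
            raise ValueError("direction must be 'less' or 'greater'")
        return self.p_less if which == "less" else self.p_greater

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for direction, frame in (("less", self.p_less), ("greater", self.p_greater)):
            long = frame.reset_index(names="mirna_id").melt(
                id_vars="mirna_id", var_name="subject_id", value_name="p"
            )
            long["direction"] = direction
            rows.append(long)
        out = pd.concat(rows, ignore_index=True).pivot_table(
            index=["mirna_id", "subject_id"],
            columns="direction",
            values="p",
            dropna=False,
        )
        out = out.rename(columns={"less": "p_less", "greater": "p_greater"}).reset_index()
        out.columns.name = None
        out.insert(0, "layer", self.layer)
        out.insert(1, "region_ell", self.region_pair[0])
        out.insert(2, "region_ellprime", self.region_pair[1])
        out["method"] = self.method
        return out.sort_values(["mirna_id", "subject_id"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "DirectionalPValueTable":
        layers = frame["layer"].unique()
        pairs = frame[["region_ell", "region_ellprime"]].drop_duplicates()
        if len(layers) != 1 or len(pairs) != 1:
            raise ValueError("long frame must hold exactly one layer and region pair")
        p_less = frame.pivot(index="mirna_id", columns="subject_id", values="p_less")
        p_greater = frame.pivot(index="mirna_id", columns="subject_id", values="p_greater")
        for f in (p_less, p_greater):
            f.index.name = None
            f.columns.name = None
        return cls(
            layer=layers[0],
            region_pair=(pairs.iloc[0, 0], pairs.iloc[0, 1]),
            p_less=p_less,
            p_greater=p_greater,
            method=frame["method"].iloc[0],
        )


# ---------------------------------------------------------------------------
# per-gene paired differences


def _delta_matrix(
    study: AlignedStudy,
    layer: str,
    region_pair: tuple[str, str],
    subjects: list[str],
    epsilon: float = LOG_EPSILON,
) -> pd.DataFrame:
    """Gene × subject matrix of paired differences; genes with any missing
    value in a used sample are dropped (logged)."""
    om = study.layer(layer)
    ell, ellprime = region_pair
    cols_l = [study.sample_id(s, ell) for s in subjects]
    cols_lp = [study.sample_id(s, ellprime) for s in subjects]
    left = om.values[cols_l].to_numpy()
    right = om.values[cols_lp].to_numpy()
    if layer in EXPRESSION_LAYERS:
        delta = safe_log(left, epsilon) - safe_log(right, epsilon)
    else:
        delta = left - right
    frame = pd.DataFrame(delta, index=om.values.index, columns=subjects)
    keep = frame.notna().all(axis=1)
    if (~keep).any():
        logger.info(
            "layer %s pair %s–%s: dropped %d feature(s) with missing values",
            layer,
            ell,
            ellprime,
            int((~keep).sum()),
        )
    return frame.loc[keep]


def per_gene_delta(
    study: AlignedStudy,
    layer: str,
    region_pair: tuple[str, str],
    subject: str,
    epsilon: float = LOG_EPSILON,
) -> pd.Series:
    """Per-gene paired difference Δ_g for one subject.

    Expression layers: Δ_g = log(x_gl) − log(x_gl′) with pseudo-floor
    ``epsilon``; methylation: Δ_g = beta_gl − beta_gl′.
    """
    if subject not in study.paired_subjects(region_pair):
        raise ValueError(
            f"subject {subject!r} is not paired for regions {region_pair}"
        )
    return _delta_matrix(study, layer, tuple(region_pair), [subject], epsilon).iloc[:, 0]


# ---------------------------------------------------------------------------
# one-sided two-sample tests


def _ranksum_normal_from_ranks(
    rank_sum: np.ndarray,
    n1: np.ndarray,
    n_total: int,
    tie_term: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Tie- and continuity-corrected normal rank-sum P-values.

    ``rank_sum`` holds the target groups' rank sums (average ranks over the
    pooled vector of ``n_total`` values, ties contributing ``tie_term`` =
    Σ(t³−t)). Returns (p_less, p_greater).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = n_total - n1
    u1 = rank_sum - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.sqrt(var)
        z_greater = (u1 - mu - 0.5) / sd
        z_less = (u1 - mu + 0.5) / sd
        p_greater = stats.norm.sf(z_greater)
        p_less = stats.norm.cdf(z_less)
    degenerate = var <= 0
    p_greater = np.where(degenerate, np.nan, p_greater)
    p_less = np.where(degenerate, np.nan, p_less)
    return clip_pvalue(p_less), clip_pvalue(p_greater)


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def target_set_test(
    delta,
    targets,
    direction: str,
    method: str = "auto",
) -> float:
    """One-sided P that targets' Δ are stochastically greater (or less) than
    non-targets' Δ.

    ``delta`` may be a pandas Series indexed by gene id with ``targets`` a set
    of gene ids, or a plain array with ``targets`` a boolean mask. NaN deltas
    are excluded. An empty target or complement group yields NaN (a missing
    entry, not an exception).
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if isinstance(delta, pd.Series):
        mask = delta.index.isin(set(targets))
        values = delta.to_numpy(dtype=float)
    else:
        values = np.asarray(delta, dtype=float)
        mask = np.asarray(targets, dtype=bool)
    finite = np.isfinite(values)
    values, mask = values[finite], mask[finite]
    x, y = values[mask], values[~mask]
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    use = method
    if method == "auto":
        use = "ranksum_exact" if min(len(x), len(y)) <= EXACT_GROUP_CUTOFF else "ranksum_normal"
    if use == "ttest":
        if np.ptp(values) == 0:
            return float("nan")
        res = stats.ttest_ind(x, y, equal_var=False, alternative=direction)
        return float(clip_pvalue(res.pvalue))
    if use == "ranksum_exact":
        if np.ptp(values) == 0:
            return float("nan")
        res = stats.mannwhitneyu(x, y, alternative=direction, method="exact")
        return float(clip_pvalue(res.pvalue))
    ranks = stats.rankdata(values)
    p_less, p_greater = _ranksum_normal_from_ranks(
        np.array([ranks[mask].sum()]),
        np.array([mask.sum()]),
        len(values),
        _tie_term(values),
    )
    return float(p_less[0] if direction == "less" else p_greater[0])


def compute_pvalue_table(
    study: AlignedStudy,
    layer: str,
    region_pair: tuple[str, str],
    method: str = "auto",
    epsilon: float = LOG_EPSILON,
) -> DirectionalPValueTable:
    """Both directional P-values for every (miRNA, paired subject).

    miRNAs with an empty effective target set (or empty complement) after
    missing-value filtering carry NaN rows.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    region_pair = tuple(region_pair)
    subjects = study.paired_subjects(region_pair)
    if not subjects:
        raise ValueError(f"no paired subjects for region pair {region_pair}")
    deltas = _delta_matrix(study, layer, region_pair, subjects, epsilon)
    genes = deltas.index
    gene_pos = pd.Index(genes)
    mirnas = study.target_map.mirna_ids
    masks = np.zeros((len(mirnas), len(genes)), dtype=bool)
    for i, m in enumerate(mirnas):
        idx = gene_pos.get_indexer_for(sorted(study.target_map.targets[m]))
        masks[i, idx[idx >= 0]] = True
    n1 = masks.sum(axis=1)
    n_total = len(genes)
    valid = (n1 > 0) & (n1 < n_total)

    p_less = np.full((len(mirnas), len(subjects)), np.nan)
    p_greater = np.full((len(mirnas), len(subjects)), np.nan)
    values = deltas.to_numpy()

    if method in ("auto", "ranksum_normal"):
        for j in range(len(subjects)):
            col = values[:, j]
            ranks = stats.rankdata(col)
            rank_sums = masks[valid] @ ranks
            pl, pg = _ranksum_normal_from_ranks(
                rank_sums, n1[valid], n_total, _tie_term(col)
            )
            p_less[valid, j] = pl
            p_greater[valid, j] = pg
        if method == "auto":
            small = valid & (np.minimum(n1, n_total - n1) <= EXACT_GROUP_CUTOFF)
            for i in np.nonzero(small)[0]:
                for j in range(len(subjects)):
                    p_less[i, j] = target_set_test(
                        values[:, j], masks[i], "less", "ranksum_exact"
                    )
                    p_greater[i, j] = target_set_test(
                        values[:, j], masks[i], "greater", "ranksum_exact"
                    )
    else:
        for i in np.nonzero(valid)[0]:
            for j in range(len(subjects)):
                p_less[i, j] = target_set_test(values[:, j], masks[i], "less", method)
                p_greater[i, j] = target_set_test(values[:, j], masks[i], "greater", method)

    return DirectionalPValueTable(
        layer=layer,
        region_pair=region_pair,
        p_less=pd.DataFrame(p_less, index=mirnas, columns=subjects),
        p_greater=pd.DataFrame(p_greater, index=mirnas, columns=subjects),
        method=method,
    )


# ---------------------------------------------------------------------------
# direction-count summaries


@dataclass
class DirectionSummary:
    """Counts of miRNAs whose targets shift significantly in each direction."""

    layer: str
    region_pair: tuple[str, str]
    n_up: int
    n_down: int
    net_direction: str
    per_mirna: pd.DataFrame

    def as_row(self) -> dict:
        return {
            "layer": self.layer,
            "region_ell": self.region_pair[0],
            "region_ellprime": self.region_pair[1],
            "n_up": self.n_up,
            "n_down": self.n_down,
            "net_direction": self.net_direction,
        }


def net_direction(n_up: int, n_down: int) -> str:
    """The arrow logic: the larger directional count wins; ties give 'none'."""
    if n_up > n_down:
        return "up"
    if n_down > n_up:
        return "down"
    return "none"


def summarize_direction_counts(
    table: DirectionalPValueTable,
    alpha: float = 0.05,
    correction: str = "BH",
) -> DirectionSummary:
    """Per-miRNA median-over-subjects directional P-values, corrected across
    miRNAs, counted per direction.

    n_up counts miRNAs significant in the 'greater' channel (targets
    upregulated / hypermethylated in the first region), n_down the 'less'
    channel; net_direction compares the two counts.
    """
    if correction not in ("none", "BH"):
        raise ValueError("correction must be 'none' or 'BH'")
    med_greater = table.p_greater.median(axis=1, skipna=True)
    med_less = table.p_less.median(axis=1, skipna=True)
    if correction == "BH":
        adj_greater = bh_adjust(med_greater.to_numpy())
        adj_less = bh_adjust(med_less.to_numpy())
    else:
        adj_greater = med_greater.to_numpy()
        adj_less = med_less.to_numpy()
    sig_up = np.nan_to_num(adj_greater, nan=1.0) <= alpha
    sig_down = np.nan_to_num(adj_less, nan=1.0) <= alpha
    per_mirna = pd.DataFrame(
        {
            "median_p_greater": med_greater,
            "adj_p_greater": adj_greater,
            "significant_up": sig_up,
            "median_p_less": med_less,
            "adj_p_less": adj_less,
            "significant_down": sig_down,
        },
        index=table.p_greater.index,
    )
    n_up, n_down = int(sig_up.sum()), int(sig_down.sum())
    return DirectionSummary(
        layer=table.layer,
        region_pair=table.region_pair,
        n_up=n_up,
        n_down=n_down,
        net_direction=net_direction(n_up, n_down),
        per_mirna=per_mirna,
    )
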