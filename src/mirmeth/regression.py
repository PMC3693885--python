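"""Per-miRNA multivariate regression and Table-1-style selection.

For each miRNA and region pair, a per-subject regulation signal is regressed
on the per-subject methylation signal, the miRNA's differential expression,
and the subject's gender and (centered) age:

    y_j ~ intercept + meth_j + dmir_j + gender_j + age_j

The directional P-value pair (P_less, P_greater) of each layer is collapsed
into a single signed score z = Φ⁻¹(P_less) − Φ⁻¹(P_greater) (each quantile
clamped to ±8): positive when the targets are upregulated /
hypermethylated in the first region, negative in the opposite direction,
zero when the two tails agree. dmir_j = log(x_mjl / x_mjl') with the same
pseudo-floor used throughout.

Selection keeps miRNAs whose dmir coefficient survives Benjamini–Hochberg
across miRNAs (optionally dmir-or-meth), and labels them *reciprocal* when
the dmir coefficient is negative (miRNA up ⟹ targets down, the canonical
suppressive direction) and *nonreciprocal* otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._common import LOG_EPSILON, Z_CLAMP, bh_adjust, safe_log
from .io import AlignedStudy
from .targeting import DirectionalPValueTable

logger = logging.getLogger(__name__)

PREDICTORS = ("meth", "dmir", "gender", "age")
COEFFICIENTS = ("intercept",) + PREDICTORS
RECIPROCAL = "reciprocal"
NONRECIPROCAL = "nonreciprocal"


def signed_regulation_score(p_less, p_greater, clamp: float = Z_CLAMP):
    """Signed normal-quantile score of a directional P-value pair.

    z = Φ⁻¹(p_less) − Φ⁻¹(p_greater), each quantile clamped to ±``clamp``.
    Positive ⟺ targets up (small p_greater); antisymmetric in its arguments;
    NaN propagates.
    """
    ql = np.clip(stats.norm.ppf(p_less), -clamp, clamp)
    qg = np.clip(stats.norm.ppf(p_greater), -clamp, clamp)
    return ql - qg


@dataclass
class RegressionDesign:
    """Per-subject response and predictors for one miRNA and region pair."""

    mirna_id: str
    region_pair: tuple[str, str]
    frame: pd.DataFrame  # index subject_id; columns y, meth, dmir, gender, age

    def __post_init__(self) -> None:
        needed = {"y", *PREDICTORS}
        missing = needed - set(self.frame.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")


@dataclass
class RegressionResult:
    """OLS fit of one miRNA's design, with selection annotations."""

    mirna_id: str
    region_pair: tuple[str, str]
    params: pd.Series
    pvalues: pd.Series
    n_subjects: int
    r_squared: float
    adj_pvalues: pd.Series | None = None
    selected: bool = False
    label: str | None = None
    _extra: dict = field(default_factory=dict, repr=False)

    def as_row(self) -> dict:
        row = {
            "mirna_id": self.mirna_id,
            "region_ell": self.region_pair[0],
            "region_ellprime": self.region_pair[1],
            "n_subjects": self.n_subjects,
            "r_squared": self.r_squared,
        }
        for c in COEFFICIENTS:
            row[f"coef_{c}"] = self.params[c]
            row[f"p_{c}"] = self.pvalues[c]
            row[f"adj_p_{c}"] = (
                self.adj_pvalues[c] if self.adj_pvalues is not None else np.nan
            )
        row["selected"] = self.selected
        row["label"] = self.label if self.label is not None else ""
        return row


def build_design(
    study: AlignedStudy,
    mrna_table: DirectionalPValueTable,
    methyl_table: DirectionalPValueTable,
    region_pair: tuple[str, str],
    epsilon: float = LOG_EPSILON,
) -> list[RegressionDesign]:
    """One RegressionDesign per miRNA with usable data.

    miRNAs absent from the miRNA expression layer, or with an all-missing
    P-value row in either table, are skipped with a warning.
    """
    region_pair = tuple(region_pair)
    subjects = study.paired_subjects(region_pair)
    if mrna_table.subject_ids != subjects or methyl_table.subject_ids != subjects:
        raise ValueError("P-value tables are not aligned to the study's paired subjects")
    ann = study.annotation.table.set_index("subject_id")
    first = ann[~ann.index.duplicated(keep="first")]
    age = first.loc[subjects, "age"].astype(float)
    age_centered = age - age.mean()
    gender = (first.loc[subjects, "gender"] == "female").astype(float)

    mirna_values = study.mirna.values
    cols_l = [study.sample_id(s, region_pair[0]) for s in subjects]
    cols_lp = [study.sample_id(s, region_pair[1]) for s in subjects]

    y_all = signed_regulation_score(
        mrna_table.p_less.to_numpy(), mrna_table.p_greater.to_numpy()
    )
    meth_all = signed_regulation_score(
        methyl_table.p_less.loc[mrna_table.mirna_ids].to_numpy(),
        methyl_table.p_greater.loc[mrna_table.mirna_ids].to_numpy(),
    )

    designs: list[RegressionDesign] = []
    for i, mirna in enumerate(mrna_table.mirna_ids):
        if mirna not in mirna_values.index:
            logger.warning("miRNA %s absent from the miRNA expression layer; skipped", mirna)
            continue
        y = y_all[i]
        meth = meth_all[i]
        if not (np.isfinite(y).any() and np.isfinite(meth).any()):
            logger.warning("miRNA %s has all-missing P-values; skipped", mirna)
            continue
        dmir = (
            safe_log(mirna_values.loc[mirna, cols_l].to_numpy(), epsilon)
            - safe_log(mirna_values.loc[mirna, cols_lp].to_numpy(), epsilon)
        )
        frame = pd.DataFrame(
            {
                "y": y,
                "meth": meth,
                "dmir": dmir,
                "gender": gender.to_numpy(),
                "age": age_centered.to_numpy(),
            },
            index=pd.Index(subjects, name="subject_id"),
        ).dropna()
        if len(frame) < len(PREDICTORS) + 2:
            logger.warning("miRNA %s: too few complete subjects (%d); skipped", mirna, len(frame))
            continue
        designs.append(RegressionDesign(mirna_id=mirna, region_pair=region_pair, frame=frame))
    return designs


def fit_mirna_regression(design: RegressionDesign) -> RegressionResult:
    """Ordinary least squares with two-sided t tests on each coefficient."""
    X = design.frame[list(PREDICTORS)].to_numpy()
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = ("intercept",) + PREDICTORS
        _, r = np.linalg.qr(X)
        bad = [names[k] for k in np.nonzero(np.abs(np.diag(r)) < 1e-10)[0]]
        raise ValueError(
            f"rank-deficient design for miRNA {design.mirna_id}: "
            f"collinear column(s) {bad or list(names)}"
        )
    fit = sm.OLS(design.frame["y"].to_numpy(), X).fit()
    index = pd.Index(COEFFICIENTS)
    return RegressionResult(
        mirna_id=design.mirna_id,
        region_pair=design.region_pair,
        params=pd.Series(fit.params, index=index),
        pvalues=pd.Series(np.clip(fit.pvalues, np.finfo(float).tiny, 1.0), index=index),
        n_subjects=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )


def select_mirnas(
    results: list[RegressionResult],
    alpha: float = 0.05,
    correction: str = "BH",
    criterion: str = "dmir",
) -> list[RegressionResult]:
    """Select miRNAs whose differential expression (optionally: or
    methylation) coefficient survives correction across miRNAs; annotate all
    results in place and return the selected subset.

    Adjusted P-values are computed within each coefficient, across miRNAs.
    Selected miRNAs are labelled reciprocal (dmir coefficient < 0) or
    nonreciprocal.
    """
    if correction not in ("BH", "none"):
        raise ValueError("correction must be 'BH' or 'none'")
    if criterion not in ("dmir", "dmir_or_meth"):
        raise ValueError("criterion must be 'dmir' or 'dmir_or_meth'")
    if not results:
        return []
    for coef in COEFFICIENTS:
        raw = np.array([r.pvalues[coef] for r in results])
        adj = bh_adjust(raw) if correction == "BH" else raw
        for r, a in zip(results, adj):
            if r.adj_pvalues is None:
                r.adj_pvalues = pd.Series(np.nan, index=pd.Index(COEFFICIENTS))
            r.adj_pvalues[coef] = a
    selected = []
    for r in results:
        hit = r.adj_pvalues["dmir"] <= alpha
        if criterion == "dmir_or_meth":
            hit = hit or r.adj_pvalues["meth"] <= alpha
        r.selected = bool(hit)
        if r.selected:
            r.label = RECIPROCAL if r.params["dmir"] < 0 else NONRECIPROCAL
            selected.append(r)
        else:
            r.label = None
    return selected


def results_frame(results: list[RegressionResult]) -> pd.DataFrame:
    rows = [r.as_row() for r in results]
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(
            ["region_ell", "region_ellprime", "mirna_id"], kind="stable"
        ).reset_index(drop=True)
    return frame
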