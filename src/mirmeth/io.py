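"""Reading, validating and assembling the multi-layer study inputs.

All tabular inputs are plain TSV: feature-by-sample matrices with a header
row of sample ids, a sample annotation table, a two-column miRNA→target map,
and GMT pathway files (handled in :mod:`mirmeth.enrichment`).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYER_MRNA = "mrna"
LAYER_MIRNA = "mirna"
LAYER_METHYLATION = "methylation"
LAYERS = (LAYER_MRNA, LAYER_MIRNA, LAYER_METHYLATION)
#: layers on a positive signal scale; the log is taken downstream.
EXPRESSION_LAYERS = (LAYER_MRNA, LAYER_MIRNA)

ANNOTATION_COLUMNS = ("sample_id", "subject_id", "region", "age", "gender")
GENDERS = ("male", "female")


class ValidationError(ValueError):
    """An input violated a structural invariant."""


def _check_unique(ids, what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups.index[:5]))}")


@dataclass
class OmicsMatrix:
    """One numeric omics layer, features × samples.

    Expression layers (mrna, mirna) are on a positive signal scale;
    methylation is on the beta scale in [0, 1]. NaN marks a missing
    measurement; infinities are rejected.
    """

    layer_name: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer_name not in LAYERS:
            raise ValidationError(
                f"unknown layer {self.layer_name!r}; expected one of {LAYERS}"
            )
        _check_unique(self.values.index, f"feature id in layer {self.layer_name}")
        _check_unique(self.values.columns, f"sample id in layer {self.layer_name}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.values.map(lambda v: not isinstance(v, (int, float, np.number)))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValidationError(
                f"non-numeric cell in layer {self.layer_name} at feature "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        if np.isinf(arr).any():
            raise ValidationError(f"infinite value in layer {self.layer_name}")
        if self.layer_name == LAYER_METHYLATION:
            with np.errstate(invalid="ignore"):
                out = (arr < 0) | (arr > 1)
            if np.nan_to_num(out, nan=0).any():
                r, c = np.argwhere(np.nan_to_num(out, nan=0)).tolist()[0]
                raise ValidationError(
                    f"methylation beta outside [0, 1] at feature "
                    f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleAnnotationTable:
    """Per-sample metadata: subject, region label, age (years), gender."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing column(s): {', '.join(missing)}")
        self.table = self.table.loc[:, list(ANNOTATION_COLUMNS)].reset_index(drop=True)
        _check_unique(self.table["sample_id"], "sample_id in annotation")
        if (self.table["age"] < 0).any():
            bad = self.table.loc[self.table["age"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"negative age for sample {bad!r}")
        bad_gender = ~self.table["gender"].isin(GENDERS)
        if bad_gender.any():
            raise ValidationError(
                f"gender must be one of {GENDERS}; got "
                f"{self.table.loc[bad_gender, 'gender'].iloc[0]!r}"
            )
        dup = self.table.duplicated(subset=["subject_id", "region"], keep=False)
        if dup.any():
            row = self.table.loc[dup].iloc[0]
            raise ValidationError(
                f"subject {row['subject_id']!r} has more than one sample in "
                f"region {row['region']!r}"
            )

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def sample_for(self, subject_id: str, region: str) -> str | None:
        hit = self.table[
            (self.table["subject_id"] == subject_id) & (self.table["region"] == region)
        ]
        return None if hit.empty else hit["sample_id"].iloc[0]


@dataclass
class TargetMap:
    """Mapping miRNA id → set of target gene ids (post universe intersection)."""

    targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            if not genes:
                raise ValidationError(f"miRNA {mirna!r} retained with empty target set")

    @property
    def n_mirnas(self) -> int:
        """M, the number of miRNAs with at least one retained target."""
        return len(self.targets)

    @property
    def mirna_ids(self) -> list[str]:
        return sorted(self.targets)

    def gene_universe(self) -> frozenset[str]:
        return frozenset(itertools.chain.from_iterable(self.targets.values()))


@dataclass
class AlignedStudy:
    """The three layers, the annotation, and the target map, subject-paired.

    A subject is *paired* for region pair (l, l') when it has a sample in
    both regions and those samples are present in all three layers.
    """

    mrna: OmicsMatrix
    mirna: OmicsMatrix
    methylation: OmicsMatrix
    annotation: SampleAnnotationTable
    target_map: TargetMap
    _paired: dict[tuple[str, str], list[str]] = field(default_factory=dict, repr=False)

    MIN_PAIRED_SUBJECTS = 3

    def __post_init__(self) -> None:
        known = set(self.annotation.sample_ids)
        for layer in (self.mrna, self.mirna, self.methylation):
            unseen = [s for s in layer.sample_ids if s not in known]
            if unseen:
                raise ValidationError(
                    f"sample id(s) in layer {layer.layer_name} missing from "
                    f"annotation: {', '.join(unseen[:5])}"
                )
        self._paired = self._pair_subjects()

    def layer(self, layer_name: str) -> OmicsMatrix:
        return {
            LAYER_MRNA: self.mrna,
            LAYER_MIRNA: self.mirna,
            LAYER_METHYLATION: self.methylation,
        }[layer_name]

    @property
    def regions(self) -> list[str]:
        return self.annotation.regions

    def region_pairs(self) -> list[tuple[str, str]]:
        """All C(R, 2) ordered pairs of the sorted region labels."""
        return list(itertools.combinations(self.regions, 2))

    def _pair_subjects(self) -> dict[tuple[str, str], list[str]]:
        present: dict[tuple[str, str], str] = {}
        layer_samples = [set(l.sample_ids) for l in (self.mrna, self.mirna, self.methylation)]
        for row in self.annotation.table.itertuples(index=False):
            if all(row.sample_id in s for s in layer_samples):
                present[(row.subject_id, row.region)] = row.sample_id
        paired: dict[tuple[str, str], list[str]] = {}
        for pair in self.region_pairs():
            subjects = sorted(
                subj
                for subj in {s for s, _ in present}
                if (subj, pair[0]) in present and (subj, pair[1]) in present
            )
            paired[pair] = subjects
        return paired

    def paired_subjects(self, region_pair: tuple[str, str]) -> list[str]:
        pair = tuple(region_pair)
        if pair in self._paired:
            return list(self._paired[pair])
        if (pair[1], pair[0]) in self._paired:
            return list(self._paired[(pair[1], pair[0])])
        raise KeyError(f"unknown region pair {pair!r}")

    def pair_usable(self, region_pair: tuple[str, str]) -> bool:
        """A pair with fewer than 3 paired subjects is flagged unusable."""
        return len(self.paired_subjects(region_pair)) >= self.MIN_PAIRED_SUBJECTS

    def sample_id(self, subject_id: str, region: str) -> str:
        sid = self.annotation.sample_for(subject_id, region)
        if sid is None:
            raise KeyError(f"subject {subject_id!r} has no sample in region {region!r}")
        return sid


# ---------------------------------------------------------------------------
# readers / writers


def read_omics_matrix(
    path: str | Path, layer_name: str, aggregate_duplicates: bool = False
) -> OmicsMatrix:
    """Read a feature-by-sample TSV (header = sample ids, first column = feature ids).

    With ``aggregate_duplicates`` duplicate feature ids are collapsed by their
    mean (probe→gene reduction); otherwise they are a validation error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise ValidationError(
                    f"non-numeric cell at feature {df.index[bad.argmax()]!r}, "
                    f"sample {col!r} in {path}"
                )
            df[col] = coerced
    if aggregate_duplicates and df.index.duplicated().any():
        n_before = len(df)
        df = df.groupby(level=0, sort=False).mean()
        logger.info(
            "layer %s: aggregated %d duplicate feature rows by mean",
            layer_name,
            n_before - len(df),
        )
    return OmicsMatrix(layer_name=layer_name, values=df.astype(float))


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_annotation(path: str | Path) -> SampleAnnotationTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "subject_id": str, "region": str, "gender": str},
    )
    return SampleAnnotationTable(table=df)


def write_sample_annotation(annotation: SampleAnnotationTable, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_target_map(path: str | Path, gene_universe) -> TargetMap:
    """Read a two-column (mirna_id, gene_id) TSV and intersect with the universe.

    miRNAs whose target set is empty after intersection are dropped with a
    logged warning; duplicate pairs deduplicate silently.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna_id", "gene_id"], dtype=str)
    if df.empty:
        raise ValidationError(f"target map {path} is empty")
    universe = frozenset(gene_universe)
    targets: dict[str, frozenset[str]] = {}
    dropped = []
    for mirna, group in df.groupby("mirna_id", sort=True):
        genes = frozenset(group["gene_id"]) & universe
        if genes:
            targets[mirna] = genes
        else:
            dropped.append(mirna)
    if dropped:
        logger.warning(
            "dropped %d miRNA(s) with no targets in the gene universe: %s%s",
            len(dropped),
            ", ".join(dropped[:5]),
            "…" if len(dropped) > 5 else "",
        )
    tm = TargetMap(targets=targets)
    logger.info("target map: M=%d miRNAs retained", tm.n_mirnas)
    return tm


def write_target_map(target_map: TargetMap, path: str | Path) -> None:
    rows = [
        (m, g) for m in target_map.mirna_ids for g in sorted(target_map.targets[m])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def assemble_study(
    mrna: OmicsMatrix,
    mirna: OmicsMatrix,
    methylation: OmicsMatrix,
    annotation: SampleAnnotationTable,
    target_map: TargetMap,
) -> AlignedStudy:
    """Assemble the subject-paired multi-layer study object."""
    study = AlignedStudy(
        mrna=mrna,
        mirna=mirna,
        methylation=methylation,
        annotation=annotation,
        target_map=target_map,
    )
    for pair in study.region_pairs():
        if not study.pair_usable(pair):
            logger.warning(
                "region pair %s–%s has %d paired subjects (<%d): flagged unusable",
                pair[0],
                pair[1],
                len(study.paired_subjects(pair)),
                AlignedStudy.MIN_PAIRED_SUBJECTS,
            )
    return study
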