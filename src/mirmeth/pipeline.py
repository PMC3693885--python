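"""End-to-end orchestration: simulate/load → stats → couple → regress → enrich.

Stages communicate exclusively through plain TSV files in the output
directory, so each stage is independently runnable and the composed run is
byte-identical to running the stages one at a time. A JSON run summary
(parameters, seed, per-pair counts, correlations, selections, top
enrichments) is written at the end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._common import LOG_EPSILON
from .coupling import coupling_correlation
from .enrichment import (
    PathwayDB,
    enrich,
    enrichment_frame,
    presence_matrix,
    read_gmt,
    union_targets,
    write_gmt,
)
from .io import (
    LAYER_METHYLATION,
    LAYER_MIRNA,
    LAYER_MRNA,
    AlignedStudy,
    assemble_study,
    read_omics_matrix,
    read_sample_annotation,
    read_target_map,
    write_omics_matrix,
    write_sample_annotation,
    write_target_map,
)
from .regression import build_design, fit_mirna_regression, results_frame, select_mirnas
from .synthetic import SyntheticConfig, generate_study, simulate_pathway_gene_sets
from .targeting import (
    DirectionalPValueTable,
    compute_pvalue_table,
    summarize_direction_counts,
)

logger = logging.getLogger(__name__)

INPUT_KEYS = ("mrna", "mirna", "methylation", "annotation", "targets")


@dataclass
class RunConfig:
    """Everything a run needs: either input paths or a simulate block."""

    outdir: str
    seed: int
    inputs: dict | None = None  # paths: mrna, mirna, methylation, annotation, targets, [pathways]
    simulate: SyntheticConfig | None = None
    region_pairs: list[tuple[str, str]] | None = None  # default: all pairs
    method: str = "auto"
    alpha: float = 0.05
    correction: str = "BH"
    selection_criterion: str = "dmir"
    direction: str = "greater"
    epsilon: float = LOG_EPSILON
    log_level: str = "INFO"
    n_synthetic_pathways: int = 20
    synthetic_pathway_size: tuple[int, int] = (20, 80)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of inputs / simulate must be given")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.inputs is not None:
            missing = [k for k in INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ValueError(f"inputs block missing path(s): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed"))
            for key in ("region_labels", "targets_per_mirna"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            raw["simulate"] = SyntheticConfig(**sim)
        if "region_pairs" in raw and raw["region_pairs"] is not None:
            raw["region_pairs"] = [tuple(p) for p in raw["region_pairs"]]
        if "synthetic_pathway_size" in raw:
            raw["synthetic_pathway_size"] = tuple(raw["synthetic_pathway_size"])
        return cls(**raw)


def _pair_tag(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> dict:
    """Write the full synthetic TSV input set plus truth tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study, truth = generate_study(config.simulate)
    write_omics_matrix(study.mrna, outdir / "mrna.tsv")
    write_omics_matrix(study.mirna, outdir / "mirna.tsv")
    write_omics_matrix(study.methylation, outdir / "methylation.tsv")
    write_sample_annotation(study.annotation, outdir / "annotation.tsv")
    write_target_map(study.target_map, outdir / "targets.tsv")
    for kind, frame in truth.to_frames().items():
        _write_tsv(frame, outdir / f"truth_{kind}.tsv")
    planted = sorted({e.mirna_id for e in truth.regulation})
    pathways = simulate_pathway_gene_sets(
        study.target_map,
        planted,
        config.n_synthetic_pathways,
        config.synthetic_pathway_size,
        seed=config.simulate.seed + 1,
    )
    write_gmt(pathways, outdir / "pathways.gmt")
    return {
        "n_genes": len(study.mrna.feature_ids),
        "n_mirnas": study.target_map.n_mirnas,
        "n_subjects": config.simulate.n_subjects,
        "n_samples": len(study.annotation.sample_ids),
        "regions": study.regions,
        "n_planted_regulation": len(truth.regulation),
        "n_planted_methylation": len(truth.methylation),
        "n_planted_mirna_de": len(truth.mirna_de),
    }


def load_study(config: RunConfig) -> AlignedStudy:
    """Load the study from the inputs block or from simulate-stage outputs."""
    if config.inputs is not None:
        paths = config.inputs
    else:
        outdir = Path(config.outdir)
        paths = {
            "mrna": outdir / "mrna.tsv",
            "mirna": outdir / "mirna.tsv",
            "methylation": outdir / "methylation.tsv",
            "annotation": outdir / "annotation.tsv",
            "targets": outdir / "targets.tsv",
        }
    mrna = read_omics_matrix(paths["mrna"], LAYER_MRNA)
    mirna = read_omics_matrix(paths["mirna"], LAYER_MIRNA)
    methylation = read_omics_matrix(paths["methylation"], LAYER_METHYLATION)
    annotation = read_sample_annotation(paths["annotation"])
    target_map = read_target_map(paths["targets"], mrna.feature_ids)
    return assemble_study(mrna, mirna, methylation, annotation, target_map)


def _selected_pairs(config: RunConfig, study: AlignedStudy) -> list[tuple[str, str]]:
    pairs = (
        [tuple(p) for p in config.region_pairs]
        if config.region_pairs
        else study.region_pairs()
    )
    usable = [p for p in pairs if study.pair_usable(p)]
    skipped = [p for p in pairs if p not in usable]
    if skipped:
        logger.warning("skipping unusable region pair(s): %s", skipped)
    return usable


def stage_stats(config: RunConfig) -> dict:
    """Directional P-value tables for both layers and every region pair."""
    outdir = Path(config.outdir)
    study = load_study(config)
    summary = {"pairs": {}}
    count_rows = []
    for pair in _selected_pairs(config, study):
        tag = _pair_tag(pair)
        pair_info = {}
        for layer in (LAYER_MRNA, LAYER_METHYLATION):
            table = compute_pvalue_table(
                study, layer, pair, method=config.method, epsilon=config.epsilon
            )
            _write_tsv(table.to_long_frame(), outdir / f"pvalues_{layer}_{tag}.tsv")
            counts = summarize_direction_counts(
                table, alpha=config.alpha, correction=config.correction
            )
            count_rows.append(counts.as_row())
            pair_info[layer] = {
                "n_up": counts.n_up,
                "n_down": counts.n_down,
                "net_direction": counts.net_direction,
            }
        summary["pairs"][tag] = pair_info
    _write_tsv(pd.DataFrame(count_rows), outdir / "direction_counts.tsv")
    return summary


def _load_table(outdir: Path, layer: str, pair: tuple[str, str]) -> DirectionalPValueTable:
    path = outdir / f"pvalues_{layer}_{_pair_tag(pair)}.tsv"
    if not path.exists():
        raise FileNotFoundError(f"stats output missing: {path}; run the stats stage first")
    frame = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "subject_id": str})
    needed = {"layer", "region_ell", "region_ellprime", "mirna_id", "subject_id",
              "p_less", "p_greater", "method"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return DirectionalPValueTable.from_long_frame(frame)


def stage_couple(config: RunConfig) -> dict:
    """Mean-rank ρ, per-subject ρ_j and Δρ for every region pair."""
    outdir = Path(config.outdir)
    study = load_study(config)
    rows, long_rows, summary = [], [], {}
    for pair in _selected_pairs(config, study):
        mrna_table = _load_table(outdir, LAYER_MRNA, pair)
        methyl_table = _load_table(outdir, LAYER_METHYLATION, pair)
        cs = coupling_correlation(mrna_table, methyl_table, direction=config.direction)
        rows.append(cs.as_row())
        for subject, rho_j in cs.rho_per_subject.items():
            long_rows.append(
                {
                    "region_ell": pair[0],
                    "region_ellprime": pair[1],
                    "subject_id": subject,
                    "rho_j": rho_j,
                }
            )
        summary[_pair_tag(pair)] = {
            "rho_mean_rank": cs.rho_mean_rank,
            "delta_rho": cs.delta_rho,
            "p_value": cs.p_value,
            "m_used": cs.m_used,
        }
    _write_tsv(pd.DataFrame(rows), outdir / "coupling.tsv")
    _write_tsv(pd.DataFrame(long_rows), outdir / "coupling_subjects.tsv")
    return summary


def stage_regress(config: RunConfig) -> dict:
    """Per-miRNA regressions plus reciprocal/nonreciprocal selection."""
    outdir = Path(config.outdir)
    study = load_study(config)
    all_frames, summary = [], {}
    for pair in _selected_pairs(config, study):
        mrna_table = _load_table(outdir, LAYER_MRNA, pair)
        methyl_table = _load_table(outdir, LAYER_METHYLATION, pair)
        designs = build_design(study, mrna_table, methyl_table, pair, epsilon=config.epsilon)
        results = [fit_mirna_regression(d) for d in designs]
        selected = select_mirnas(
            results,
            alpha=config.alpha,
            correction=config.correction,
            criterion=config.selection_criterion,
        )
        frame = results_frame(results)
        _write_tsv(frame, outdir / f"regression_{_pair_tag(pair)}.tsv")
        all_frames.append(frame)
        summary[_pair_tag(pair)] = {
            "n_fitted": len(results),
            "n_selected": len(selected),
            "reciprocal": sorted(r.mirna_id for r in selected if r.label == "reciprocal"),
            "nonreciprocal": sorted(
                r.mirna_id for r in selected if r.label == "nonreciprocal"
            ),
        }
    combined = (
        pd.concat(all_frames, ignore_index=True) if all_frames else pd.DataFrame()
    )
    _write_tsv(combined, outdir / "regression_all.tsv")
    return summary


def stage_enrich(config: RunConfig) -> dict:
    """Per pair × label enrichment plus the presence/absence matrix."""
    outdir = Path(config.outdir)
    study = load_study(config)
    gmt_path = (
        config.inputs.get("pathways") if config.inputs else outdir / "pathways.gmt"
    )
    if gmt_path is None or not Path(gmt_path).exists():
        raise FileNotFoundError("no pathway GMT available for the enrich stage")
    db = PathwayDB.from_gene_sets(read_gmt(gmt_path), study.mrna.feature_ids)
    reg_path = outdir / "regression_all.tsv"
    if not reg_path.exists():
        raise FileNotFoundError(f"{reg_path} missing; run the regress stage first")
    reg = pd.read_csv(reg_path, sep="\t", dtype={"mirna_id": str})
    rows, grouped, summary = [], {}, {}
    if not reg.empty:
        sel = reg[reg["selected"] == True]  # noqa: E712
        for (ell, ellp, label), grp in sel.groupby(
            ["region_ell", "region_ellprime", "label"], sort=True
        ):
            group = f"{_pair_tag((ell, ellp))}/{label}"
            query = union_targets(sorted(grp["mirna_id"]), study.target_map)
            results = enrich(query, db, alpha=config.alpha, correction=config.correction)
            grouped[group] = results
            frame = enrichment_frame(results)
            frame.insert(0, "group", group)
            rows.append(frame)
            hits = [r.pathway_id for r in results if r.adj_p_value <= config.alpha]
            summary[group] = {"n_query_genes": len(query), "significant_pathways": hits}
    combined = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    _write_tsv(combined, outdir / "enrichment.tsv")
    _write_tsv(
        presence_matrix(grouped, alpha=config.alpha) if grouped else pd.DataFrame(),
        outdir / "enrichment_presence.tsv",
        index=True,
    )
    return summary


STAGES = ("simulate", "stats", "couple", "regress", "enrich")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write the JSON run summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "method": config.method,
            "alpha": config.alpha,
            "correction": config.correction,
            "selection_criterion": config.selection_criterion,
            "direction": config.direction,
            "epsilon": config.epsilon,
        },
    }
    if config.simulate is not None:
        summary["simulate"] = stage_simulate(config)
    summary["stats"] = stage_stats(config)
    summary["couple"] = stage_couple(config)
    summary["regress"] = stage_regress(config)
    try:
        summary["enrich"] = stage_enrich(config)
    except FileNotFoundError as exc:
        logger.warning("enrich stage skipped: %s", exc)
        summary["enrich"] = {"skipped": str(exc)}
    with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
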