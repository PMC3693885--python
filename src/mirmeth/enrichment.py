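"""Hypergeometric pathway enrichment of selected miRNAs' target genes.

The query set is the union of the selected miRNAs' target genes; each pathway
is scored by the upper-tail hypergeometric P-value of its overlap with the
query inside a fixed universe (genes present in both the study's mRNA layer
and at least one pathway), with Benjamini–Hochberg correction across
pathways. A presence/absence matrix (pathway × analysis group, thresholded at
adjusted P ≤ α) summarises which pathways recur across region pairs and
reciprocal/nonreciprocal labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._common import bh_adjust
from .io import TargetMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PathwayDB:
    """Pathway id → gene set, with the enrichment universe."""

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("pathway universe is empty")
        self.pathways = {
            name: frozenset(genes) & self.universe
            for name, genes in self.pathways.items()
        }
        empty = [n for n, g in self.pathways.items() if not g]
        if empty:
            logger.warning("dropped %d empty pathway(s) after intersection", len(empty))
            self.pathways = {n: g for n, g in self.pathways.items() if g}
        if not self.pathways:
            raise ValidationError("no pathway survived universe intersection")

    @classmethod
    def from_gene_sets(cls, gene_sets: dict, study_genes) -> "PathwayDB":
        """Universe = union of pathway genes ∩ study gene universe."""
        union = frozenset().union(*map(frozenset, gene_sets.values()))
        return cls(
            pathways={n: frozenset(g) for n, g in gene_sets.items()},
            universe=union & frozenset(study_genes),
        )


@dataclass
class EnrichmentResult:
    pathway_id: str
    k_overlap: int
    pathway_size: int
    query_size: int
    universe_size: int
    p_value: float
    adj_p_value: float
    overlap_genes: tuple[str, ...]

    def as_row(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "k_overlap": self.k_overlap,
            "pathway_size": self.pathway_size,
            "query_size": self.query_size,
            "universe_size": self.universe_size,
            "p_value": self.p_value,
            "adj_p_value": self.adj_p_value,
            "overlap_genes": ",".join(self.overlap_genes),
        }


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file: name <tab> description <tab> gene…, one set per line."""
    gene_sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name = parts[0]
            if name in gene_sets:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway {name!r}")
            gene_sets[name] = frozenset(g for g in parts[2:] if g)
    if not gene_sets:
        raise ValidationError(f"GMT file {path} is empty")
    return gene_sets


def write_gmt(gene_sets: dict, path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(gene_sets):
            fh.write("\t".join([name, description, *sorted(gene_sets[name])]) + "\n")


def union_targets(selected_mirnas, target_map: TargetMap) -> frozenset[str]:
    """Union of the selected miRNAs' target gene sets."""
    missing = [m for m in selected_mirnas if m not in target_map.targets]
    if missing:
        raise KeyError(f"miRNA(s) absent from target map: {', '.join(missing[:5])}")
    sets = [target_map.targets[m] for m in selected_mirnas]
    return frozenset().union(*sets) if sets else frozenset()


def hypergeometric_test(k: int, pathway_size: int, query_size: int, universe_size: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(pathway_size, query_size) <= universe_size):
        raise ValueError(
            f"invalid counts: k={k}, K={pathway_size}, n={query_size}, N={universe_size}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, pathway_size, query_size))


def enrich(
    query,
    db: PathwayDB,
    alpha: float = 0.05,
    correction: str = "BH",
) -> list[EnrichmentResult]:
    """One EnrichmentResult per pathway, BH-corrected, sorted by adjusted P.

    Query genes outside the universe are dropped (count logged).
    """
    if correction not in ("BH", "none"):
        raise ValueError("correction must be 'BH' or 'none'")
    query = frozenset(query)
    inside = query & db.universe
    if len(inside) < len(query):
        logger.info("dropped %d query gene(s) outside the universe", len(query) - len(inside))
    n = len(inside)
    N = len(db.universe)
    names = sorted(db.pathways)
    raw = []
    overlaps = []
    for name in names:
        genes = db.pathways[name]
        overlap = tuple(sorted(inside & genes))
        overlaps.append(overlap)
        raw.append(hypergeometric_test(len(overlap), len(genes), n, N))
    adj = bh_adjust(np.asarray(raw)) if correction == "BH" else np.asarray(raw)
    results = [
        EnrichmentResult(
            pathway_id=name,
            k_overlap=len(overlap),
            pathway_size=len(db.pathways[name]),
            query_size=n,
            universe_size=N,
            p_value=p,
            adj_p_value=a,
            overlap_genes=overlap,
        )
        for name, overlap, p, a in zip(names, overlaps, raw, adj)
    ]
    results.sort(key=lambda r: (r.adj_p_value, r.p_value, r.pathway_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def presence_matrix(
    grouped_results: dict[str, list[EnrichmentResult]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pathway × analysis-group presence matrix (1 ⟺ adjusted P ≤ alpha).

    ``grouped_results`` maps a group label (e.g. "CRBLM_vs_FCTX/reciprocal")
    to that group's enrichment results.
    """
    pathways = sorted({r.pathway_id for rs in grouped_results.values() for r in rs})
    out = pd.DataFrame(0, index=pathways, columns=sorted(grouped_results), dtype=int)
    for group, rs in grouped_results.items():
        for r in rs:
            if r.adj_p_value <= alpha:
                out.loc[r.pathway_id, group] = 1
    out.index.name = "pathway_id"
    return out
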