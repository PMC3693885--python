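"""Synthetic multi-omics studies with known planted effects.

The generator emulates the statistical structure the analysis assumes: a
cohort of subjects each sampled in every region (fully crossed by default),
with three co-measured layers — mRNA expression and miRNA expression as
positive array-style signals (Gaussian on the natural-log scale) and promoter
methylation as beta values in [0, 1] (Gaussian noise, clipped).

Planted effects come in three kinds, each tied to a miRNA and a region pair:

* **regulation** — the miRNA's target genes are shifted by ±δ_reg on the log
  scale in the first region of the pair (or, when the config couples
  regulation to miRNA expression, by β·dmir_j + N(0, σ_β) per subject, where
  dmir_j is the subject's realised miRNA log-ratio);
* **methylation** — the targets' promoter betas are shifted by ±δ_meth;
* **miRNA differential expression** — the miRNA itself is shifted by δ_mir.

The planted truth is returned alongside the study so downstream stages can be
scored by parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    LAYER_METHYLATION,
    LAYER_MIRNA,
    LAYER_MRNA,
    AlignedStudy,
    OmicsMatrix,
    SampleAnnotationTable,
    TargetMap,
    assemble_study,
)

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = ("CRBLM", "FCTX", "PONS", "TCTX")


@dataclass(frozen=True)
class PlantedRegulation:
    """Targets of ``mirna_id`` shifted in ``region_pair[0]`` vs ``region_pair[1]``."""

    mirna_id: str
    region_pair: tuple[str, str]
    sign: int  # +1 targets up in the first region, -1 down
    delta: float  # log-scale shift magnitude (ignored when coupling is on)


@dataclass(frozen=True)
class PlantedMethylation:
    mirna_id: str
    region_pair: tuple[str, str]
    sign: int  # +1 target promoters hypermethylated in the first region
    delta: float  # beta-scale shift magnitude


@dataclass(frozen=True)
class PlantedMirnaDE:
    mirna_id: str
    region_pair: tuple[str, str]
    delta: float  # signed log-fold shift of the miRNA in the first region


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the reference design: four brain-region groups sampled
    in the same 150 subjects (600 samples), a few thousand genes and a couple
    of hundred miRNAs with 20–60 targets each.
    """

    seed: int
    n_genes: int = 2000
    n_mirnas: int = 200
    n_subjects: int = 150
    region_labels: tuple[str, ...] = DEFAULT_REGIONS
    targets_per_mirna: tuple[int, int] = (20, 60)
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    noise_sd_mrna: float = 0.5
    noise_sd_mirna: float = 0.5
    noise_sd_methylation: float = 0.05
    methylation_baseline_range: tuple[float, float] = (0.2, 0.8)
    regulation_effects: tuple[PlantedRegulation, ...] = ()
    methylation_effects: tuple[PlantedMethylation, ...] = ()
    mirna_de_effects: tuple[PlantedMirnaDE, ...] = ()
    couple_regulation_to_mirna: bool = False
    coupling_beta: float = 0.0
    coupling_noise_sd: float = 0.0
    age_effect: float = 0.0  # per-year log-expression slope
    gender_effect: float = 0.0  # female-minus-male log-expression offset
    age_range: tuple[float, float] = (20.0, 90.0)
    gender_p_female: float = 0.5
    dropout_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes <= 0 or self.n_mirnas <= 0 or self.n_subjects <= 0:
            raise ValueError("n_genes, n_mirnas and n_subjects must be positive")
        if len(self.region_labels) < 2:
            raise ValueError("need at least two region labels")
        if self.targets_per_mirna[1] > self.n_genes:
            raise ValueError(
                f"targets_per_mirna upper bound {self.targets_per_mirna[1]} "
                f"exceeds n_genes={self.n_genes}"
            )
        labels = set(self.region_labels)
        for eff in (
            self.regulation_effects + self.methylation_effects + self.mirna_de_effects
        ):
            if not set(eff.region_pair) <= labels:
                raise ValueError(f"effect region pair {eff.region_pair} not in labels")


@dataclass
class PlantedTruth:
    """Ground truth of the planted effects, keyed for recovery scoring."""

    regulation: tuple[PlantedRegulation, ...] = ()
    methylation: tuple[PlantedMethylation, ...] = ()
    mirna_de: tuple[PlantedMirnaDE, ...] = ()

    def is_empty(self) -> bool:
        return not (self.regulation or self.methylation or self.mirna_de)

    def regulation_mirnas(self, region_pair: tuple[str, str]) -> dict[str, int]:
        pair = tuple(region_pair)
        out: dict[str, int] = {}
        for eff in self.regulation:
            if tuple(eff.region_pair) == pair:
                out[eff.mirna_id] = eff.sign
            elif tuple(eff.region_pair) == pair[::-1]:
                out[eff.mirna_id] = -eff.sign
        return out

    def to_frames(self) -> dict[str, pd.DataFrame]:
        def frame(effects, extra):
            rows = [
                {
                    "mirna_id": e.mirna_id,
                    "region_ell": e.region_pair[0],
                    "region_ellprime": e.region_pair[1],
                    **extra(e),
                }
                for e in effects
            ]
            cols = ["mirna_id", "region_ell", "region_ellprime"] + list(
                extra(effects[0]).keys() if effects else []
            )
            return pd.DataFrame(rows, columns=cols or None)

        return {
            "regulation": frame(
                self.regulation, lambda e: {"sign": e.sign, "delta": e.delta}
            ),
            "methylation": frame(
                self.methylation, lambda e: {"sign": e.sign, "delta": e.delta}
            ),
            "mirna_de": frame(self.mirna_de, lambda e: {"delta": e.delta}),
        }


def default_null_config(n_mirnas: int, n_subjects: int, seed: int) -> SyntheticConfig:
    """A config with every effect size zero — the global null."""
    return SyntheticConfig(seed=seed, n_mirnas=n_mirnas, n_subjects=n_subjects)


def gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def mirna_ids(n: int) -> list[str]:
    return [f"mir{i:04d}" for i in range(n)]


def _sample_id(subject: str, region: str) -> str:
    return f"{subject}_{region}"


def generate_study(config: SyntheticConfig) -> tuple[AlignedStudy, PlantedTruth]:
    """Generate one AlignedStudy plus its PlantedTruth, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)
    mirnas = mirna_ids(config.n_mirnas)
    subjects = [f"s{i:04d}" for i in range(config.n_subjects)]
    regions = list(config.region_labels)
    n_reg = len(regions)

    # target map
    lo, hi = config.targets_per_mirna
    sizes = rng.integers(lo, hi + 1, size=config.n_mirnas)
    gene_arr = np.asarray(genes)
    targets = {
        m: frozenset(rng.choice(gene_arr, size=int(k), replace=False))
        for m, k in zip(mirnas, sizes)
    }
    target_map = TargetMap(targets=targets)

    # cohort covariates
    ages = rng.uniform(*config.age_range, size=config.n_subjects)
    female = rng.random(config.n_subjects) < config.gender_p_female

    region_index = {r: i for i, r in enumerate(regions)}
    gene_index = {g: i for i, g in enumerate(genes)}

    # miRNA layer first: coupled regulation needs the realised log-ratios
    mirna_base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_mirnas)
    log_mirna = (
        mirna_base[:, None, None]
        + rng.normal(0.0, config.noise_sd_mirna, (config.n_mirnas, config.n_subjects, n_reg))
    )
    mirna_pos = {m: i for i, m in enumerate(mirnas)}
    for eff in config.mirna_de_effects:
        log_mirna[mirna_pos[eff.mirna_id], :, region_index[eff.region_pair[0]]] += eff.delta

    # mRNA layer
    gene_base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    log_mrna = (
        gene_base[:, None, None]
        + config.age_effect * (ages - ages.mean())[None, :, None]
        + config.gender_effect * female.astype(float)[None, :, None]
        + rng.normal(0.0, config.noise_sd_mrna, (config.n_genes, config.n_subjects, n_reg))
    )
    for eff in config.regulation_effects:
        rows = [gene_index[g] for g in sorted(targets[eff.mirna_id])]
        r0 = region_index[eff.region_pair[0]]
        if config.couple_regulation_to_mirna:
            m = mirna_pos[eff.mirna_id]
            dmir = (
                log_mirna[m, :, r0]
                - log_mirna[m, :, region_index[eff.region_pair[1]]]
            )
            shift = eff.sign * config.coupling_beta * dmir + rng.normal(
                0.0, config.coupling_noise_sd, config.n_subjects
            )
        else:
            shift = np.full(config.n_subjects, eff.sign * eff.delta)
        log_mrna[rows, :, r0] += shift[None, :]

    # methylation layer
    meth_base = rng.uniform(*config.methylation_baseline_range, size=config.n_genes)
    beta = (
        meth_base[:, None, None]
        + rng.normal(
            0.0, config.noise_sd_methylation, (config.n_genes, config.n_subjects, n_reg)
        )
    )
    for eff in config.methylation_effects:
        rows = [gene_index[g] for g in sorted(targets[eff.mirna_id])]
        beta[rows, :, region_index[eff.region_pair[0]]] += eff.sign * eff.delta
    clipped = (beta < 0) | (beta > 1)
    clip_frac = clipped.mean()
    if clip_frac > 0.01:
        logger.warning("methylation clipping affected %.2f%% of entries", 100 * clip_frac)
    beta = np.clip(beta, 0.0, 1.0)

    # drop a fraction of subject×region samples (incomplete designs)
    sample_keys = [(s, r) for s in subjects for r in regions]
    if config.dropout_fraction > 0:
        keep = rng.random(len(sample_keys)) >= config.dropout_fraction
        sample_keys = [k for k, kp in zip(sample_keys, keep) if kp]

    sample_ids = [_sample_id(s, r) for s, r in sample_keys]
    cols = [(subjects.index(s), region_index[r]) for s, r in sample_keys]
    j_idx = np.array([c[0] for c in cols])
    r_idx = np.array([c[1] for c in cols])

    def layer_frame(cube: np.ndarray, features: list[str]) -> pd.DataFrame:
        return pd.DataFrame(cube[:, j_idx, r_idx], index=features, columns=sample_ids)

    mrna = OmicsMatrix(LAYER_MRNA, layer_frame(np.exp(log_mrna), genes))
    mirna = OmicsMatrix(LAYER_MIRNA, layer_frame(np.exp(log_mirna), mirnas))
    methylation = OmicsMatrix(LAYER_METHYLATION, layer_frame(beta, genes))

    annotation = SampleAnnotationTable(
        table=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": [s for s, _ in sample_keys],
                "region": [r for _, r in sample_keys],
                "age": [ages[subjects.index(s)] for s, _ in sample_keys],
                "gender": [
                    "female" if female[subjects.index(s)] else "male"
                    for s, _ in sample_keys
                ],
            }
        )
    )

    truth = PlantedTruth(
        regulation=tuple(config.regulation_effects),
        methylation=tuple(config.methylation_effects),
        mirna_de=tuple(config.mirna_de_effects),
    )
    study = assemble_study(mrna, mirna, methylation, annotation, target_map)
    return study, truth


# ---------------------------------------------------------------------------
# planted-effect config builders


def planted_regulation_config(
    n_planted_up: int,
    n_planted_down: int,
    delta: float,
    region_pair: tuple[str, str] | None = None,
    **overrides,
) -> SyntheticConfig:
    """Config planting constant ±delta regulation on the first miRNAs."""
    base = SyntheticConfig(**overrides)
    pair = tuple(region_pair) if region_pair else tuple(base.region_labels[:2])
    ids = mirna_ids(base.n_mirnas)
    effects = tuple(
        PlantedRegulation(ids[i], pair, +1, delta) for i in range(n_planted_up)
    ) + tuple(
        PlantedRegulation(ids[n_planted_up + i], pair, -1, delta)
        for i in range(n_planted_down)
    )
    return replace(base, regulation_effects=effects)


def coupled_regulation_config(
    n_planted: int,
    beta: float,
    sigma_beta: float,
    region_pair: tuple[str, str] | None = None,
    signs: tuple[int, ...] | None = None,
    **overrides,
) -> SyntheticConfig:
    """Config coupling the first ``n_planted`` miRNAs' target regulation
    linearly (slope ±beta, noise sigma_beta) to their realised differential
    expression."""
    base = SyntheticConfig(**overrides)
    pair = tuple(region_pair) if region_pair else tuple(base.region_labels[:2])
    ids = mirna_ids(base.n_mirnas)
    if signs is None:
        signs = tuple(1 if i % 2 == 0 else -1 for i in range(n_planted))
    effects = tuple(
        PlantedRegulation(ids[i], pair, signs[i], 0.0) for i in range(n_planted)
    )
    return replace(
        base,
        regulation_effects=effects,
        couple_regulation_to_mirna=True,
        coupling_beta=beta,
        coupling_noise_sd=sigma_beta,
    )


def simulate_coupled_pvalue_tables(
    n_mirnas: int,
    n_subjects: int,
    spearman_rho: float,
    seed: int,
    subject_noise_sd: float = 0.5,
    region_pair: tuple[str, str] = ("A", "B"),
):
    """Two directional P-value tables whose per-miRNA latent signals have
    Spearman correlation ``spearman_rho`` (Gaussian copula; the latent Pearson
    correlation is 2·sin(π·ρ/6) so the latent Spearman equals ρ exactly).

    Each observed P is Φ(latent + per-subject noise), so per-subject
    correlations are attenuated by the noise while the mean-rank profile
    recovers the planted ρ as the subject count grows. Used for coupling
    parameter-recovery studies without running the full omics generator.
    """
    from scipy.stats import norm

    from .targeting import DirectionalPValueTable

    if not -1.0 < spearman_rho < 1.0:
        raise ValueError("spearman_rho must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * spearman_rho / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n_mirnas)
    mirnas = mirna_ids(n_mirnas)
    subjects = [f"s{i:04d}" for i in range(n_subjects)]

    def table(latent_col: np.ndarray, layer: str) -> DirectionalPValueTable:
        noise = rng.normal(0.0, subject_noise_sd, (n_mirnas, n_subjects))
        p_greater = norm.cdf(latent_col[:, None] + noise)
        p_greater = np.clip(p_greater, 1e-12, 1.0)
        frame_g = pd.DataFrame(p_greater, index=mirnas, columns=subjects)
        frame_l = 1.0 - frame_g
        return DirectionalPValueTable(
            layer=layer,
            region_pair=tuple(region_pair),
            p_less=frame_l.clip(lower=1e-12),
            p_greater=frame_g,
            method="synthetic_copula",
        )

    return table(latent[:, 0], LAYER_MRNA), table(latent[:, 1], LAYER_METHYLATION)


def simulate_pathway_gene_sets(
    target_map: TargetMap,
    planted_mirnas: list[str],
    n_pathways: int,
    size_range: tuple[int, int],
    seed: int,
    gene_universe: list[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Random pathway gene sets plus one planted pathway drawn entirely from
    the planted miRNAs' target union (named ``planted_pathway``)."""
    rng = np.random.default_rng(seed)
    universe = np.asarray(
        sorted(gene_universe) if gene_universe else sorted(target_map.gene_universe())
    )
    lo, hi = size_range
    pathways: dict[str, frozenset[str]] = {}
    for i in range(n_pathways):
        k = int(rng.integers(lo, hi + 1))
        pathways[f"pw{i:03d}"] = frozenset(rng.choice(universe, size=k, replace=False))
    if planted_mirnas:
        union = sorted(
            set().union(*(target_map.targets[m] for m in planted_mirnas))
        )
        k = min(len(union), int(rng.integers(lo, hi + 1)))
        pathways["planted_pathway"] = frozenset(
            rng.choice(np.asarray(union), size=k, replace=False)
        )
    return pathways
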