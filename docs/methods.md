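# Methods

This note documents the statistical model behind `mirmeth`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the package's numerical conventions and limitations.

## Data model

The unit of analysis is a cohort of subjects each measured in several tissue
groups ("regions") on three co-registered layers: mRNA expression and miRNA
expression as positive processed array signals, and promoter methylation as
beta values in [0, 1] (one promoter value per gene). Signals are used as
provided — no normalization is applied — with the log taken internally where
needed. A miRNA→target map relates the miRNA and gene universes; M denotes
the number of miRNAs with at least one target in the study's gene universe.

Pairing is by subject: for a region pair (ℓ, ℓ′) a subject contributes only
if it has a sample in both regions present in all three layers. The
per-sample index in the directional P-values is therefore a per-subject
index. Genes with any missing value among the samples used for a region
pair are dropped for that pair (logged); no imputation is attempted.
Duplicate probes mapping to one gene can be collapsed by their mean at read
time (`aggregate_duplicates=True`); by default duplicates are an error.

## Directional target-set statistics

Per subject and region pair, the per-gene paired difference is
Δ_g = log(max(x_gℓ, ε)) − log(max(x_gℓ′, ε)) with ε = 1e-8 for expression
(processed array signals can be ≤ 0 after background correction) and the
plain beta difference for methylation. For each miRNA the one-sided
hypothesis "targets' Δ exceed non-targets' Δ" (and its mirror) is tested
against the complement of the target set within the full gene universe —
not against "genes targeted by no miRNA" — because the contrast is
per-miRNA.

The default test is the Wilcoxon rank-sum. The normal approximation uses
the standard tie-corrected variance
n₁n₂/12 · (N + 1 − ΣT(t³−t)/(N(N−1))) and a 0.5 continuity correction on
each tail, so P_< and P_> are computed from the same U statistic and swap
exactly (bitwise) when the region order flips. When the smaller group has at
most 10 members the exact null distribution is used instead (the normal
approximation is poor there); this switch is the `auto` method, and the pure
variants `ranksum_exact`, `ranksum_normal` and `ttest` (Welch, one-sided)
can be forced. A rank test was chosen as default because the scale of
processed signals is platform-dependent and only the ordering of Δ is
trusted; the t variant exists for users who trust the scale.

Implementation note: for a whole table the Δ vector is shared by all miRNAs
within a subject, so each subject's genes are ranked once and every miRNA's
U follows from a masked rank-sum (one boolean-matrix product per subject).
The scalar path and the vectorised path share the same kernel and are
cross-checked against `scipy.stats.mannwhitneyu` in the tests.

Direction-count summaries aggregate each miRNA's per-subject P-values by
their median (robust, order-preserving; the aggregation is deliberately
simple since per-subject values are also exported), correct across miRNAs by
Benjamini–Hochberg at α = 0.05, and count significant miRNAs per direction.
The net direction is larger-count-wins, with ties reported as `none`.

## Coupling between regulation and methylation

Within each subject column the P-values are ranked across miRNAs (average
ranks for ties) and rescaled by the number of non-missing entries, so
subjects with missing miRNAs remain comparable on (0, 1]. The per-miRNA mean
of these rescaled ranks over subjects is the mean-rank profile; the Spearman
correlation of the mRNA and methylation profiles is ρ, with a two-sided
P-value from t = ρ√((M−2)/(1−ρ²)) on M−2 degrees of freedom (|ρ| = 1
returns P = 0 with a degeneracy flag). Per-subject correlations ρ_j are
Spearman between the two tables' columns — identical to correlating
within-subject ranks, since Spearman is rank-invariant — and are summarised
by Δρ = √(mean ρ_j²). By Jensen's inequality Δρ ≥ |mean ρ_j| always: a small
ρ with a large Δρ indicates per-subject coupling whose sign varies across
subjects.

Both layers' coupling uses the P_> channel by default (configurable). The
sign of ρ is not constrained a priori: methylation suppresses expression,
but targets respond to miRNA abundance in either direction, so positive and
negative coupling are both meaningful.

## Per-miRNA regression and selection

The directional pair of each layer is collapsed to a signed score
z = Φ⁻¹(P_<) − Φ⁻¹(P_>), each quantile clamped to ±8 (the clamp caps the
influence of P-values beyond ~1e-15). Under a uniform null P_< the score is
approximately N(0, 4), which makes it a reasonable OLS response; it is
positive when targets are up in ℓ, negative when down, zero when the tails
agree. Per miRNA and region pair the model

    y_j = b₀ + b₁·meth_j + b₂·dmir_j + b₃·gender_j + b₄·(age_j − mean age) + e_j

is fitted by ordinary least squares over paired subjects (y from the mRNA
table, meth from the methylation table, dmir_j the subject's miRNA
log-ratio, gender coded female = 1). Coefficient P-values are two-sided t
tests; rank-deficient designs raise an error naming the collinear columns.

Selection keeps miRNAs whose dmir coefficient survives BH across miRNAs at
α = 0.05 (a `dmir_or_meth` criterion is available). Selected miRNAs are
labelled **reciprocal** when b₂ < 0 — the canonical suppressive relation,
miRNA up ⟹ targets down — and **nonreciprocal** otherwise. This sign-based
reading is the package's operationalisation of the reciprocal/nonreciprocal
dichotomy; it is the only binary, testable definition available and is
recovered exactly on synthetic cohorts where the planted coupling slope's
sign is known. One regression per miRNA per region pair; no pooling across
pairs.

## Pathway enrichment

The union of the selected miRNAs' target genes (per region pair and per
label) is tested against each pathway by the upper-tail hypergeometric
P(X ≥ k) with universe N = |study genes ∩ union of pathway genes| — a
conservative, reconstructible universe choice — pathway size K, query size n
(after dropping query genes outside the universe, logged) and overlap k.
BH correction is applied across pathways; a pathway × (pair, label)
presence/absence matrix thresholded at adjusted P ≤ 0.05 summarises runs.
This local hypergeometric test is the package's own enrichment statistic; it
stands where a web enrichment service would otherwise sit, with a fully
specified universe instead of an opaque one.

## Synthetic generator

`generate_study` emulates the assumed data structure: one shared subject set
fully crossed with the region labels (default four labels, 150 subjects —
600 samples; a dropout fraction, default 0, removes random subject×region
samples to exercise incomplete designs). Gene and miRNA log-signals are
Gaussian (baseline mean 6, sd 1 across features; within-feature noise sd 0.5
per sample) and exponentiated to the positive signal scale; methylation
baselines are uniform on [0.2, 0.8] with Gaussian noise sd 0.05, clipped to
[0, 1] (clipping affects < 1 % of entries at these defaults and is logged if
it exceeds that). Ages are uniform on [20, 90], gender Bernoulli(0.5);
age/gender effects on expression default to 0 but are available. Defaults of
2000 genes, 200 miRNAs with 20–60 targets each keep a full cohort cheap to
simulate while leaving target sets small relative to the gene universe, as
in real target maps.

Planted effects add ±δ shifts to the first region of an effect's pair: on
target-gene log-expression (regulation), on target-promoter betas
(methylation), or on the miRNA itself (differential expression). With the
coupling flag, a planted miRNA's per-subject target shift is instead
β·dmir_j + N(0, σ_β) computed from the *realised* (noisy) miRNA log-ratio,
so the regression stage's slope recovery is testable against a known β. Sign
conventions follow the analysis: δ > 0 in region ℓ elevates targets' Δ.

For coupling-recovery studies the full generator is bypassed by
`simulate_coupled_pvalue_tables`: per-miRNA latent pairs are drawn from a
bivariate Gaussian with Pearson correlation 2·sin(π·ρ*/6), which makes the
latent *Spearman* correlation exactly ρ*; observed P-values are
Φ(latent + per-subject noise). Per-subject noise (sd 0.5) attenuates each
ρ_j, but the mean-rank profile averages it away, so the mean-rank ρ
approaches ρ* as subjects grow (attenuation factor ≈ 1/(1 + σ²/n) on the
Pearson scale; ≈ 0.99 at 30 subjects).

What the generator does **not** emulate: real probe-level correlation
structure, platform artifacts, batch effects, heavy-tailed signal
distributions, or any real target-prediction database. Passing recovery
tests therefore demonstrates that the pipeline's inference is correct under
its own model assumptions — uniform null P-values, controlled FDR, unbiased
recovery of planted coupling and regression slopes — not that a specific
biological dataset's published correlation values would be reproduced; those
depend on the particular cohort, target map and thresholds used there.

## Problem sizes and numerical conventions

The test suite and acceptance script size their simulations to make each
check statistically sharp while keeping a full run to a couple of minutes:
null calibration pools 10,000 P-values (200 miRNAs × 50 subjects);
exact-test enumeration sweeps 500 instances of ≤ 10 pooled genes; coupling
recovery uses M = 500 miRNAs × 30 subjects over 20 seeds (null: 100 seeds);
regression recovery uses 10 planted among 200 null miRNAs at 50 subjects
over 100 seeds, and 1000 null fits for P-value calibration. All randomness
flows from a single seed via `numpy.random.default_rng`; pipeline outputs
are plain TSV written with pandas' full-precision float repr, which is what
makes identically seeded runs byte-identical and the staged CLI equal to
the composed run.

Degenerate inputs are mapped to missing values rather than errors wherever a
table cell is the natural unit: empty target sets or complements, constant
pooled Δ, and constant correlation inputs yield NaN (with warnings where a
user decision is likely needed), while structural violations — duplicate
ids, out-of-range betas, unknown samples, rank-deficient designs — raise.
P-values are floored at 1e-300 to stay in (0, 1].

## Known limitations

* The per-miRNA tests within one subject share the same Δ vector and
  overlapping target sets, so the 10,000 pooled null P-values are weakly
  dependent; the KS calibration bound absorbs this at the sizes used.
* The signed-score response is bounded by the ±8 clamp, so very strong
  planted shifts saturate y and the fitted slope is not on the planted
  log-expression scale (the planted slope's *sign* and detectability are
  preserved; generator-level slope recovery is checked on the realised
  target-shift scale instead).
* Reciprocal/nonreciprocal labelling reads only the sign of the dmir
  coefficient; biological readings that also involve methylation direction
  would need the exported coefficient table, which contains everything
  required.
* The enrichment universe excludes study genes absent from every pathway;
  enrichment P-values are therefore conditional on pathway-annotated genes.
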