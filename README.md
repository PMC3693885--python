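# mirmeth

Integrative analysis of miRNA-mediated target-gene regulation, miRNA-
targeting-specific promoter methylation, and differential miRNA expression
across tissue groups — with a synthetic multi-omics generator that plants
known effects so every stage can be validated by parameter recovery.

The package is aimed at computational biologists working with matched
multi-layer array data (mRNA expression, miRNA expression, promoter
methylation beta values) from the same subjects sampled in several tissue
groups — e.g. distinct brain regions — who want to ask, per miRNA:

* Are this miRNA's target genes coordinately up- or down-shifted between two
  tissue groups?
* Are the targets' promoters coordinately hyper- or hypo-methylated?
* Are the two phenomena coupled across miRNAs, and does the regulation track
  the miRNA's own differential expression once methylation, age and gender
  are accounted for?

## The statistics

For a tissue-group pair (ℓ, ℓ′) and subject *j*, every gene *g* carries a
paired difference Δ_g = log x_gℓ − log x_gℓ′ (expression; natural log,
pseudo-floor 1e-8) or Δ_g = β_gℓ − β_gℓ′ (methylation). For miRNA *m* with
target set T_m the genes split into targets and non-targets, and a one-sided
rank-sum test gives the directional P-value pair

    P_mj,>  — targets' Δ stochastically greater than non-targets' (up in ℓ)
    P_mj,<  — the opposite tail

on each layer (tie- and continuity-corrected normal approximation; the exact
null when the smaller group has ≤ 10 members; a Welch-t variant is
available). Stage summaries:

* **Direction counts** — per miRNA, the median over subjects of each
  directional P, Benjamini–Hochberg-corrected across miRNAs at α = 0.05;
  counting significant miRNAs per direction gives (n_up, n_down) and a net
  direction by larger-count-wins.
* **Coupling ρ and Δρ** — within each subject the P-values are ranked across
  miRNAs (average ranks, rescaled to (0, 1]); per-miRNA mean ranks from the
  mRNA and methylation tables are Spearman-correlated (ρ, with the usual
  t-approximation P-value on M miRNAs), and per-subject Spearman
  correlations ρ_j are summarised by their root mean square Δρ, which
  exposes coupling even when positive and negative ρ_j cancel in the mean.
* **Per-miRNA regression** — each layer's P-pair is collapsed to a signed
  score z = Φ⁻¹(P_<) − Φ⁻¹(P_>) (quantiles clamped at ±8) and, per miRNA,
  OLS fits y ~ meth + dmir + gender + age with dmir_j = log(x_mjℓ/x_mjℓ′).
  miRNAs whose dmir coefficient survives BH across miRNAs are selected and
  labelled *reciprocal* (coefficient < 0: miRNA up ⟹ targets down) or
  *nonreciprocal*.
* **Pathway enrichment** — the selected miRNAs' target-gene union is tested
  per pathway by the upper-tail hypergeometric P inside a fixed universe
  (study genes ∩ pathway genes), BH-corrected, with a pathway ×
  (pair, label) presence matrix.

## Worked example

Simulate a four-region cohort (20 subjects, 500 genes, 40 miRNAs) in which
five miRNAs' target regulation is coupled to their own differential
expression with slope ±1.5, then run the whole pipeline:

```python
import mirmeth as mm

sim = mm.SyntheticConfig(
    seed=11, n_genes=500, n_mirnas=40, n_subjects=20,
    region_labels=("CRBLM", "FCTX", "PONS", "TCTX"),
    targets_per_mirna=(15, 25),
    regulation_effects=tuple(
        mm.PlantedRegulation(f"mir{i:04d}", ("CRBLM", "FCTX"),
                             1 if i < 3 else -1, 0.0)
        for i in range(5)
    ),
    couple_regulation_to_mirna=True, coupling_beta=1.5, coupling_noise_sd=0.5,
)
cfg = mm.RunConfig(outdir="demo", seed=11, simulate=sim, log_level="WARNING")
summary = mm.run_pipeline(cfg)
print(summary["regress"]["CRBLM_vs_FCTX"])
```

prints

```
{'n_fitted': 40, 'n_selected': 5,
 'reciprocal': ['mir0003', 'mir0004'],
 'nonreciprocal': ['mir0000', 'mir0001', 'mir0002']}
```

All six region pairs are analysed; only the planted pair selects miRNAs, and
the selection splits exactly by the planted coupling sign — the two miRNAs
planted with negative slope come out *reciprocal*, the three positive ones
*nonreciprocal*. The coupling stage reports ρ = 0.207 (Δρ = 0.142, P = 0.199,
M = 40) for that pair — regulation and methylation are uncoupled in this
simulation, so ρ is statistically indistinguishable from zero — and the
enrichment stage flags `planted_pathway` (a gene set drawn from the planted
miRNAs' targets) as the only significant pathway for both labels. The same
run is available from the shell via `mirmeth all --config demo.yaml`, with
stage-wise subcommands `simulate | stats | couple | regress | enrich`
producing byte-identical outputs.

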