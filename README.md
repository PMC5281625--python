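# corrosomics

Joint metabolomic/metagenomic diagnostics of microbially influenced
corrosion (MIC) in oil-production pipelines.

## The problem

Two pipelines with near-identical water chemistry can corrode at wildly
different rates because their wall biofilms respire differently: sulfate
reducers generate corrosive sulfide, while denitrifiers generally do not.
Pigging debris (the material scraped off the pipe wall) can be profiled two
ways at once — untargeted LC-MS metabolomics of the extractable chemistry,
and shotgun metagenomics of the community DNA. `corrosomics` implements
the downstream arithmetic that turns those two data streams into a
comparable diagnosis for a high-corrosion (HC) versus a low-corrosion (LC)
system, sampled at an early and a late pig run (samples `LC3`, `LC11`,
`HC3`, `HC11`).

It is a library plus a thin CLI for analysts who already have aligned (or
alignable) feature tables and annotated genome bins, and who want the
comparison statistics — not a raw-spectra or read-assembly tool.

## What it computes

**Feature processing.** Per-replicate LC-MS observations are merged by
single-linkage grouping within 6 ppm mass and 0.25 min retention time;
features below 1,000 i.u. (instrument units) in every sample are dropped.
Replicate quality is judged against ion-counting shot noise: with
~12.5 i.u. per detected ion, an abundance *A* implies *N = A/12.5* ions
and an expected relative standard deviation RSD = 1/√N.

**Putative identification.** Features are matched to a compound library by
exact neutral mass (|Δm/m| ≤ 6 ppm against the monoisotopic mass of the
formula). For positive-mode features a six-descriptor linear QSRR model,
`rt = β₀ + Σₖ βₖ dₖ`, calibrated on authentic standards by ordinary least
squares, predicts retention time; candidates more than 45% off the
prediction are rejected. Retained candidates get a deterministic 1–10
confidence score (mass error, RT deviation, database priority) and the
best-scoring metabolite is selected, then rolled up to pathways.

**Targeted screen.** Alkylsuccinates C₍ₙ₊₄₎H₍₂ₙ₊₆₎O₄ and benzylsuccinates
C₍₁₁₊ₘ₎H₍₁₂₊₂ₘ₎O₄ — diagnostic products of anaerobic hydrocarbon
activation by addition to fumarate — are screened at ±2 ppm mass and ±10%
retention time, with RTs interpolated along the homolog series from
standard anchors. Aerobic products (hydroxylated aromatics) are screened
as single targets.

**Odd-mass statistic.** By the nitrogen rule, a CHNOPS molecule has an odd
nominal mass exactly when it has an odd number of nitrogen atoms. The
organonitrogen signal of a sample is summarized as

```
RN = Σ abundances of odd-nominal-mass features / Σ abundances of all features
```

reported in percent, for all features and for the identified subset.

**System comparison.** Per-system abundances (HC = HC3+HC11, LC =
LC3+LC11) feed differential-feature selection (>10,000 i.u. in at least
one system and a ≥5-fold ratio), a fold-ratio similarity summary, the
identified:non-identified ratio among the top-200 features, and a PCA of
replicate abundance profiles.

**Metagenome arithmetic.** Gene counts are normalized to hits per million
reads; gene families are compared between systems as fold ratios; genome
bins are called positive for terminal-electron-acceptor pathways
(denitrification, sulfate reduction, …) from their gene annotations; and
the fraction of community cells carrying a pathway in sample *s* is
estimated from bin coverage:

```
fraction(s) = Σ over pathway-positive bins  coverage_s × bin_length / total_bases_s × 100%
```

A seeded synthetic-data module generates every input with recorded ground
truth (Poisson shot noise, calibrated RN shares, spiked succinate series,
configurable bin communities), so the whole pipeline is testable offline.

## Worked example

```python
from corrosomics import GeneratorConfig, simulate_metabolome, rn_statistic, \
    system_sums, differential_features
from corrosomics.feature_pipeline import filter_low_abundance, qc_shot_noise
from corrosomics.targeted_screen import reference_targets, screen

bundle = simulate_metabolome(GeneratorConfig(seed=1))
table, report = filter_low_abundance(bundle.table, 1000.0)
print(f"retained {report.n_retained} of {report.n_input} aligned features")
print(f"shot-noise consistent fraction: {qc_shot_noise(table).consistent_fraction:.3f}")
for s in ("LC3", "LC11", "HC3", "HC11"):
    print(f"RN[{s}] = {rn_statistic(bundle.table, s).rn_percent:.1f}%")
diff = differential_features(system_sums(table))
print(f"HC-enriched: {diff.hc_enriched_count}, LC-enriched: {diff.lc_enriched_count}")
series, singles = reference_targets()
for h in sorted(screen(table, series, singles), key=lambda h: h.n):
    print(f"detected {h.series_name} n={h.n}: {h.mass_error_ppm:+.2f} ppm")
```

prints

```
retained 898 of 1005 aligned features
shot-noise consistent fraction: 0.982
RN[LC3] = 40.0%
RN[LC11] = 55.0%
RN[HC3] = 40.0%
RN[HC11] = 30.0%
HC-enriched: 43, LC-enriched: 21
detected alkylsuccinate n=2: +0.32 ppm
detected alkylsuccinate n=3: +0.39 ppm
detected alkylsuccinate n=4: +0.14 ppm
detected alkylsuccinate n=5: +0.19 ppm
detected alkylsuccinate n=6: +0.24 ppm
```

Reading: 107 of the 1,005 aligned features fall below the 1,000 i.u. floor
in every sample; replicate scatter is almost entirely ion-counting shot
noise; the abundance-weighted odd-mass share RN rises with pig depth in
the low-corrosion system (40→55%) and falls in the high-corrosion one
(40→30%), the organonitrogen signature of the denitrifying community; 43
features are strongly HC-enriched versus 21 LC-enriched; and the complete
spiked alkylsuccinate homolog series (C2–C6 side chains) is recovered at
sub-ppm mass error — the fumarate-addition fingerprint of anaerobic
hydrocarbon degradation.

The same workflow runs from the shell:

```
corrosomics simulate --seed 1 --out inputs/
corrosomics run --features inputs/raw_features.tsv --library inputs/library.tsv \
    --standards inputs/rt_standards.tsv --bins inputs/bins.tsv \
    --gene-counts inputs/gene_counts.tsv --sizes inputs/metagenome_sizes.tsv \
    --out results/
```

which writes per-stage tables plus `report.json` / `report.txt`.

## Layout

- `src/corrosomics/chem_mass.py` — formulas, exact masses, adducts, nitrogen rule
- `src/corrosomics/feature_pipeline.py` — alignment, filtering, shot-noise QC
- `src/corrosomics/annotate.py` — library matching, QSRR RT model, confidence, pathways
- `src/corrosomics/targeted_screen.py` — succinate homolog series, ±2 ppm/±10% screen
- `src/corrosomics/metabolome_stats.py` — RN, differential features, ratios, PCA
- `src/corrosomics/metagenome_tea.py` — per-million frequencies, pathway calls, cell fractions
- `src/corrosomics/synthetic_data.py` — seeded generators with ground truth
- `src/corrosomics/cli.py` — click CLI and end-to-end orchestration
- `docs/methods.md` — models, assumptions, parameter choices, limitations
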