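# Methods

This note documents the models behind `corrosomics`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions used throughout.

## Exact-mass arithmetic

Monoisotopic masses are summed from a packaged IUPAC constants table
(`data/element_masses.tsv`, ≥6 decimals; CHNOPS plus halogens). Average
(standard-atomic-weight) masses back the mg/L → mM concentration helper.
ESI adduct conversion uses the proton mass 1.007276 Da — not the hydrogen
atom mass — because the electron stays with the neutral: [M+H]⁺ observes
M + m_p, [M−H]⁻ observes M − m_p. Only singly charged
protonated/deprotonated adducts are registered by default; the adduct
registry is an ordinary dict and extensible.

The formula grammar is deliberately minimal — element symbol plus optional
positive integer count, no parentheses, charges, or isotope labels — which
covers every formula the analysis handles (small metabolites ≤ 500 Da).

### The nitrogen rule and its domain of validity

For an even-electron CHNOPS molecule, valence closure forces
H ≡ N + P (mod 2), and since only ¹H (mass number 1) and ³¹P contribute
odd integer mass, the nominal mass is odd exactly when the nitrogen count
is odd. The rule is a statement about *valence-consistent formulas*;
arbitrary element multisets (e.g. "CH") violate it, and the property tests
therefore sweep formulas with a non-negative ring-plus-double-bond count
and the correct hydrogen parity.

Applied to a *measured* neutral mass, the rule needs a nominal mass from
rounding. We round half-up (`floor(m + 0.5)`). The cumulative mass defect
of H (+0.00783/atom) pushes the fractional mass up with size; parity calls
are flagged unreliable above 500 Da (default, configurable), below which
the defect stays safely under half a dalton for the compound classes
handled here.

## Feature alignment and filtering

Raw per-replicate observations are merged by **single-linkage transitive
closure**: two observations in the same ionization mode are linked when
their mass difference is within 6 ppm (computed against the pair mean, so
the comparison is symmetric) *and* their retention times are within
0.25 min; connected components become features. Tolerance comparisons are
inclusive (≤). Merged mass and RT are abundance-weighted means; merged
abundance per (sample, replicate) is the member sum, so total abundance is
conserved. Chained merges can in principle span more than the pairwise
tolerance — a known property of single linkage, accepted here because the
alignment upstream of this package behaves the same way; re-alignment of
merged centroids is stable in practice (tested on seeded random tables)
though not a theorem.

Features recovered in both ionization modes under the same tolerances are
counted once: the mode with the higher total abundance keeps its values
and the feature is flagged `both`.

The abundance floor removes a feature only when its per-sample mean (over
replicates — the aggregation is our choice; any single per-sample number
must come from the triplicate somehow, and the mean is what the RSD QC is
defined against) is below 1,000 i.u. in **every** sample; the cut is
strict, so an exactly-1,000 mean retains.

**Shot-noise QC.** The detector registers ≈12.5 i.u. per ion, so an
abundance A corresponds to N = A/12.5 ions and Poisson counting alone
gives RSD = 1/√N. A triplicate is flagged consistent when its observed
RSD (sd/mean, ddof = 1) is within 2× that expectation; the factor 2
absorbs the heavy upper tail of a 2-df sd estimate (P(χ²₂ ≤ 8) ≈ 0.98).

## Retention-time model and annotation

The QSRR model is ordinary least squares of retention time on six
physico-chemical descriptors plus an intercept, fitted with statsmodels.
The descriptors are treated as an opaque ordered vector supplied with the
library: their chemical identity is irrelevant to the arithmetic, and
fixing an identity would add nothing testable. At least 8 standards
(7 parameters + 1 residual df) and a full-rank design are required;
33 standards with ~0.5 min residual noise is the calibration scale the
defaults model.

Candidates match on |Δm/m| ≤ 6 ppm against the library formula's
monoisotopic mass. The RT gate — reject when |observed − predicted| /
predicted > 0.45 — applies only to features seen in positive mode (the
HILIC separation the model describes); the deviation is relative to the
predicted RT, not to run length. A candidate whose library reference RT is
within 10% of the observed RT counts as matched to an authentic standard.

**Confidence rubric (1–10).** Documented stand-in with the three stated
ingredients: start at 10; subtract up to 3 linearly in |ppm|/6, up to 3
linearly in RT-deviation/0.45 (flat 1 when no prediction exists), and 0–3
by database rank (KEGG > MetaCyc > HMDB > LipidMaps by default —
configuration, not chemistry); round half-up, clamp to [1, 10]; a
standard match forces 10. Best-match selection orders by confidence, then
database rank, then |ppm|, then compound id — a total order, so the winner
is independent of candidate ordering.

## Targeted succinate screen

Homolog formulas: alkylsuccinates C₍ₙ₊₄₎H₍₂ₙ₊₆₎O₄ (n = alkyl-chain
carbons), benzylsuccinates C₍₁₁₊ₘ₎H₍₁₂₊₂ₘ₎O₄ (m = additional
methyl/alkyl carbons). Expected RT along a series is piecewise-linear in
carbon number through the standard anchors — the standard chromatographic
assumption for homolog series, an approximation flagged as such — with
linear extension (flagged `extrapolated`) beyond the anchored range, a
single anchor gating only its own member, and no anchors degrading to a
flagged mass-only screen. Detection needs |Δm/m| ≤ 2 ppm and, when an RT
expectation exists, |rt − expected|/expected ≤ 0.10. All co-qualifying
features are reported (positional isomers co-elute near-isobarically);
the most abundant per target is flagged rather than silently chosen.

## Metabolome statistics

**RN** is the abundance share of odd-nominal-mass features, per sample,
as a percent; abundances are per-sample replicate means. For annotated
features the formula's nitrogen parity may override the mass-rounding call
(the rule is exact when the formula is known). RN is scale-invariant and
bounded in [0, 100]; zero total abundance is an explicit error.

**Differential features** operate on per-system sums (HC = HC3 + HC11,
LC = LC3 + LC11). A feature is enriched in a system when at least one
system's sum is strictly above 10,000 i.u. and the ratio in its favor is
≥ 5 (inclusive); a zero denominator with the numerator above the gate
counts as infinitely enriched. The HC- and LC-enriched sets are disjoint
for any ratio gate > 1.

**Similarity summary**: fraction of features present in both systems with
max/min ratio < 3; one-sided features are tallied separately rather than
entering the fraction.

**PCA** takes individual sample × replicate abundance vectors as
observations (replicates, not sample means — the replicate scatter is part
of the signal being displayed), gated at ≥ 10,000 i.u. per-sample mean in
at least one sample, optionally log10(x+1)-transformed, mean-centered per
feature and decomposed by SVD (scikit-learn, full solver). No
unit-variance scaling: absolute abundance differences are meaningful in a
single-batch design.

## Metagenome arithmetic

Gene frequencies are counts per million mapped reads. Pathway presence on
a genome bin is a conjunction of alternative-gene groups (e.g.
denitrification = {narG|napA} ∧ {nirS|nirK} ∧ {norB} ∧ {nosZ}; sulfate
reduction = dsrA ∧ dsrB); the definitions are configuration (YAML), not
code, because marker-gene choices are a judgment call that varies by
annotation source.

The cell-fraction estimator uses coverage × bin length = bases recruited
to the bin, divided by total bases sequenced in the sample. The
denominator is the whole metagenome, not the binned portion, so fractions
across pathways do not sum to 100% when binning is incomplete — that is a
feature, not a defect: the estimate is "share of all sequenced cells",
assuming roughly uniform genome sizes and no coverage bias. Where
metagenome sizes are needed in reads, the packaged sizes table derives
reads as bases / 250 bp mean read length.

## Synthetic-data generator

The generator emulates the study design end to end at desk scale: four
samples (two systems × two pig runs), triplicates, two ionization modes,
600 library metabolites + 400 exochemical background features + an
alkylsuccinate spike-in series (problem sizes chosen so the full suite
runs in seconds; the real survey is an order of magnitude larger).

* **Formulas** are valence-consistent CHNOPS draws (H derived from a
  sampled unsaturation count), so nitrogen-rule parity is exact by
  construction. Library masses keep ≥ 25 ppm mutual separation and stay
  clear of all screening-target masses, making exact-mass annotation
  unambiguous — real libraries are *not* separated, so annotation recall
  on synthetic data says nothing about isobaric ambiguity in real data.
* **Abundances** are log-normal true means (median ~10³·⁵ i.u., sd 0.6
  dex) with a system-enrichment effect (1.2 dex) on 7%/4% of compounds
  (HC/LC), pig-run jitter of 0.15 dex, and Poisson ion-count replicate
  noise at 12.5 i.u./ion. Per-sample odd-mass abundance shares are then
  calibrated multiplicatively to RN targets of 40/55/40/30%
  (LC3/LC11/HC3/HC11) — the observed survey values, used here as
  generator parameters, not as test oracles.
* **Exochemicals** get masses rejection-sampled to match nothing at the
  annotation tolerance (clearance 10 ppm), emulating non-identifiable
  background; real unidentified features are unidentifiable for messier
  reasons (adducts, fragments, isotopologues) that are not modeled.
* **Spike-ins** place alkylsuccinates C2–C6 at their authentic-standard
  retention anchors with ≤ 1 ppm mass error, abundant predominantly in
  HC11.
* **Metagenomes** invert the estimator: coverage = fraction ×
  total_bases / length × lognormal noise (σ = 0.02). Default bin
  fractions are chosen so the true pathway-positive cell fractions are
  78/39% (denitrification in LC3/LC11) and 29/34% with a 1.5/1.6%
  minority (sulfate reduction in HC/LC). Metagenome sizes are the
  packaged per-sample base counts.

Everything is driven by one `numpy` Generator seeded from the config;
identical seeds give identical tables (integer draws exactly; floating
point identical on one platform, not guaranteed across BLAS builds).

What passing tests on this generator show: the estimators invert their
own generative model at the configured noise levels. What they do not
show: robustness to retention drift, batch effects, adduct/fragment
clutter, chimeric bins, or annotation error in real data.

## Numerical conventions and edge cases

* ppm between two measured masses uses the pair mean; ppm of a measurement
  against a theoretical mass uses the theoretical mass.
* Nominal mass: round half-up. Confidence scores: round half-up, clamp.
* All tolerance gates are inclusive (≤).
* Zero-abundance merge groups fall back to unweighted means.
* Zero denominators: fold ratios and differential ratios return flagged
  infinities, never exceptions; RN with zero total abundance raises.
* Ties in best-match selection and top-N ranking break deterministically
  (documented orderings), so outputs are byte-reproducible for a seed.

## Known limitations

Single-linkage alignment can chain; no retention-time warping across
batches; charge states > 1, adducts beyond (de)protonation, and isotope
patterns are out of scope; the confidence rubric is a documented
convention, not a reimplementation of any proprietary scoring; pathway
definitions are minimal marker sets; the cell-fraction estimator assumes
unbiased coverage and complete pathway annotation within bins.
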