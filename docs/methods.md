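# Methods

## Scope and model

kinomescreen analyzes arrayed loss-of-function viability screens: each
384-well plate carries one siRNA pool per library well (columns 5–24,
row-major), negative controls (Rluc, no human target) at G04–J04,
positive controls (UBC, essential gene) at F03–I03, untreated wells
(default K03–N03, configurable — assay plans rarely fix their positions,
so the default is explicit) and filler wells in the remaining control
columns. The readout is luminescence (RLU), proportional to viable cell
number. A *screen* is one pass of one cell preparation over all library
plates; preparations are nested in donors, and each preparation is
screened in technical replicates (default: duplicate).

## Scoring pipeline

Gene scoring treats plate effects as multiplicative and works on the
log₂ scale, in this fixed order:

1. **Multiplicative plate scaling.** Every well is divided by the median
   RLU of the plate's library wells; log₂ of the ratio is taken. The
   library median of each plate is 0 by construction, so cell-number,
   reagent-lot and reader-gain differences between plates cancel. Wells
   with zero RLU get relative viability 0 and are excluded from
   log-scale statistics with a logged warning.
2. **Variance adjustment by experiment.** Within each replicate screen
   (one preparation × one replicate, across its plates), log₂ ratios are
   divided by the screen's robust spread, 1.4826 × MAD of library-well
   values. The MAD is used rather than the sd because up to ~13 % of
   kinase knockdowns carry real phenotypes that would inflate a plain
   sd; a plain-sd estimator is available via `estimator="sd"`.
3. **Replicate summarization.** The median across technical replicates,
   per (gene, sample) — robust to a single failed screen. With the
   default two replicates it equals the mean.
4. **Plate-mean z-scores.** Summarized values are standardized per
   source plate against the mean and sample sd of that plate's *library*
   genes. Control wells are excluded from the plate statistics so that
   control performance cannot bias gene scores. The sentence order of
   the pipeline (summarize, then z-score) follows the screening
   convention; computing z per replicate first and summarizing after
   gives nearly identical scores at duplicate depth but is not what the
   pipeline does.

Two control-referenced products are computed alongside:

- **Relative viability** — RLU divided by the plate mean of the
  untreated + negative-control wells (the assay's no-effect reference;
  configurable to negative controls only). Used for fold-change hit
  calling, on the linear scale.
- **Fingerprint values (`log2_ctrl`)** — log₂(RLU / plate mean of
  negative-control wells), then centered by the plate's library-well
  median. The centering step matters: the negative-control mean of a
  plate is estimated from 4 wells sharing one reagent batch per screen,
  and dividing by it alone would inject that shared estimation noise
  into every gene on the plate, visibly deflating replicate
  correlations. Library-median centering removes it while leaving the
  control-anchored interpretation intact. `center_fingerprint=False`
  disables the centering.

All steps are invariant to multiplying a plate's RLU by any positive
constant.

## Quality control

- **Z′-factor** per plate, `1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|`,
  computed on raw control RLU (the statistic is invariant under common
  positive affine transforms, so raw RLU and relative viability give
  identical values). Both mean and median across plates are reported,
  0.5 being the conventional floor for an excellent assay.
- **Profile correlations**: Pearson r between single-replicate
  fingerprints of one sample (technical level) and between
  replicate-summarized fingerprints of different samples, labeled
  preparation / donor / cross-class from the sample annotations.
- **QQ tail analysis**: sorted z-scores against Φ⁻¹((i−½)/n) with the
  identity reference (inputs are standardized); genes deviating below
  by more than `delta` (default 0.5) count as lower-tail excess,
  symmetrically above. The default `delta` is a reporting choice, not a
  test: even exactly normal screens of 778 genes show a ±0.5 deviation
  of an extreme order statistic in roughly 15 % of realizations, so
  single-gene excess counts should be read as descriptive, and the
  meaningful signal is the lower-vs-upper asymmetry.

## Hit calling

Candidates are genes whose replicate-summarized relative viability,
averaged over an explicit sample subset, is ≥ 1.20 (growth increase) or
≤ 0.75 (growth/viability decrease); thresholds are inclusive and
configurable. The candidate set is monotone in the thresholds. No
off-target modeling or re-test logic is included.

## Fingerprinting and the differential panel

The fingerprint matrix (genes × samples of summarized `log2_ctrl`
values) feeds three analyses:

- **Sample correlations** — pairwise Pearson r over gene profiles.
- **Biclustering** — agglomerative clustering of both axes with
  distance 1 − Pearson r and average linkage; "standard settings" of the
  common heatmap tools. Leaf order is optimized (minimal sum of
  adjacent-leaf distances). Zero-variance rows/columns, for which
  correlation is undefined, are assigned the maximal distance 2 to all
  other items with a logged warning. Samples are cut into k flat
  clusters (default k = 2, the MSC-vs-fibroblast question).
- **Differential panel** — preparations of the same donor are first
  averaged into one profile (they are not biologically independent;
  unweighted mean), fibroblast subtypes form one class; then each gene
  gets an unpaired two-tailed Student *t*-test (equal variance,
  df = n₁+n₂−2) between classes. Welch's correction is deliberately not
  used — the equal-variance Student test is the stated analysis
  convention at these group sizes. Selection is p ≤ α (default 0.05)
  with **no multiple-testing correction by default**, mirroring the
  exploratory character of the analysis; `correction="bh"` enables
  Benjamini–Hochberg. Cohen's d = |mean difference| / pooled sd, and
  post-hoc power comes from the noncentral t distribution with
  ncp = d·√(n₁n₂/(n₁+n₂)): P(|T′| > t₁₋α/₂,df). At d = 0 the power
  equals α exactly; for extreme ncp where the noncentral-t evaluation
  overflows, a normal approximation (accurate there to < 1e−6) is
  substituted and the result clipped to [α, 1]. Power is computed per
  gene; averaging d within a gene cluster first is a caller-side option.
  Genes with zero pooled variance are excluded and logged.

## Synthetic screens

`simulate_screen` draws

    RLU(well) = baseline_plate · 2^(θ_g + Δ_g[class] + ν_donor + ν_prep + ν_screen + ε_well)

with per-plate log-normal baselines (median 20 000 RLU, log-sd 0.25) and
per-gene deviations at four levels. Defaults (log₂ units):

| parameter | default | role |
|---|---|---|
| effect mixture | 10 % kill N(−0.9, 0.35²), 3 % enhance N(+0.35, 0.12²), rest N(0, 0.05²) | heavy lower phenotype tail; ~10 % of genes below 75 % viability |
| σ_well | 0.08 | pipetting/reader noise per well |
| σ_screen | 0.11 | per-gene, per-replicate-screen deviation |
| σ_prep | 0.08 | per-gene deviation between preparations of a donor |
| σ_donor | 0.17 | per-gene deviation between donors |
| θ_pos | −2.74 | positive-control effect (~15 % viability), well clear of the negative controls |
| n_differential | 35, magnitudes U[0.6, 0.9], split 18/17 between a stronger-in-MSC and a stronger-in-fibroblast cluster, kill-direction | planted class-differential panel |

The noise sds were chosen so that the closed-form profile correlation
(`expected_profile_correlation`, r = V_shared/(V_shared + V_profile),
where deviations below the comparison level count as shared signal and
those at or above it as per-profile noise, technical noise divided by
the replicate count when summarized) reproduces the reproducibility
hierarchy of a well-behaved primary-cell screen: ≈ 0.88 technical,
≈ 0.90 preparation (summarized), ≈ 0.70 inter-donor. The planted
differential magnitudes start at 0.6 log₂ because the panel emulates
*detected* class-differential genes — effects strong enough that the
two-sample t-test at N = (2, 4) retains high power (> 0.9 at the top of
the range), consistent with a post-hoc power ≥ 0.9 for an identified
panel; weaker offsets would mostly be undetectable at these group sizes
by construction. Control wells share a per-screen reagent deviation
(sd σ_screen) per control siRNA; untreated and filler wells read the
baseline with well noise only. An optional edge effect (default off)
depresses the outer well ring as a robustness stressor.

What the simulator does **not** emulate: spatial gradients within
plates (beyond the optional edge ring), dispensing failures and
row/column artifacts, siRNA off-target structure, correlated
gene–gene effects, or donor-specific global growth differences. Tests
passing on simulated screens therefore demonstrate the correctness and
calibration of the statistics, not robustness to every real-world
plate pathology (the pipeline deliberately contains no B-score or
spatial smoothing).

## Numerical choices and degenerate inputs

- Medians follow the numpy convention (midpoint of the two central
  values at even n); ties in hit and panel sorting are broken by gene id
  for determinism.
- Degenerate inputs raise typed errors rather than propagating NaNs:
  zero control means, constant plates, zero robust spread, equal control
  means in Z′, constant profiles in correlations, < 10 z-scores in the
  QQ analysis.
- All simulation randomness flows from a single `numpy` generator
  seeded by `SimulationConfig.seed`; a fixed configuration is
  bit-reproducible, and the CLI chain writes byte-identical outputs
  under a fixed seed (the `run-all` command round-trips its own TSVs so
  the staged and single-command paths agree exactly).
- Score TSVs carry 12 significant digits; measurement TSVs carry 17
  (lossless for doubles), so write → read is the identity.

## Problem sizes used in the shipped checks

Calibration quantities are measured on 25 independent simulated screens
(778 genes each) per statistic and 100 plates for the Z′ floor; the
power calibration uses a 100 000-replicate Monte-Carlo t-test and the
type-I check 10 000 null genes. These sizes put Monte-Carlo standard
errors well inside the tolerances being checked (e.g. se(r̄) ≈ 0.002,
se(power) ≈ 0.0016).

## Known limitations

- The equal-variance t-test is mildly anticonservative when the smaller
  group has the larger variance; with the default grouping the averaged
  MSC profile has slightly *lower* variance, which is the conservative
  direction (measured type-I ≈ 0.046 at nominal 0.05).
- With only two MSC profiles, per-gene variance estimates at df = 4 are
  noisy; the uncorrected p ≤ 0.05 panel contains an expected ~5 % of
  null genes (~39 of 778) alongside the planted effects. That is the
  price of the exploratory design, and why the panel is reported with
  effect sizes and power rather than as a significance claim.
- The closed-form correlation oracle assumes effects and noises are
  independent across genes; it is exact for the simulator but only a
  first-order guide for real screens with correlated biology.
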