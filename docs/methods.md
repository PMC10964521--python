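# Methods

This note documents the models, conventions and design choices behind
`droughtscreen`, in the spirit of a statistical-software methods appendix.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Tolerance indices and the STS score

The screening model treats a trial as a set of genotypes observed in two
environments: non-stress yield `Yp` and stress yield `Ys` (any consistent
units; `Yp > 0`, `Ys ≥ 0` enforced — a record violating this is rejected
with an error rather than silently dropped, because silent dropping changes
the population means that SSI and STI depend on). Population quantities
(Ȳp, Ȳs, SI = 1 − Ȳs/Ȳp) are always taken over all genotypes in the input
table. SSI is undefined when SI = 0 (no stress differential) and this is an
error, not a NaN.

The composite score is the raw sum

```
STS = GMP + STI + HM + MP − TOL − SSI − b .
```

Three conventions deserve explanation:

- **`b` is per-genotype.** The sensitivity coefficient is read as the
  Finlay–Wilkinson slope: the least-squares regression of genotype *i*'s
  yields on the environment mean yields. A single population-level slope
  would be a constant offset to every genotype's STS and could never move a
  rank, so the per-genotype reading is the only one under which the term
  participates in selection. With exactly two environments the slope
  collapses to `(Yp_i − Ys_i)/(Ȳp − Ȳs)`; `compute_b` also accepts ≥ 3
  environment columns. All environment means equal ⇒ the slope is
  undefined ⇒ error.
- **Raw components.** The six indices have different scales, and a z-score
  standardization before summing is a defensible alternative; it is
  available (`standardize=True`) but off by default, since the published
  per-genotype scores are consistent with a raw sum and a default should
  not quietly rescale a selection criterion.
- **Deterministic ranking.** Rank 1 = largest STS; ties broken by ascending
  genotype identifier. The genotype → rank map is a pure function of the
  (genotype, STS) pairs, invariant to row order — property-tested.

Classification of extremes is parameterized (`k_tolerant`, `k_sensitive`,
defaults 9 and 11, the sizes of the selections in the field screen this
package mirrors); no absolute STS cutoff exists in the field's practice.

The packaged table `data/table1_sts.csv` transcribes the published field
screen (114 genotypes, STS and rank). It is stored with a sha256 verified
at load time. Re-ranking its STS column reproduces its rank column exactly,
which is the pipeline's strongest external anchor.

## Relative expression (comparative CT)

Pure Livak quantification: amplification efficiency is assumed exactly 2,
so fold change = 2^−ΔΔCT. Primer efficiencies estimated from dilution
series (E = 10^(−1/slope) − 1, slope of CT on log10 input) are reported for
QC only and never folded into quantification — efficiency-corrected
(Pfaffl) quantification is out of scope.

Conventions: technical replicates are collapsed by the arithmetic mean of
CT before ΔCT; biological replicates are preserved and flow into the ANOVA
stage. The calibrator for each (genotype, gene) is the same genotype's
well-watered control cell, with its ΔCT averaged over the calibrator's
biological replicates; consequently a calibrator cell's mean ΔΔCT is 0 and
its geometric-mean fold change exactly 1 (the per-replicate calibrator
folds scatter around 1 under noise, which is correct behaviour, not an
artefact). Fold-change summaries are geometric means (arithmetic mean of
ΔΔCT back-transformed). CT values outside [5, 45] trigger a warning, not
rejection. The downstream ANOVA of expression is run on fold changes by
default; running it on ΔΔCT instead is a caller-level choice since the
fold table carries both columns.

## Pigments

The second displayed formula in the source protocol is printed with the
label "Chl a" but carries chlorophyll-b coefficients; it is implemented as
**Chl b** (20.13·A646 − 5.1·A663), matching the standard
Lichtenthaler-style coefficient sets. The carotenoid formula's printed
bracketing is ambiguous; it is resolved as the whole numerator over 227.
Units are µg/ml of 96% ethanol extract — the protocol states none, so this
is a documented assumption; `to_mg_per_g` converts using the protocol's
2 ml extract per 25 mg tissue (1 µg/ml ≙ 0.08 mg/g fresh weight).

All four outputs are linear in the absorbances, so the map
(Chl a, Chl b, Car) → (A663, A646, A470) is an invertible linear system
(the 2×2 chlorophyll block has fixed positive determinant ≈ 231.4). The
generator exploits this to fabricate absorbance panels whose pigment truth
is exact to machine precision; targets requiring negative absorbances are
rejected as nonphysical. Negative computed carotenoids are flagged with a
warning but returned, since rounding a QC signal to zero would hide it.

## Factorial ANOVA and Duncan grouping

`anova_two_factor` is the classical balanced fixed-effects decomposition
for a genotype × stress CRD with r replicates per cell, computed in closed
form (marginal and cell means). Imbalance is an **error**: the closed form
is only valid for equal cell counts, and silently switching to a Type-II/III
least-squares decomposition would change the meaning of the sums of
squares. One replicate per cell leaves no error term and is likewise an
error. The implementation is cross-checked in the test suite against
statsmodels' `anova_lm` (which serves as oracle, never as implementation)
and against an explicit-loop reference; agreement is required to 1e−8
relative. CV% = 100·√MSE/|grand mean|, undefined (error) at zero grand
mean. Significance stars use `p ≤ 0.05` / `p ≤ 0.01`.

Duncan's multiple range test computes, for every span p = 2..k of the
descending-ordered means, the least significant range
R_p = q(α_p, p, df_E)·√(MSE/r) with protection level
α_p = 1 − (1−α)^(p−1), using scipy's studentized-range distribution (the
quantile is cached per (α, p, df) — it involves numerical integration).
Letters come from the classical underlining rule: maximal runs of means
whose extremes differ by at most their span's R_p share a letter; the
containment protection (a non-significant range protects everything inside
it) is implied by taking maximal runs, and the test suite verifies the
resulting letter-sharing relation pair-by-pair against a literal
every-containing-range check. α defaults to 0.05. Two means closer than
R_2 are never separated (property-tested). Comparisons are run on the
genotype × stress cell means, the level at which lettered groups are
reported in this literature.

## Synthetic data: what it emulates, and what it does not

The generators are first-class, tested code; their defaults are the study
conditions, not tuning knobs:

- **Field trial**: 114 genotypes; 9 tolerant / 11 sensitive / 94
  intermediate (the sizes of the screen's selected extremes); control
  yields log-normal (yields are positive and right-skewed) with mean 10
  arbitrary units and CV 0.3; stress yields apply archetype reductions of
  0.2 / 0.45 / 0.7 with 10% multiplicative Gaussian noise. Truth labels
  are always emitted so recovery tests never re-derive them.
- **Greenhouse**: genotypes 88 (tolerant) and 72 (sensitive) × three
  soil-moisture levels (90–95 / 50–55 / 25–30% of field capacity), three
  replicates for traits, 2 biological × 2 technical for expression.
- **Expression truth**: the per-(gene, genotype, treatment) fold table
  defaults to the study's reported values (Dhn1 12.51/5.15 tolerant and
  2.86/4.69 sensitive; CAT 7.36/3.55 tolerant; POD 7.07 vs 3.89 and SOD
  7.39 vs 3.60 at severe stress). Cells the study does not report
  (mild-stress POD/SOD, the sensitive genotype's CAT) are filled once by
  the geometric midpoint between 1 and the severe value — a neutral
  monotone interpolation — and not revisited. Target CTs sit ~2–5 cycles
  above the reference baseline of 20; well noise is N(0, 0.15²) cycles.
  With zero noise the expression module recovers the configured folds
  exactly (round-trip property).
- **Traits**: additive cell-mean model, grand mean 10, genotype effect 1.0,
  stress span 2.0, crossed interaction 1.5, residual σ = 0.5. The
  interaction size was fixed a priori by noncentral-F power analysis:
  λ = r·Σγ²/σ² = 27 gives power ≈ 0.99 for F(2,12) at α = 0.05, clearing
  the ≥ 0.9 design requirement with margin.
- **Pigments**: baseline (8, 3.5, 2.5) µg/ml retained at archetype- and
  stress-dependent fractions, then inverted to absorbances.

Determinism: each generator draws from `default_rng([seed, stream])` with a
fixed per-generator stream id, so tables are bit-reproducible for a given
config and independent across generators.

What the generators deliberately do **not** emulate: field spatial
heterogeneity and the augmented-design check-plot adjustment, year × 
genotype structure beyond the two-environment contrast, qPCR artefacts
(efficiency drift, off-target amplification, Poisson sampling at low
copy number), pigment matrix effects, or heteroscedastic trait noise.
Passing tests therefore demonstrate correctness of the *computations* and
internal consistency of the method under its own assumptions — not that the
generator's numbers resemble any particular real dataset beyond the
published fold changes and the design shape.

## Problem sizes and numerical choices

The Monte-Carlo checks use 100 simulated field trials for archetype
separation, 2000 null simulations for the type-I calibration of the G × S
F-test (empirical rate required within [0.03, 0.07] at nominal 0.05) and
200 simulations for power — sizes chosen so the whole calibration runs in
seconds on one CPU while the binomial standard error (~0.005 at n = 2000)
is well inside the acceptance band. Index identities are asserted to 1e−9
relative, ANOVA oracle equality to 1e−8 relative, pigment round trips to
1e−9 absolute; these reflect double-precision arithmetic through sums of
tens of terms, not statistical tolerances.

## Known limitations

- The ANOVA is balanced-only by design; real unbalanced datasets need a
  least-squares ANOVA (statsmodels) upstream of the Duncan stage.
- Duncan's test is implemented because it is the field's reporting
  convention; it does not control the familywise error rate, and Tukey HSD
  would be the conservative alternative.
- The two-environment sensitivity slope is perfectly collinear with
  (Yp − Ys); with only Yp/Ys data, `b` adds a rescaled TOL term to STS
  rather than independent stability information. This is a property of the
  score's definition, not of the implementation.
- Fold-change ANOVA on the raw 2^−ΔΔCT scale (the default, matching
  common practice) is right-skewed; log-scale analysis via the ΔΔCT column
  is available and statistically preferable.
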