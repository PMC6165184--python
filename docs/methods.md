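# Methods

## Model and assumptions

`mrkit` implements summary-statistic two-sample Mendelian randomization.
The data are J independent SNPs; for SNP j the exposure GWAS reports an
effect `β_exp,j` (per allele, on the natural-log scale of the trait) with
standard error `se_exp,j`, and the outcome GWAS reports a log odds ratio
`β_out,j` with `se_out,j`. Under the instrumental-variable assumptions
(relevance, no confounding of the variant–outcome relation, and no effect
on the outcome except through the exposure) and an approximately linear
causal model on the log-odds scale,

    β_out,j ≈ θ β_exp,j + α_j ,

where θ is the causal log OR per ln-unit of exposure and α_j is a direct
(pleiotropic) effect, zero for a valid instrument. The estimators differ
in what they assume about the α_j:

- **Wald ratio** per SNP: `r_j = β_out,j / β_exp,j`, first-order standard
  error `se_out,j / |β_exp,j|`. The exposure-side noise is neglected, the
  standard convention for strong instruments (all fixture instruments reach
  p < 5 × 10⁻⁸); a consequence is that the weights below depend only on
  observed quantities.
- **IVW** assumes all α_j = 0. With `w_j = (β_exp,j / se_out,j)²`,
  `θ̂ = Σ w_j r_j / Σ w_j` and `se(θ̂) = (Σ w_j)^{-1/2}`. This is exactly
  weighted least squares of β_out on β_exp through the origin (the
  equivalence is asserted in tests to 1e-12 relative). The default is
  fixed-effect with z-based inference; `random_multiplicative` inflates the
  SE by `max(1, √(Q/df))`.
- **Weighted median** tolerates up to half the weight on invalid
  instruments. The ratios are sorted, standardized midpoint cumulative
  weights `s_j = (Σ_{i≤j} w_i − w_j/2) / Σ w` are formed, and the estimate
  is the linear interpolation of r at s = 0.5. Its SE comes from a
  parametric bootstrap: `β_out,j* ~ N(β_out,j, se_out,j²)` and
  `β_exp,j* ~ N(β_exp,j, se_exp,j²)` drawn independently, the weighted
  median recomputed per replicate with the weights held at their observed
  values (recomputing them changes the SE by < 1 % on the fixture but
  breaks the clean separation between the location statistic and its
  resampling distribution). Default 10,000 replicates; the seed defaults to
  a package constant and is recorded in the result metadata.
- **MR-Egger** relaxes the zero-pleiotropy assumption to InSIDE
  (pleiotropic effects independent of instrument strength): weighted
  regression of β_out on β_exp with weights `1/se_out,j²` and a free
  intercept. The intercept estimates the mean directional pleiotropic
  effect; the slope estimates θ. SEs are the weighted-least-squares ones
  inflated by `max(1, RSE)` where RSE² is the weighted residual mean square
  on J − 2 df; inference is normal by default with a Student-t (J − 2 df)
  option. The intercept requires a fixed orientation of the instruments;
  `mrkit` (like the orientation convention of the fixture) orients every
  instrument to its exposure-increasing allele. IVW is invariant under
  re-orienting any SNP; the Egger intercept is not (both asserted by test).
- **Cochran's Q** `= Σ w_j (r_j − θ̂_IVW)²` on J − 1 df tests ratio
  heterogeneity; it is dimensionless (invariant under per-SD rescaling)
  and zero iff all ratios coincide.
- **Leave-one-out** re-runs fixed-effect IVW omitting each SNP in turn.

**Per-SD reporting.** Causal estimates are multiplied by `sd_scale`, the
standard deviation of the ln-transformed exposure (0.33 ln-units for both
packaged exposures, from a population-based cohort), so results read as
log-OR (or OR) per SD. Rescaling multiplies estimate, SE and CI bounds by
the same factor, leaving z and p untouched, and commutes with pooling for
every implemented estimator (asserted by test). The Egger intercept is a
log-OR offset, not a per-ln-unit slope, and is never rescaled.

## Harmonization conventions

- Exposure records with negative beta are flipped to the other allele
  (negate beta, swap alleles, reflect EAF); the flip is involutive. The
  frequency reflection `1 − (1 − f)` is exact only to one ulp in floating
  point; tests compare EAF at 1e-15.
- With full allele pairs on both sides, the outcome pair must equal the
  exposure pair on the reported strand or its complement; the outcome beta
  is negated when its effect allele is the exposure's other allele.
  Anything else is a per-SNP error, not a silent drop.
- When either table lacks the other allele (published instrument tables
  often print only the effect allele), harmonization runs in *pre-oriented*
  mode: the outcome beta is trusted to refer to the printed exposure
  effect allele. The packaged tables are in this form.
- Palindromic variants (A/T, C/G): policy `drop`, `trust` (same strand), or
  the default `eaf_infer`, which aligns by comparing both allele
  frequencies to 0.5 and refuses when either is within `eaf_tolerance`
  (default 0.08, a conservative community convention) of 0.5.
- Proxy substitution assigns a high-LD proxy's outcome statistics to the
  target rsid (`proxied_by` records the provenance), refusing below
  `min_r2` (default 0.8).
- Instrument selection keeps p < threshold (strict, default 5 × 10⁻⁸) and
  prunes any pair with r² ≥ 0.05, retaining the smaller p-value; ties break
  by smaller SE, then lexicographic rsid (the fixture never exercises the
  tie-break; the rule exists to make pruning deterministic).
- Unit conversion for exposures reported per SD of the standardized
  ln-trait multiplies beta and SE by `sd_scale`, preserving the z-score.
  For the packaged rs117913124 this uses the analysis's own 0.33, the
  convention that reproduces the published pooled OR.
- GWAS p-values below the double-precision range (the packaged 4.74e-343)
  are clamped to the smallest positive double on read, keeping the (0, 1]
  invariant without discarding the row.

## Synthetic data

`simulate_instruments` draws `γ_j` from `gamma_dist` (default uniform on
[0.02, 0.10] ln-units), SEs from `se_exp_dist` (uniform [0.002, 0.02]) and
`se_out_dist` (uniform [0.016, 0.022]) — magnitudes of a small
serum-biomarker exposure GWAS and a ~50k-sample case-control outcome GWAS —
then `β_exp,j ~ N(γ_j, se²)`, `β_out,j ~ N(θγ_j + α_j, se²)`. Pleiotropy
regimes: `none`; `balanced` `α_j ~ N(0, τ²)`; `directional`
`α_j ~ N(μ_α, τ²)` (InSIDE holds since α is independent of γ);
`prop_invalid` restricts pleiotropy to a random SNP subset so
minority-invalid regimes for the weighted median can be generated. Sets
whose sampled exposure effect is negative are re-oriented exactly as
harmonization would. Replicate k of `run_replicates` uses
`numpy.random.SeedSequence(seed).spawn(n_reps)[k]`, making every
performance table bit-reproducible.

What the generator does *not* emulate: LD between instruments, winner's
curse in instrument selection, sample overlap between the two GWAS, and
non-collapsibility of the odds ratio under strong effects. Passing
calibration tests therefore validate the estimators under the stated
sampling model, not the full complexity of real GWAS pipelines.

Monte-Carlo problem sizes in the test suite — 2,000 replicates for null
calibration (type-I error, coverage), 300–500 for the pleiotropy
orderings, 12-SNP sets throughout — keep Monte-Carlo error well below the
asserted margins while the whole suite runs in seconds.

## Numerical and design notes

- All inference is two-sided; the CI level defaults to 0.95.
- Display rounding (ORs/CIs to 2 decimals, intercepts to 3, p-values to
  1–2 significant figures) is a reporting concern; files carry full double
  precision, and written summary tables round-trip bit-exactly via `repr`.
- The weighted-median interpolation clamps outside the midpoint range: if
  one instrument carries more than half the weight, its ratio is returned.
- Degenerate inputs raise typed errors naming the offending SNP or column
  (zero exposure beta, collinear Egger design, < 3 instruments for median/
  Egger/leave-one-out, empty method list) rather than propagating NaNs.

## Known limitations of the packaged example

The shipped tables carry the printed 2–3 decimal effect sizes, not the
unrounded source GWAS values. Two reported quantities sit exactly on a
rounding boundary as a result: the 25OHD weighted-median OR computes to
0.8751 (prints as 0.88 against the published 0.87) and the 25OHD IVW upper
CI to 0.9465 (0.95 vs 0.94). Every other published quantity — both IVW
ORs, CIs and p-values, the PTH weighted median, and both Egger
intercepts — reproduces at printed precision, and `reproduce_paper()`
flags exactly these two cells. The published weighted-median bootstrap CI
for PTH (0.97–1.34) is also slightly wider than the one computed here
(0.98–1.32); the original replicate count and seed are unknown. The Egger
intercept CI/p match only approximately because the original software's SE
convention is unstated; intercept point estimates match exactly.
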