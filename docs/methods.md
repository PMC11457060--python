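# Methods

This note records the statistical models implemented in `strigagp`,
the defaults that matter, the design choices that were genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Trait derivation

Emerged-parasite counts are recorded at 8, 10 and 12 weeks after
planting (WAP); the package converts weeks to days at 7 days/week
(56, 70, 84) and integrates the piecewise-linear progress curve with
the trapezoid rule, `AUSNPC = Σ (yᵢ + yᵢ₋₁)/2 · (tᵢ − tᵢ₋₁)`. The
result carries units of count·days; field reports sometimes label the
same number in m², and the label is left to the caller — the value is
identical. The damage score SDR is the arithmetic mean of the 10- and
12-WAP ratings on the 1 (healthy) to 9 (dead) scale. Grain yield is
`ear_weight · 0.80 · (100 − m)/(100 − 12.5) · 10/plot_area` t ha⁻¹
with a default plot of one 4 m row at 0.75 m spacing (3 m²); when no
per-plot moisture is recorded the moisture factor is 1 (grain assumed
at the 12.5 % reference).

## Trial mixed models

Single-site: `y_ijk = μ + G_i + R_j + B_k(R_j) + ε_ijk`; across-site:
`y_ijkl = μ + G_i + E_j + R_k(E_j) + B_l(ER)_jk + GE_ij + ε_ijkl`,
environment fixed, all other non-intercept terms random. The tester of
each testcross enters as an extra fixed effect and reported line values
are averaged over testers (the trials cross each DH line to two
testers; nothing in the data identifies a line×tester interaction, so
none is modelled). BLUEs come from the genotype-fixed generalized
least-squares fit at the REML components, BLUPs from the
genotype-random mixed-model equations.

Variance components are estimated by EM-REML on Henderson's equations:
monotone in the restricted likelihood, convergent from any interior
start, and exactly equal to the ANOVA expected-mean-squares estimators
on balanced designs (verified to 1e−10 in the tests; tolerance asserted
1e−4). Components are floored at 1e−8·var(y) during iteration and
reported as 0 when they finish at the floor. Convergence: relative
change of every component < 1e−8 or 200 iterations. A pseudo-inverse
fallback handles the near-singular equations that arise when several
components collapse simultaneously (e.g. a constant response).

Heritability on an entry-mean basis:
`H² = σ²G/(σ²G + σ²ε/R)` per site and
`H² = σ²G/(σ²G + σ²GE/E + σ²ε/(E·R))` across sites; an all-zero
denominator is defined as H² = 0. The LSD at α = 0.05 is
`t₀.₉₇₅(ν) √(2σ̂²ε/(R·E))` with ν the residual degrees of freedom.

For genomic prediction the response is the stack of per-environment
single-site BLUEs (one value per line × environment), since the
reaction-norm model carries its own environment effects. An
across-site BLUE path exists as well.

## Markers and kinship

Dominant rAmpSeq tags are 0/1 presence/absence calls; the minor-class
frequency `min(f₁, 1 − f₁)` plays the role of the minor allele
frequency. QC removes monomorphic/zero-variance tags and tags below
the MAF threshold (default 0.05). Missing calls stay missing in the
stored matrix and are mean-imputed per tag only for standardisation
(variance-neutral). Standardisation uses the population (divide-by-n)
variance so that `G = SS'/p` has mean diagonal exactly 1; `G` is
singular by construction (column centring puts the all-ones vector in
its null space), which the samplers accommodate by working in the
positive eigenspace — no ridge is ever added to the stored kernel.

## Reaction-norm model and sampler

`y = μ + Z_E β_E + Z_g g + u + e` with `β_E ~ N(0, σ²_E I)` (dummy
location effects, modelled as random with their own variance),
`g ~ N(0, σ²_g G)` over *all* lines (phenotyped or not), interaction
`u ~ N(0, σ²_gxE (Z_g G Z_g') ∘ (Z_E Z_E'))`, residual
`e ~ N(0, σ²_e I)`. Because the environment incidence kernel is 1 only
within an environment, the interaction kernel is block-diagonal by
environment, each block a submatrix of `G` — the sampler exploits this
and never forms the full observation × observation kernel.

Each Gaussian block is sampled through the eigendecomposition of its
kernel (computed once and cached): with the effect written as
`Φδ`, `Φ = V√Λ`, the full conditional of `δ` has precision
`Φ'Φ/σ²_e + I/σ²`, which is diagonal for balanced unmasked designs
(O(n) per sweep) and a ~n×n Cholesky solve otherwise. Variances take
scaled inverse-χ² priors with conjugate updates. Unphenotyped lines
are carried inside `G` during sampling, so their breeding values come
from the joint full conditional rather than post-hoc kriging; a
phenotyped line and its unphenotyped marker clone receive equal GEBVs
up to Monte-Carlo error (tested).

**Priors.** The prior scale is set so the mode equals a share of the
sample phenotypic variance: 0.5·var(y) for σ²_e and the remaining half
split equally among β_E, g and u. The prior degrees of freedom default
to **1** (weakly informative). This choice is deliberate: with only
three environments the interaction variance is weakly identified
(every eigen-coordinate of the interaction block has signal-to-noise
λσ²_gxE/σ²_e well below 1 at realistic values), and under a df = 5
prior with mode ≈ 2× the true value the posterior mean of σ²_gxE is
dragged ~35 % upward. With df = 1 the likelihood dominates wherever it
carries information, and simulation shows the posterior means of
(σ²_g, σ²_gxE, σ²_e) averaged over 20 trials land within 25 % of the
generating values. Prediction accuracy is essentially insensitive to
this choice; variance interpretation is not.

**Schedule.** Defaults follow common practice for this model class:
30,000 iterations, 15,000 burn-in, thinning 10 (1,500 retained draws);
`(iterations − burn_in)/thin` is floored when not divisible. Chains
are fully seeded and reproducible. Divergent variance draws abort with
the iteration index.

## Cross-validation

CV0 masks one environment entirely (one fold per environment) — the
prediction for a new environment is `μ + g` since the held-out
environment's β and u have no data and posterior mean ≈ 0. CV1 masks
every cell of a random 20 % of lines per fold; CV2 masks 20 % of
line×environment cells with the constraint that every line keeps at
least one observed environment (violations are repaired by re-drawing).
Accuracy is the raw Pearson r between observed and predicted values on
masked cells, computed per fold within each environment, averaged over
folds, and combined across environments by pair-count weighting (the
weighting rule is configurable; pair counts are the default because
environments contribute accuracy estimates with precision proportional
to their number of validation pairs). Fold-level r is averaged rather
than pooling pairs across folds. Environments with fewer than 3 masked
pairs in a fold are skipped with a warning. Accuracy is not divided by
√H².

## Synthetic data generator

The generator emulates: dominant biallelic tags with a controlled
frequency spectrum (carrier counts placed by permutation so realised
frequencies match the drawn ones); line main genetic values as linear
combinations of causal-tag genotypes, exactly rescaled so the realised
variance equals `var_genetic` (sharp recovery tests); G×E deviations
built from fresh per-environment effects on the same causal tags,
exactly scaled to `var_gxe` per environment and independent across
environments — keeping the simulated interaction inside the span of
the genomic kernel, i.e. the fitted model is correctly specified;
fixed additive tester offsets; environment, replicate-in-environment
and block-in-replicate effects; iid Gaussian plot error; and a
`round(max(0, ·))` mapping for count-like traits. The default
configuration mirrors the reference trial geometry: 116 lines × 2
testers at 3 locations × 2 replicates in blocks of 4, an 8,439-tag
panel, and components (σ²_G, σ²_GE, σ²_ε) = (80, 23, 323) typical of a
mid-heritability emerged-parasite count; σ²_env = 40 and rep/block
variances of 8 are plausible nuisance scales not separately reported
in trial summaries. `simulate_striga_dataset` produces a full
multi-trait phenotype file (counts at 3 WAPs, two ratings, ear weight
at 12.5 % moisture) over one shared field layout.

What the generator does **not** emulate: linkage/LD structure among
tags, pedigree relatedness, cross-trait genetic correlations,
non-Gaussian count dispersion, spatial field trends, or missing-data
patterns. Passing tests therefore demonstrate correctness of the
estimators under the assumed model, not robustness to these real-data
features.

## Test problem sizes and identifiability

The statistical acceptance tests run at deliberately reduced sizes:
variance recovery uses 300 lines × 3 environments × one cell each with
a 150-tag panel and a 3,000-iteration chain over 20 seeds; CV checks
use 10 folds at the same scale. The 150-tag (fewer tags than lines)
geometry is chosen so that all three variance components are actually
identifiable: the GRM then has null directions that pin σ²_e exactly
and a wide positive spectrum that informs σ²_gxE. In tag-rich panels
(tags ≫ lines, as in real rAmpSeq data) the GRM's spectrum
concentrates near 1 and σ²_gxE and σ²_e become nearly non-separable —
the maximum-likelihood estimator itself then has a per-dataset SD of
about half the parameter value, so no estimator could be validated
there; only the sum σ²_gxE + σ²_e and the predictions are stable.
Genomic prediction is unaffected by this confounding, which is why CV
accuracies are also reported at tag-rich scales without caveat.

## Numerical details and edge cases

Eigenvalues below 1e−8·λ_max are truncated from every kernel basis;
kernels with eigenvalues below −1e−8·λ_max are rejected as non-PSD.
Duplicate design keys, duplicate line ids, non-{0,1,missing} marker
tokens, phenotyped lines absent from the kernel, masked cells without
phenotypes, single-replicate sites, and constant traits in correlation
tables all raise typed errors (or warnings where the analysis can
proceed). Every output file records the package version, a
configuration hash (destination-independent) and the seed; rerunning a
pipeline with the same config and seed reproduces outputs byte for
byte.

## Known limitations

- EM-REML is dense; trials beyond a few thousand plots per fit would
  need sparse or average-information variants.
- One homoscedastic residual variance across environments; no spatial
  (row-column/AR1) adjustment.
- The reaction-norm model uses a single genomic kernel — no epistatic
  or environmental-covariate kernels, no multi-trait model.
- Variance-component significance is not tested (no LRT machinery);
  components are reported with no stars.
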