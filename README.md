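# strigagp

Genomic prediction for *Striga hermonthica* resistance breeding in
tropical maize.

*Striga* (witchweed) is an obligate root parasite that devastates maize
across sub-Saharan Africa. Screening for resistance requires artificial
infestation of field plots — expensive and limited in capacity — so
breeding programmes want to phenotype a small **training set** of
doubled-haploid (DH) testcross hybrids and *predict* the genetic merit
of the much larger pool of unphenotyped lines from dominant
presence/absence markers (rAmpSeq tags). `strigagp` implements that
workflow end to end:

1. **Derived traits** from plot records: the area under the *Striga*
   number progress curve (trapezoid rule over emerged-parasite counts
   at 8/10/12 weeks after planting), the average 1–9 damage rating, and
   grain yield in t ha⁻¹ from plot ear weight (80 % shelling, adjusted
   to 12.5 % moisture).
2. **Trial mixed models** (EM-REML): single-site
   `y = μ + G + R + B(R) + ε` and across-site
   `y = μ + G + E + R(E) + B(ER) + GE + ε` for alpha-lattice designs,
   yielding BLUEs, BLUPs, variance components, and broad-sense
   heritability `H² = σ²G/(σ²G + σ²ε/R)` per site and
   `H² = σ²G/(σ²G + σ²GE/E + σ²ε/ER)` across sites.
3. **Marker QC and kinship**: minor-class frequency filtering of
   dominant 0/1 markers and the VanRaden-style genomic relationship
   matrix `G = SS'/p` from column-standardised markers.
4. **Reaction-norm G×E model** fitted by Gibbs sampling:
   `y = μ + Z_E β_E + Z_g g + u + e` with `g ~ N(0, σ²_g G)` and the
   interaction kernel `(Z_g G Z_g') ∘ (Z_E Z_E')` (Hadamard product),
   giving genomic estimated breeding values (GEBVs) for phenotyped and
   unphenotyped lines alike.
5. **Sparse-testing cross-validation**: CV0 (leave one environment
   out), CV1 (untested lines), CV2 (lines tested in some environments,
   predicted in the rest), with per-environment and pair-count-weighted
   across-environment Pearson accuracies.
6. A **synthetic trial generator** that reproduces the assumed data
   structure (marker panel, alpha-lattice layout, genetic / G×E /
   design / residual variance components) so the whole pipeline is
   testable without any field data.

## Worked example

Run the full pipeline on a synthetic 80-line trial (3 locations ×
2 replicates × 2 testers, 400 markers):

```python
from strigagp import PipelineConfig, run_pipeline

config = PipelineConfig(
    output_dir="demo",
    prediction_traits=("STR10WAP", "GY"),
    sampler=dict(iterations=4000, burn_in=2000, thin=10),
    cv=dict(schemes=("CV0", "CV2"), n_folds=5, test_fraction=0.2),
    simulation=dict(n_lines=80, n_markers=400, n_testers=2, block_size=8),
    seed=1,
)
outputs = run_pipeline(config)
```

`demo/variance_components.csv` then holds, per trait, the across-site
REML components and heritability — e.g. for the emerged-parasite count
at 10 WAP this run prints

```
trait,sigma2_G,sigma2_GE,sigma2_error,heritability
STR10WAP,67.73,14.05,267.56,0.579
```

meaning: genotypic variance 67.7, G×E variance 14.0, plot residual
267.6, so entry-mean heritability 0.58 — selection on testcross means
is worthwhile for this trait. `demo/accuracy.csv` reports the
cross-validated accuracies (Pearson r between observed and predicted
held-out cells), here

```
trait,scheme,across,...
STR10WAP,CV0,0.528,...
STR10WAP,CV2,0.486,...
```

i.e. lines already phenotyped elsewhere are predicted into a new
location with r ≈ 0.5. `demo/gebv.csv` lists every line's GEBV
(across-location and per-location), labelled TRN for phenotyped lines
and TST for lines predicted purely through the relationship matrix.

The same stages are available as CLI subcommands that compose to the
identical result:

```bash
strigagp simulate --seed 1 --n-lines 80 --n-markers 400 \
    --phenotypes pheno.csv --markers markers.csv
strigagp grm markers.csv --out grm.csv
strigagp blue pheno.csv STR10WAP --per-environment --out blues.csv
strigagp fit blues.csv grm.csv --iterations 4000 --burn-in 2000 --out gebv.csv
strigagp cv blues.csv grm.csv --scheme CV2 --n-folds 5 --iterations 4000 --burn-in 2000
```

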