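# Methods

## Model

For `N` phenotype records on `n_G` genotyped individuals in `n_E`
location-by-season environments the package fits

```
y = X b + Z u + r
```

with `u ~ N(0, G_AxE ⊗ G_A)` and `r ~ N(0, R)`. The random-effect vector is
laid out in environment-major blocks (all individuals of environment 1, then
environment 2, ...), so under that layout the Kronecker factors appear as
`G_AxE ⊗ G_A`; the same model written individual-major is `G_A ⊗ G_AxE` —
the ordering is purely a layout convention and the restricted likelihood is
identical as long as `Z` indexes cells consistently. The observed-data
covariance used everywhere is

```
V = Z (G_AxE ⊗ G_A) Zᵀ + R,
V[a, b] = G_AxE[env_a, env_b] · G_A[ind_a, ind_b] + R[a, b],
```

built directly from the record indices; no Kronecker product is ever
materialised during estimation.

**Fixed effects.** Intercept plus reference-coded environment means (the
first environment, in sorted (location, season) order, is the reference),
plus reference-coded planting-year levels applied only to records at the one
location where that factor is declared. Least-square environment means are
re-expanded cell means, averaging over planting-year levels at the location
where the factor applies; pairwise z-tests on those means at α = 0.05 feed a
compact-letter display computed on mean-sorted maximal runs of mutually
non-different environments.

**Environment covariance structures** (`metgblup.structures`):

| kind      | parameters                | G_AxE                                  |
|-----------|---------------------------|----------------------------------------|
| `uniform` | σ²_A                      | σ²_A · J (correlation 1 everywhere)    |
| `cs`      | σ²_A, σ²_AxE              | σ²_A · J + σ²_AxE · I                  |
| `fa1`     | λ₁..λ_nE, ψ₁..ψ_nE        | ΛΛᵀ + diag(Ψ)                          |

`uniform ⊂ cs ⊂ fa1` as models (an FA(1) with equal loadings and equal
specifics is exactly a compound-symmetry matrix), so fitted restricted
log-likelihoods must be non-decreasing in that order; this nesting is
asserted in the tests. FA identifiability at order 1 needs only a sign
convention: the first loading is made non-negative after convergence. The
average additive correlation among environments is reported from the
compound-symmetry fit as `r̄ = σ²_A / (σ²_A + σ²_AxE)`.

**Residual model.** Independent experimental units with a heterogeneous
residual variance per environment. An optional `resid_cov` mode adds one
season covariance per location for repeated observations of the same
experimental unit (|implied correlation| clamped below 1); it defaults to
off because the per-environment-variances model is the reported baseline and
the covariance is weakly identified in small trials.

## Estimation

Restricted maximum likelihood,

```
ℓ_R = −½ [ (N−p) ln 2π + ln|V| + ln|XᵀV⁻¹X| + yᵀPy ],
P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹,
```

maximised by average-information updates: score
`s_i = −½ [tr(P ∂V_i) − yᵀP ∂V_i P y]` and AI matrix
`AI_ij = ½ yᵀP ∂V_i P ∂V_j P y`. Safeguards, in order:

* **Active set** — a variance parameter at its lower bound with an
  outward-pointing score is pinned for that iteration (this is how a zero
  genetic variance is estimated *at* the boundary rather than near it).
* **Step halving** — up to 10 halvings of the AI step; candidate parameters
  are clamped to the feasible region before evaluation.
* **Gradient fallback** — if no halved AI step improves the likelihood, a
  scaled-gradient step (norm 0.1 × phenotypic variance) is tried with the
  same halving. This structure-agnostic fallback replaces a
  structure-specific EM update; on every fixture exercised it is entered
  rarely and convergence was never lost.
* A small ridge (1e−8 of the mean AI diagonal) regularises the AI solve.

Convergence requires |Δℓ_R| < `tol_logl` (default 1e−6) **and** a maximum
relative parameter change < `tol_par` (default 1e−4), within `max_iter`
(default 200) iterations; if no feasible direction improves ℓ_R the current
point is accepted as a (local) optimum. Non-convergence returns the last
iterate flagged, never an exception. Starting values: residual variances at
half the per-environment phenotypic variance, loadings at √(half variance),
specifics at 0.1 × variance — overridable via `fit(start=...)`.

The residual-variance lower bound is `1e−8 × var(y)` (keeps V positive
definite under noiseless synthetic data); genetic variances and specifics
are bounded at exactly 0.

## BLUE/BLUP solutions

`solve_mme` evaluates Henderson's mixed-model solution in its equivalent
variance form: `b̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y`, `û = G Zᵀ V⁻¹ (y − Xb̂)`,
`cov(b̂) = (XᵀV⁻¹X)⁻¹`, with prediction-error variances
`diag(G − G Zᵀ P Z G)` on request. This is algebraically the MME solution
but needs no inverse of `G`, which matters because the fitted `G` is
*routinely* singular here: the uniform structure is rank 1, FA specific
variances are often estimated at the zero boundary, and duplicate genotypes
make `G_A` itself singular. (The MME identity `G⁻¹û = ZᵀV⁻¹(y − Xb̂)` is
what the test suite verifies.) Breeding values are returned for every
(individual, environment) cell, observed or not — prediction into untested
environments is the point of the model.

## Relatedness and LD

* GRM: VanRaden method 1 on the complete imputed dosage matrix with
  observed allele frequencies (rows then sum to zero — asserted as an
  invariant). Near-singular GRMs are bent by ε·I (ε = 1e−6) only where an
  inverse-free route is impossible.
* Pedigree A: tabular method; unknown parents are unrelated and non-inbred;
  validated against a 10⁵-replicate gene-dropping Monte Carlo oracle.
* Individual-by-location GRM `C = M G_A Mᵀ` and its eigen-ordination;
  "fraction of variation explained" divides by the sum of positive
  eigenvalues by default (configurable to trace) since relationship matrices
  can carry small negative eigenvalues after bending.
* LD: squared Pearson correlation of dosage vectors (composite LD on
  unphased genotypes, the PLINK genotype-count convention), same-chromosome
  pairs, distance-ranked bins of 1000 pairs; kb→cM at a constant rate
  (default 465 kb/cM). The count-weighted mean of the bin means equals the
  global mean exactly — asserted as an invariant.
* Summary variances of relationship-matrix elements use the population
  convention (divide by the element count).

## Curation

Names are canonicalised by NFKD-decomposing diacritics to ASCII base
letters, lowercasing, mapping whitespace runs to single underscores and
deleting all other non-alphanumerics without inserting a separator (so
`Precoce d'Isigny → precoce_disigny`). Partial matching combines substring
containment with normalised Levenshtein distance ≤ 0.2, candidates ranked by
score. Multi-source SNP calls merge by unanimity: agreement is kept, a
single-source call fills a missing cell, any disagreement becomes missing
and is logged; the merge is order-insensitive. Locus filters: missing
fraction > 30% or minor allele frequency < 0.05 (on non-missing calls).
Duplicate DNA profiles: pairwise concordance ≥ 0.99 over ≥ 100 jointly
called loci, grouped transitively, one representative retained.

Missing genotypes are imputed by a single-pass flanking-marker conditional
scheme: the modal dosage among individuals sharing the nearest non-missing
left/right flanking dosages, falling back to a seeded Hardy–Weinberg draw at
the locus frequency. This is a deliberately simple, deterministic stand-in
for haplotype-HMM imputation and is a known fidelity gap: it ignores family
information and long-range haplotypes, so imputation accuracy is below what
an HMM would achieve; at the few-percent missingness the pipeline produces
after merging, the effect on the GRM is negligible.

## Synthetic studies

The generator's defaults reproduce the motivating study design: 550
individuals (250 founders + 60 families × 5 offspring), 1273 SNPs on 8
chromosomes of 30 Mb, four locations × two seasons (8 environments),
membership patterns that put most US material only in the US, most French
material at both French sites, and 5 individuals everywhere; per-environment
additive variances 26.5–111.3 and residual variances 8.1–20.0 (Julian
days²), giving true heritabilities 0.60–0.91; an FA(1) truth with
communalities 0.97 (Europe) and 0.82 (US), i.e. cross-environment additive
correlations 0.82–0.97; environment means 144–186 Julian days with the US
site ~36 days later; a two-level planting-year factor (0 / +2.5 days) at one
French site; and each (individual, location, season) record emitted with
probability 0.85.

Mechanics and the reasoning behind them:

* **Genotypes** — founder haplotypes from a first-order binary chain along
  each chromosome with latent adjacent-allele correlation `exp(−d/decay)`.
  The transition probabilities are clamped to [0, 1] for heterogeneous
  allele frequencies, which attenuates the realised correlation; the default
  decay length (400 kb) is therefore calibrated so the *realised* dosage ρ²
  averages ~0.37 within 100 kb and the binned decay crosses 0.2 near 200 kb.
* **Families** — gametes recombine the founders' true haplotypes with
  Haldane (no-interference) crossover probabilities at the configured
  kb/cM rate, preserving LD through meiosis; the pedigree is recorded.
* **True breeding values** — the marker-effect route: per-locus effect
  vectors across environments drawn with the target correlation structure,
  multiplied by centred dosages, then each environment column rescaled so
  the realised additive variance equals the target exactly. Chosen over
  drawing from `N(0, G_AxE ⊗ G_A)` so that breeding values are reproducible
  functions of the genotypes and realised covariances match the fitted
  model's assumptions; the exact-variance rescaling slightly deflates
  sampling noise in the realised variances (not in the correlations).
* **Phenotypes** — environment mean + planting-year effect + breeding value
  + a residual drawn per experimental unit and season; the truth record
  stores every component so phenotypes reconstruct exactly.

What the generator does **not** emulate: genotype-calling error, selection,
mutation, dominance/epistasis, spatial field trends, and the coalescent
fine structure of real LD. Passing tests therefore demonstrate that the
estimation machinery recovers truth under the model's own assumptions — not
that real cherry data meet those assumptions.

## Cross-validation

Adjusted phenotypes are `y − xᵀb̂` from the full-data FA fit (fixed effects
only, no shrinkage). Within-location CV assigns each location's individuals
to k = 5 sets (stratified by location only — deliberately not by family, so
close training–validation relatives can inflate accuracy exactly as they do
in practice), masks one set's records at that location, refits the FA model
on the remainder (warm-started from the full-data estimates; a fold that
fails to converge falls back to the full-data variance parameters with a
flag), and predicts the masked cells. PA is computed per
location-by-set-by-season and averaged over sets for the season-level
report; `PACC = PA/√h²` uses the full-data heritability of the target
environment (independent estimates being unavailable), and
`se = 1/√n_{G×LS}` uses the season-level validation count. Leave-location-out
CV drops a location entirely, refits, and correlates each dropped
individual's mean predicted breeding value across the preserved environments
with the dropped location's adjusted phenotypes per season. Folds with fewer
than 3 validation phenotypes in a season are flagged rather than reported.

## Numerical choices and degenerate inputs

* Likelihood-ratio tests use the naive chi-square degrees of freedom even
  when a null parameter lies on a boundary (the ½χ²₀+½χ²₁ mixture issue is
  noted, not implemented); a negative statistic beyond 1e−6 is clipped to 0
  with p = 1 and a convergence warning.
* An environment losing all its records in a CV training fold changes the
  fold's environment set; the refit then starts cold instead of
  warm-started.
* Zero-variance loci are skipped (and logged) in LD; monomorphic loci are
  rejected by the GRM and must be filtered first.
* All generators and analyses are pure functions of their inputs and a
  seed; repeated runs are byte-identical.

## Problem sizes

The default full-scale study (550 individuals, 1273 SNPs, ~1100 records)
fits all three structures in under 15 s and completes both CV schemes in
about 2 minutes on one CPU. The test suite runs on a down-scaled study (150
individuals, 300 SNPs) for unit-level checks, and uses 400 individuals ×
2000 SNPs × 5 seeds with a balanced two-locations-per-individual overlap for
parameter-recovery checks — the balanced overlap is used there because
environments with ~50 records (the smallest sites of the unbalanced default)
estimate their heritability with an upward boundary bias that reflects data
scarcity, not an estimation defect.

## Known limitations

* FA order is fixed at 1; unstructured or higher-order FA covariances are
  out of scope, as are non-additive kernels and Bayesian estimation.
* The flanking-marker imputation is a documented approximation to
  haplotype-based HMM imputation.
* Heritabilities of environments with few records are frequently estimated
  at the `h² = 1` boundary; interpret per-environment components from small
  trials with their sampling variability in mind.
* The LRT boundary issue above makes the reported p-values mildly
  conservative-to-liberal depending on the null.
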