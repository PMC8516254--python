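# Methods

## The model

For a panel of fully homozygous inbred lines, each line carries one founder
haplotype ID per *reference range* (a genomic interval bounded by gene
models). For gene *g* with expression vector **y** over *n* lines, three
nested models partition expression variance:

1. **y** = **1**μ + **Z**α + **e** — cis haplotype effects fixed
   (one-way ANOVA on the haplotype groups at the gene's range);
2. **y** = **1**μ + **u**_cis + **e**, with
   **u**_cis ~ N(0, **H**_cis σ²_cis);
3. **y** = **1**μ + **u**_cis + **u**_trans + **e**, adding
   **u**_trans ~ N(0, **H**_trans σ²_trans) to absorb genome-wide
   (trans) regulation, **e** ~ N(0, **I** σ²_e).

**Z** is the n × p 0/1 indicator of the p haplotypes observed at the
gene's range (columns in ascending haplotype ID). The relationship
matrices are trace-normalised: **H** = **ZZ**′ / (tr(**ZZ**′)/n), so
tr(**H**) = n; **H**_trans concatenates the indicators of *all* genic
ranges, including the focal gene's own range (the genome-wide kernel is
defined once for the panel; with hundreds of ranges the focal gene's
contribution is negligible, and a leave-one-out switch exists on
`build_trans_hrm` for sensitivity checks).

From a model-3 fit the shares are
h²_cis = σ²_cis/(σ²_cis+σ²_trans+σ²_e), analogously h²_trans, the
heritable proportion (σ²_cis+σ²_trans)/total, and the cis share of
heritable variance σ²_cis/(σ²_cis+σ²_trans).

## REML

Models 2 and 3 are fitted by restricted maximum likelihood with
**X** = **1** as the only fixed effect.

*Model 2* profiles the restricted likelihood over the ratio
γ = σ²_cis/σ²_e using the eigendecomposition of **H**_cis: in the rotated
basis the covariance is diagonal, μ and σ²_e have closed-form GLS/profile
solutions, and the scalar search over log γ runs a 101-point scan of
[−25, 25] followed by bounded Brent refinement. A ratio at the search
boundary is flagged (`ratio_at_bound`).

*Model 3* maximises the restricted log-likelihood over
(log σ²_cis, log σ²_trans, log σ²_e) with L-BFGS-B from three starts
(balanced split, scenario-shaped split, noise-dominated split), keeping the
best. When the cis term is supplied as a design matrix, each likelihood
evaluation inverts V = σ²_cis **H**_cis + σ²_trans **H**_trans + σ²_e **I**
through a low-rank Woodbury update around the eigendecomposition of
**H**_trans (computed once per panel and shared across genes): with
A = σ²_trans **D** + σ²_e **I** diagonal in the rotated basis and
σ²_a = σ²_cis/c, c = tr(**ZZ**′)/n,

    V⁻¹ = A⁻¹ − σ²_a A⁻¹ Z (I + σ²_a Z′A⁻¹Z)⁻¹ Z′A⁻¹,
    ln|V| = Σ ln a_i + ln|I + σ²_a Z′A⁻¹Z|.

This is exact and reduces a per-evaluation O(n³) Cholesky to O(np²) with
p ≤ the founder count, which is what makes per-gene fits over hundreds of
lines cheap. A dense Cholesky path handles arbitrary kernels and serves as
an internal cross-check. If the quasi-Newton search fails to converge, an
EM-style multiplicative fixed-point refinement on the dense representation
is attempted; the fit is flagged either way. Variances below 1e-10 (on the
internally y-standardised scale) are floored to exactly zero. Expression is
centred/scaled internally per gene and restored on output, so reported
components live on the data scale and shares are scale-invariant. Nearly
collinear cis and trans kernels (off-diagonal correlation > 0.999) trigger
an identifiability flag: the total genetic variance is then estimated but
its split is arbitrary.

## Haplotype effects and imputation

Model 1 effects are group means minus the unweighted grand mean (the
intercept is the unweighted grand mean; with unbalanced groups the effects
therefore do not sum to zero — documented, deliberate). Models 2/3 use the
haplotype-level BLUP

    â = σ²_a Z′ V⁻¹ (y − 1μ̂),   σ²_a = σ²_cis / c,

the unique vector with **u**_cis = **Z â** exactly (because
**H**_cis ∝ **ZZ**′). All effects shrink to zero as σ²_cis → 0, and in the
infinite-ratio limit on balanced designs they converge to the model-1 group
effects.

Per-gene effects are assembled over the full founder universe; haplotypes
unobserved in the training panel receive the gene's mean estimated effect
(mean imputation) and carry a `mean_imputed` provenance flag. Imputation
into a target panel is the deterministic lookup
μ̂_g + effect(g, haplotype(line, g)); lines with a missing assignment get
μ̂_g plus the mean estimated effect. Effects are stored relative to μ̂_g
and the intercept is re-added on imputation so imputed values live on the
expression scale, which is what makes the correlation comparisons with
measured expression meaningful.

## Prediction

Ridge regression on standardised features (training means/SDs; test panels
reuse training statistics), unpenalised intercept, closed-form solution via
the primal normal equations or the dual form when p > n (identical for
λ > 0). λ is selected by minimum mean squared error in k-fold
cross-validation (default 10) over a log-spaced grid spanning
[1e-4, 1e4] × ‖X′X‖₂/n, ties broken toward the larger λ; the whole grid is
evaluated from one SVD per fold. λ is re-selected inside every training
split so test data never influence the penalty. Accuracy is the Pearson
correlation of observed and predicted trait values.

Two protocols: *within-panel* (repeated 80/20 Monte Carlo splits, default
20 repeats, splits with a constant test trait excluded and logged) and
*cross-panel* (training on family-stratified subsets — default 10 lines per
family, 20 subsets, matching a 250-line training set for 25 families — with
lines present in both panels removed from the test set first). One master
seed expands deterministically into split, fold and subset seeds.

## Permutation baseline

"Random" effect matrices preserve haplotype structure: per gene,
independently across genes, the haplotype → effect map is shuffled
uniformly, so the multiset of effects per gene — and which lines share a
value after imputation — is unchanged while the labelling is destroyed.
The observed run and all k permuted runs (default k = 100) reuse the exact
same train/test partitions; significance is the Monte Carlo estimate
p = (r+1)/(k+1), with ties counting toward r (conservative), hence
p ≥ 1/(k+1).

## The simulator

The generators produce the study design the estimators assume:

* **NAM design**: 25 biparental RIL families of 200 fully inbred lines
  sharing one common parent. Ranges are ordered on a single linear genome;
  recombination is a symmetric two-state Markov chain with per-step switch
  probability `crossovers_per_range_set / (n_ranges − 1)` (default 30
  expected switches, approximating the selfing-expanded crossover count of
  a cereal RIL genome). The marginal parent probability is 1/2 at every
  range, so the idealised frequency spectrum at a range is 1/2 for the
  common parent and 1/50 per family parent — median haplotype count 100 and
  plug-in entropy −(0.5 ln 0.5 + 25·0.02 ln 0.02) = 2.3026 nats.
* **Diverse panel**: founder-haplotype block mosaics with geometric block
  lengths (default mean 20 ranges), all founders equally likely; a
  structural stand-in for a diversity panel sharing the founder haplotypes,
  not a population-genetic model of any particular panel.
* **Expression**: y = μ_g + Z_g a_g + w_t + e per gene and tissue, with
  per-haplotype cis effects shared across tissues, trans values built from
  random projections of the haplotype indicators at all non-focal genes
  (only the covariance structure of trans regulation matters to the
  estimators, so no explicit regulator genes are simulated), and iid noise.
  Baselines μ_g ~ N(8, 2), log-scale-expression-like. Scenario targets pin
  the variance shares — defaults cis_share = 1/3 of heritable variance and
  heritability 0.55, the regime of a typical maize expression panel — and
  each component is empirically standardised to its target, so realised
  shares match the targets exactly up to the small sample correlation
  between components. Cross-tissue correlation of the trans component is a
  dial (`trans_tissue_corr`); genes with fewer than two distinct haplotypes
  get zero cis variance and are flagged.
* **Traits**: weighted sums of the causal genes' cis genetic values plus
  Gaussian noise; `trait_noise` is the noise SD relative to the signal SD
  (absolute for a degenerate signal). All genetic trait signal flows
  through cis expression — the regime where true effects should beat the
  permutation baseline.

What the simulator does *not* emulate: real recombination maps and
chromosome structure, residual heterozygosity, selection, linkage between
cis and trans architecture, expression count noise, or tissue-specific cis
effects. Passing tests therefore demonstrate correctness of the estimators
and protocols under the generating model, not performance on any real
panel.

## Numerical choices and problem sizes

Tolerances: HRM trace normalisation asserted to 1e-9; BLUP projection
identity to 1e-8; ridge closed form vs iterative oracle to 1e-6;
share identities to 1e-12. The model-2 grid oracle comparison allows one
grid step (81 points over 8 decades). Degenerate inputs: an identity cis
kernel makes the model-2 split non-identifiable (total variance is still
recovered); all-zero designs and empty permutation sets are errors.

The packaged end-to-end checks run at desk scale: variance-component
recovery at n = 400 lines × 100 genes; transferability at 260 lines × 100
genes × 2 tissues; permutation calibration on a 100-line panel with 25
genes, 200 null traits, k = 100; cross-panel ordering over 20 replicates
of a 500-line simulated NAM (25 × 20) against a 120-line diverse panel
with 5 stratified 250-line training subsets and 3 permutations per
replicate; penalty-selection behaviour at n = 200 × p = 2000 (the
features ≫ lines regime of transcriptome-wide prediction). These sizes are
the package's own defaults for reproducible desk-scale validation;
estimates sharpen with n, genes and repeats.

## Known limitations

* Variance-component standard errors are not computed (point estimates and
  the restricted log-likelihood only).
* Only additive cis effects per haplotype: no dominance (moot for inbreds)
  and no epistasis across ranges.
* The LD pruning scan is greedy left-to-right per chromosome with a
  trailing physical window; other orderings retain different (equally
  valid) site sets.
* Missing haplotype assignments are dropped from per-gene fits, not
  imputed; imputation of effects happens only at the effect-matrix stage.
* The diverse-panel generator is a mosaic stand-in; its entropy and
  frequency spectra, not its LD structure, are the modelled features.
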