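# hare

**Cis haplotype associated RNA expression: variance partitioning, haplotype
effect imputation, and genomic prediction for inbred panels.**

In inbred crop panels genotyped against a shared set of founder haplotypes,
every line carries one founder haplotype ID per genic reference range. A
gene's measured expression mixes a *cis* component — attributable to the
haplotype at the gene's own range — with *trans* regulation from everywhere
else and with noise. The cis component is the transferable part: it travels
with the haplotype, across tissues and across panels that share founders.

`hare` estimates that component. Per gene it fits the mixed model

    y = 1·mu + u_cis + u_trans + e,
    u_cis  ~ N(0, H_cis  sigma2_cis),    H_cis  = Z Z' / (tr(Z Z')/n)
    u_trans~ N(0, H_trans sigma2_trans), H_trans from all genic ranges

by REML (fixed-effect and cis-only variants are also provided), reports the
variance shares h2_cis, h2_trans and the cis share of heritable variance
sigma2_cis/(sigma2_cis+sigma2_trans), and extracts one expression effect per
founder haplotype — the haplotype-level BLUP `a = sigma2_a Z' V^-1 (y-mu)`,
which satisfies `u_cis = Z a` exactly. Those effects can be imputed into any
panel sharing the founder haplotypes (`value = mu_g + effect of the line's
haplotype`), integrated across tissues, and used as features in ridge
genomic prediction. Significance of the prediction gain over haplotype
structure alone is assessed with a permutation baseline that shuffles the
haplotype→effect map per gene (preserving which lines share values) and the
Monte Carlo p-value (r+1)/(k+1).

A simulator generates panels with the assumed structure — nested biparental
RIL families with a common parent (NAM design), diverse founder-mosaic
panels, multi-tissue expression with controlled cis/trans shares, and traits
whose signal flows through cis expression — so the whole pipeline is
testable without external data.

Intended users: quantitative geneticists and breeders working with inbred
panels genotyped through a shared haplotype catalogue who want imputed,
transferable expression features instead of (or alongside) measured
transcriptomes and SNPs.

## Worked example

```python
import hare

founders = hare.FounderSet(n_founders=26, n_ranges=60)
panel = hare.simulate_diverse_panel(founders, n_lines=300, mosaic_block_mean=15.0, seed=11)
sim = hare.simulate_expression(panel, hare.SimScenario(n_genes=40, seed=12))
expr = sim.expression["tissue0"]

# 1. partition one gene's expression variance
g = expr.columns[0]
dm = hare.build_design_matrix(panel, g)
trans = hare.build_trans_hrm(panel)
print(hare.fit_model3(expr[g], dm, trans).summary())

# 2. estimate per-haplotype effects for all genes and impute them back
hm = hare.hare_from_panel(expr, panel, founders.haplotype_universe, model=3)
imp = hare.impute_expression(hm, panel)
r = hare.hare_vs_measured_correlation(imp.values, expr)
print(f"median r(imputed, measured) over {len(r)} genes: {r.median():.3f}")

# 3. predict a cis-driven trait and test the gain over haplotype structure
ph = hare.simulate_phenotype(sim.truth, n_causal_genes=10, trait_noise=0.5, seed=13)
out = hare.run_permutation_study(
    hm, panel, ph.values, hare.PermutationScheme(k=100, seed=14), n_repeats=5)
print(f"observed mean accuracy: {out.observed_mean:.3f}")
print(f"permuted mean accuracy: {out.permuted_means.mean():.3f}")
print(f"Monte Carlo p (high tail): {out.p_high:.4f}")
```

Output:

```
Variance components (model 3), n = 300
  mu               8.89084
  sigma2_cis      0.147147
  sigma2_trans    0.405174
  sigma2_e        0.448159
  loglik          -387.307   converged: True
  heritable     0.5521   cis share of heritable:   0.2664

median r(imputed, measured) over 40 genes: 0.527
observed mean accuracy: 0.786
permuted mean accuracy: 0.492
Monte Carlo p (high tail): 0.0099
```

Reading it: about 55% of this gene's expression variance is heritable and
about a quarter of that heritable variance is cis — close to the simulation
targets (0.55 and 1/3). Imputed effects correlate moderately (r ≈ 0.53)
with measured expression, as expected when cis explains only part of the
variance. For a trait driven by cis expression, imputed effects predict
clearly better (0.79) than the structure-preserving permutation baseline
(0.49), and no permutation reaches the observed accuracy
(p = 1/101 ≈ 0.0099).

The same workflow runs from the shell:

```sh
hare simulate --panel nam --out-dir sim/ --seed 1
hare entropy --haplotypes sim/haplotypes.tsv --out sim/entropy.tsv
hare fit --model 3 --expression expr.tsv --haplotypes sim/haplotypes.tsv --out fits.tsv
hare impute --hare hare.tsv --target-haplotypes target.tsv --out imputed.tsv
hare predict --train imputed.tsv --phenotypes pheno.tsv --trait trait --out acc.tsv
hare pipeline --out-dir run/ --seed 1      # end to end on simulated data
```

## Layout

- `hare.popsim` — panel / expression / trait simulators with truth ledgers
- `hare.haplo` — panel data model, design and relationship matrices, entropy
- `hare.varcomp` — the three per-gene models and REML machinery
- `hare.effects` — haplotype effect estimation, mean imputation, tissues
- `hare.predict` — ridge regression, CV penalty selection, protocols
- `hare.permtest` — permutation baseline and Monte Carlo p-values
- `hare.io`, `hare.pipeline`, `hare.cli` — formats, SNP pruning, end-to-end runs

See `docs/methods.md` for the model, algorithms and design decisions.
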