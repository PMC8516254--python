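"""Synthetic panels, expression and traits with the statistical structure of
a nested-association-mapping (NAM) study.

The generators produce:

* a **NAM-design panel**: biparental recombinant-inbred-line (RIL) families
  sharing one common parent, recombining along a single ordered sequence of
  reference ranges via a two-state Markov chain;
* a **diverse mosaic panel**: each line is a block mosaic of founder
  haplotypes with geometrically distributed block lengths (a structural
  stand-in for a diversity panel sharing the founders' haplotypes);
* **multi-tissue expression** per gene: ``y = mu_g + Z_g a_g + w_t + e``
  with per-haplotype cis effects ``a_g`` shared across tissues, a polygenic
  trans value ``w_t`` built from a random projection of the haplotype
  indicators at all other genes (cross-tissue correlation is a dial), and
  iid noise; realised variance shares are pinned to the scenario targets by
  empirical standardisation of each component;
* **traits** whose genetic signal flows entirely through the cis component
  of a set of causal genes.

Every generator records a "truth ledger" (effects, trans values, causal
genes) so downstream estimators can be validated against the generating
process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import InputError
from ._rng import rng_from, spawn_seeds
from .haplo import MISSING, HaplotypePanel, ReferenceRange, build_design_matrix


@dataclass(frozen=True)
class FounderSet:
    """The founder haplotype universe.

    Each founder carries one haplotype per range; at any range the founder
    IDs are distinct, so the per-range haplotype universe is simply
    ``{0, ..., n_founders-1}`` with ``common_parent`` designated (the B73
    role in a NAM design).
    """

    n_founders: int = 26
    n_ranges: int = 200
    common_parent: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1 or self.n_ranges < 1:
            raise InputError("n_founders and n_ranges must be positive")
        if not (0 <= self.common_parent < self.n_founders):
            raise InputError("common_parent must index a founder")

    @property
    def range_ids(self) -> list[str]:
        return [f"rr{k:04d}" for k in range(self.n_ranges)]

    def reference_ranges(self, range_bp: int = 10_000) -> list[ReferenceRange]:
        """Equally sized genic ranges laid on one linear chromosome."""
        return [
            ReferenceRange(rid, "chr1", k * range_bp, (k + 1) * range_bp, genic=True)
            for k, rid in enumerate(self.range_ids)
        ]

    @property
    def haplotype_universe(self) -> np.ndarray:
        return np.arange(self.n_founders)


@dataclass(frozen=True)
class SimScenario:
    """Targets for the expression generator.

    ``cis_share`` is the target sigma2_cis / (sigma2_cis + sigma2_trans),
    ``heritability`` the target (sigma2_cis + sigma2_trans) / total. The
    defaults pin cis_share = 1/3 and heritability = 0.55, the regime of a
    typical maize expression panel where trans regulators dominate the
    heritable variance and roughly half of expression variance is heritable.
    """

    n_genes: int = 100
    cis_share: float = 1.0 / 3.0
    heritability: float = 0.55
    n_tissues: int = 1
    trans_tissue_corr: float = 0.5
    trait_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cis_share <= 1.0):
            raise InputError("cis_share must be in [0, 1]")
        if not (0.0 <= self.heritability <= 1.0):
            raise InputError("heritability must be in [0, 1]")
        if not (-1.0 <= self.trans_tissue_corr <= 1.0):
            raise InputError("trans_tissue_corr must be in [-1, 1]")
        if self.trait_noise < 0:
            raise InputError("trait_noise must be >= 0")
        if self.n_genes < 1 or self.n_tissues < 1:
            raise InputError("n_genes and n_tissues must be positive")


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------

def simulate_nam_panel(
    founders: FounderSet,
    n_families: int = 25,
    rils_per_family: int = 200,
    crossovers_per_range_set: float = 30.0,
    seed: int = 0,
) -> HaplotypePanel:
    """Biparental RIL families sharing one common parent.

    Each RIL's haplotype at each range is either the common parent's or the
    family parent's, following a two-state Markov chain along the ordered
    ranges. The per-adjacent-range switch probability is
    ``crossovers_per_range_set / (n_ranges - 1)`` (capped at 0.5), i.e.
    ``crossovers_per_range_set`` is the expected number of parent switches
    along the whole range sequence; the default of 30 approximates the
    effective (selfing-expanded) crossover count of a cereal RIL genome.
    The chain is symmetric, so each parent has marginal probability 1/2 at
    every range; lines are fully inbred (one haplotype ID per range).
    """
    if n_families < 1 or rils_per_family < 1:
        raise InputError("n_families and rils_per_family must be positive")
    if n_families > founders.n_founders - 1:
        raise InputError(
            f"n_families ({n_families}) exceeds available non-common founders "
            f"({founders.n_founders - 1})"
        )
    if crossovers_per_range_set < 0:
        raise InputError("crossovers_per_range_set must be >= 0")
    m = founders.n_ranges
    switch = 0.0 if m == 1 else min(0.5, crossovers_per_range_set / (m - 1))
    rng = rng_from(seed)
    other_parents = [f for f in range(founders.n_founders) if f != founders.common_parent]
    blocks = []
    line_ids = []
    for fam_idx in range(n_families):
        parent = other_parents[fam_idx]
        # state False = common parent, True = family parent
        state = rng.random((rils_per_family, 1)) < 0.5
        flips = rng.random((rils_per_family, m - 1)) < switch
        states = np.concatenate([state, flips], axis=1)
        states = np.logical_xor.accumulate(states, axis=1)
        ids = np.where(states, parent, founders.common_parent)
        blocks.append(ids)
        line_ids += [f"F{fam_idx:02d}_R{r:03d}" for r in range(rils_per_family)]
    table = pd.DataFrame(
        np.concatenate(blocks, axis=0), index=line_ids, columns=founders.range_ids
    )
    return HaplotypePanel(table, founders.reference_ranges())


def simulate_diverse_panel(
    founders: FounderSet,
    n_lines: int = 260,
    mosaic_block_mean: float = 20.0,
    seed: int = 0,
) -> HaplotypePanel:
    """Diverse lines as founder-haplotype block mosaics.

    Along the ordered ranges a line keeps its current founder and, with
    probability ``1/mosaic_block_mean`` per step, redraws a founder uniformly
    (redraws may repeat the current founder, so realised blocks are slightly
    longer than the nominal geometric mean). All founders have equal marginal
    probability at every range. ``mosaic_block_mean = inf`` yields single
    founder clones.
    """
    if n_lines < 1:
        raise InputError("n_lines must be >= 1")
    if mosaic_block_mean < 1:
        raise InputError("mosaic_block_mean must be >= 1")
    m = founders.n_ranges
    q = 0.0 if np.isinf(mosaic_block_mean) else 1.0 / mosaic_block_mean
    rng = rng_from(seed)
    start = rng.integers(0, founders.n_founders, size=n_lines)
    ids = np.empty((n_lines, m), dtype=np.int64)
    ids[:, 0] = start
    for k in range(1, m):
        redraw = rng.random(n_lines) < q
        draws = rng.integers(0, founders.n_founders, size=n_lines)
        ids[:, k] = np.where(redraw, draws, ids[:, k - 1])
    table = pd.DataFrame(
        ids,
        index=[f"D{i:04d}" for i in range(n_lines)],
        columns=founders.range_ids,
    )
    return HaplotypePanel(table, founders.reference_ranges())


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class TrueEffects:
    """Ledger of the generating process, for oracle checks."""

    mu: pd.Series  # per gene intercept
    cis_effects: dict[str, pd.Series]  # gene -> haplotype ID -> effect
    cis_values: pd.DataFrame  # lines x genes, Z_g a_g (centred)
    trans_values: dict[str, pd.DataFrame]  # tissue -> lines x genes
    flagged_genes: list[str] = field(default_factory=list)  # < 2 haplotypes

    @property
    def genes(self) -> pd.Index:
        return self.cis_values.columns


@dataclass
class ExpressionSim:
    """Per-tissue expression matrices plus the truth ledger."""

    expression: dict[str, pd.DataFrame]  # tissue -> lines x genes
    truth: TrueEffects
    scenario: SimScenario

    @property
    def tissues(self) -> list[str]:
        return list(self.expression)


def _standardize(v: np.ndarray, target_sd: float) -> np.ndarray:
    """Centre and rescale to the exact target standard deviation
    (zero vector if the target is zero or the input is constant)."""
    v = v - v.mean()
    sd = v.std()
    if target_sd == 0.0 or sd == 0.0:
        return np.zeros_like(v)
    return v * (target_sd / sd)


def simulate_expression(panel: HaplotypePanel, scenario: SimScenario) -> ExpressionSim:
    """Generate ``y = mu_g + Z_g a_g + w_t + e`` per gene and tissue.

    Genes occupy the first ``scenario.n_genes`` ranges of the panel, one gene
    per genic range. Per-haplotype cis effects are shared across tissues; the
    trans value of each tissue combines a shared and a tissue-specific random
    projection of the haplotype indicators at all non-focal genes so that its
    cross-tissue correlation equals ``trans_tissue_corr``. Each variance
    component is empirically standardised to its scenario target, so realised
    shares match the targets up to the (small) sample correlation between
    components. Genes with fewer than 2 distinct haplotypes get zero cis
    variance and are flagged.
    """
    if panel.n_lines < 2:
        raise InputError("panel must contain at least 2 lines")
    if scenario.n_genes > panel.n_ranges:
        raise InputError(
            f"n_genes ({scenario.n_genes}) exceeds panel ranges ({panel.n_ranges})"
        )
    genes = list(panel.range_ids[: scenario.n_genes])
    n = panel.n_lines
    s2_cis = scenario.cis_share * scenario.heritability
    s2_trans = (1.0 - scenario.cis_share) * scenario.heritability
    s2_e = 1.0 - scenario.heritability
    rho = scenario.trans_tissue_corr
    tissues = [f"tissue{t}" for t in range(scenario.n_tissues)]

    seeds = spawn_seeds(scenario.seed, len(genes) + 1)
    mu_rng = rng_from(seeds[-1])
    mu = pd.Series(mu_rng.normal(8.0, 2.0, size=len(genes)), index=genes, name="mu")

    # genome-wide indicator matrix (all ranges), for trans projections
    all_designs = {rid: build_design_matrix(panel, rid) for rid in panel.range_ids}
    G_full = np.concatenate([all_designs[rid].Z for rid in panel.range_ids], axis=1)
    col_range = np.concatenate(
        [np.full(all_designs[rid].p, k) for k, rid in enumerate(panel.range_ids)]
    )

    cis_effects: dict[str, pd.Series] = {}
    cis_vals = np.zeros((n, len(genes)))
    trans_vals = {t: np.zeros((n, len(genes))) for t in tissues}
    expr = {t: np.zeros((n, len(genes))) for t in tissues}
    flagged: list[str] = []

    for j, g in enumerate(genes):
        rng = rng_from(seeds[j])
        dm = all_designs[g]
        a_raw = rng.normal(size=dm.p)
        v = dm.Z @ a_raw
        if dm.p < 2 or v.std() == 0.0 or s2_cis == 0.0:
            if dm.p < 2 and s2_cis > 0:
                flagged.append(g)
            a = np.zeros(dm.p)
            v = np.zeros(n)
        else:
            scale = np.sqrt(s2_cis) / v.std()
            a = a_raw * scale
            shift = (dm.Z @ a).mean()
            a = a - shift  # rows of Z sum to 1, so Za is centred exactly
            v = dm.Z @ a
        cis_effects[g] = pd.Series(a, index=dm.haplotypes)
        cis_vals[:, j] = v

        # trans: random projection of non-focal indicators
        mask = col_range != list(panel.range_ids).index(g)
        Gn = G_full[:, mask]
        sd_t = np.sqrt(s2_trans)
        w_shared = _standardize(Gn @ rng.normal(size=Gn.shape[1]), sd_t)
        # a negative correlation alternates the sign of the shared component
        sgn = -1.0 if rho < 0 else 1.0
        for t_idx, t in enumerate(tissues):
            w_spec = _standardize(Gn @ rng.normal(size=Gn.shape[1]), sd_t)
            if rho != 0:
                w_t = (
                    np.sqrt(abs(rho)) * (sgn**t_idx) * w_shared
                    + np.sqrt(1.0 - abs(rho)) * w_spec
                )
            else:
                w_t = w_spec
            w_t = _standardize(w_t, sd_t)
            e_t = _standardize(rng.normal(size=n), np.sqrt(s2_e))
            trans_vals[t][:, j] = w_t
            expr[t][:, j] = mu[g] + v + w_t + e_t

    lines = panel.line_ids
    truth = TrueEffects(
        mu=mu,
        cis_effects=cis_effects,
        cis_values=pd.DataFrame(cis_vals, index=lines, columns=genes),
        trans_values={
            t: pd.DataFrame(trans_vals[t], index=lines, columns=genes) for t in tissues
        },
        flagged_genes=flagged,
    )
    return ExpressionSim(
        expression={
            t: pd.DataFrame(expr[t], index=lines, columns=genes) for t in tissues
        },
        truth=truth,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSim:
    """A simulated trait plus its causal ledger."""

    values: pd.Series  # per line
    causal_genes: list[str]
    causal_weights: pd.Series  # per causal gene
    genetic_values: pd.Series  # per line, the noiseless signal
    noise_sd: float


def simulate_phenotype(
    truth: TrueEffects,
    n_causal_genes: int,
    trait_noise: float = 0.5,
    seed: int = 0,
) -> PhenotypeSim:
    """Trait = sum over causal genes of c_g * (Z_g a_g) + noise.

    Causal genes are drawn (without replacement) from genes with non-zero cis
    variance; weights ``c_g ~ N(0, 1)``. ``trait_noise`` is the noise standard
    deviation *relative to the signal's* (absolute when the signal is
    degenerate), so ``trait_noise = 0`` gives a fully cis-determined trait.
    """
    usable = [g for g in truth.genes if g not in truth.flagged_genes]
    if n_causal_genes > len(usable):
        raise InputError(
            f"n_causal_genes ({n_causal_genes}) exceeds usable genes ({len(usable)})"
        )
    if trait_noise < 0:
        raise InputError("trait_noise must be >= 0")
    rng = rng_from(seed)
    causal = sorted(rng.choice(usable, size=n_causal_genes, replace=False).tolist())
    weights = pd.Series(rng.normal(size=n_causal_genes), index=causal)
    if n_causal_genes > 0:
        signal = truth.cis_values[causal] @ weights
    else:
        signal = pd.Series(0.0, index=truth.cis_values.index)
    sig_sd = float(signal.std())
    noise_sd = trait_noise * sig_sd if sig_sd > 0 else trait_noise
    noise = rng.normal(0.0, 1.0, size=len(signal)) * noise_sd
    return PhenotypeSim(
        values=pd.Series(signal.to_numpy() + noise, index=signal.index, name="trait"),
        causal_genes=causal,
        causal_weights=weights,
        genetic_values=signal.rename("genetic_value"),
        noise_sd=noise_sd,
    )
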