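"""Haplotype-structure-preserving permutation baseline ("random HARE") and
Monte Carlo significance of the prediction gain.

Shuffling, per gene, the assignment of effect values to haplotype IDs keeps
the multiset of effects per gene — hence which lines receive identical
imputed values (the haplotype structure) — while destroying any functional
labelling. Running the identical prediction protocol on the observed matrix
and on ``k`` permuted matrices gives the Monte Carlo p-value

    p = (r + 1) / (k + 1)

with ``r`` the number of permutations whose mean accuracy is at least
(``high`` tail) or at most (``low`` tail) the observed mean; ties count
toward ``r``, so the smallest attainable p is ``1 / (k + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InputError
from ._rng import rng_from, spawn_seeds
from .effects import HareMatrix, impute_expression
from .haplo import HaplotypePanel
from .predict import PredictionResult, evaluate_cross_panel, evaluate_within_panel


@dataclass(frozen=True)
class PermutationScheme:
    """Number of per-gene haplotype-label permutations and their seed."""

    k: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError("k must be >= 1")


def permute_hare(hare: HareMatrix, seed: int = 0) -> HareMatrix:
    """Shuffle, independently per gene, the map haplotype -> effect.

    The multiset of effects per gene is preserved exactly; genes with a
    single haplotype in the universe are left unchanged (with a warning).
    """
    rng = rng_from(seed)
    eff = hare.effects.to_numpy().copy()
    prov = hare.provenance.to_numpy().copy()
    singles = []
    for i, g in enumerate(hare.genes):
        m = eff.shape[1]
        if m < 2:
            singles.append(g)
            continue
        perm = rng.permutation(m)
        eff[i] = eff[i, perm]
        prov[i] = prov[i, perm]
    if singles:
        warnings.warn(f"single-haplotype genes left unpermuted: {singles[:5]}", stacklevel=2)
    return HareMatrix(
        effects=pd.DataFrame(eff, index=hare.effects.index, columns=hare.effects.columns),
        mu=hare.mu.copy(),
        provenance=pd.DataFrame(
            prov, index=hare.provenance.index, columns=hare.provenance.columns
        ),
        model=hare.model,
        tissue=hare.tissue,
    )


def mc_pvalue(observed: float, permuted, tail: str = "high") -> float:
    """``(r + 1) / (k + 1)`` Monte Carlo p-value; ties count toward r."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise InputError("empty permutation set")
    if tail == "high":
        r = int((permuted >= observed).sum())
    elif tail == "low":
        r = int((permuted <= observed).sum())
    else:
        raise InputError(f"unknown tail: {tail}")
    return (r + 1) / (permuted.size + 1)


@dataclass
class PermutationOutcome:
    """Observed vs permuted mean accuracies and their Monte Carlo p-values."""

    observed: PredictionResult
    permuted_means: np.ndarray
    p_high: float
    p_low: float
    manifests_equal: bool = True
    permuted_results: list[PredictionResult] = field(default_factory=list)

    @property
    def observed_mean(self) -> float:
        return self.observed.mean_accuracy


def run_permutation_study(
    hare: HareMatrix,
    panel: HaplotypePanel,
    y,
    scheme: PermutationScheme = PermutationScheme(),
    protocol: str = "within",
    test_panel: HaplotypePanel | None = None,
    y_test=None,
    family_map=None,
    keep_permuted_results: bool = False,
    **predict_kwargs,
) -> PermutationOutcome:
    """Observed accuracy of the HARE features against ``k`` permuted runs.

    All runs — observed and every permutation — reuse the exact same
    train/test partitions (the evaluation seed is fixed before permuting),
    so the comparison isolates the labelling of effects to haplotypes.
    """
    seeds = spawn_seeds(scheme.seed, scheme.k + 1)
    eval_seed = seeds[0]

    def run(matrix: HareMatrix) -> PredictionResult:
        X = impute_expression(matrix, panel).values
        if protocol == "within":
            return evaluate_within_panel(X, y, seed=eval_seed, **predict_kwargs)
        if protocol == "cross":
            if test_panel is None or y_test is None:
                raise InputError("cross protocol needs test_panel and y_test")
            X_test = impute_expression(matrix, test_panel).values
            return evaluate_cross_panel(
                X, y, X_test, y_test, family_map=family_map, seed=eval_seed,
                **predict_kwargs,
            )
        raise InputError(f"unknown protocol: {protocol}")

    observed = run(hare)
    permuted_means = np.empty(scheme.k)
    permuted_results: list[PredictionResult] = []
    manifests_equal = True
    for i in range(scheme.k):
        res = run(permute_hare(hare, seed=seeds[i + 1]))
        permuted_means[i] = res.mean_accuracy
        if res.manifest.get("split_hash") != observed.manifest.get("split_hash"):
            manifests_equal = False
        if keep_permuted_results:
            permuted_results.append(res)
    return PermutationOutcome(
        observed=observed,
        permuted_means=permuted_means,
        p_high=mc_pvalue(observed.mean_accuracy, permuted_means, "high"),
        p_low=mc_pvalue(observed.mean_accuracy, permuted_means, "low"),
        manifests_equal=manifests_equal,
        permuted_results=permuted_results,
    )
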