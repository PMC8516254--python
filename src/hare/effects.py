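"""Haplotype-associated expression effects: estimation, imputation, tissue
integration and transferability.

A fitted per-gene model yields one expression effect per founder haplotype:
fixed-effect solutions for the fixed model, best linear unbiased predictions
(BLUPs) for the random models. Because the cis kernel is proportional to
``ZZ'``, the haplotype-level BLUP

    a_hat = s2_a Z' V^{-1} (y - 1 mu_hat),   s2_a = s2_cis / c,  c = tr(ZZ')/n

is the unique vector whose line-level projection satisfies
``u_cis = Z a_hat`` exactly.

The per-gene effects are assembled into a gene x haplotype matrix over the
founder universe; haplotypes unobserved in the training panel receive the
gene's mean estimated effect (mean imputation) and are flagged. Imputing
into a target panel is then a deterministic lookup:
``value(line, gene) = mu_g + effect(gene, haplotype(line, gene))``, which
places imputed values on the expression scale for comparison with measured
expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from ._errors import InputError
from .haplo import MISSING, HaplotypePanel, build_hrm, tissue_pairs
from .varcomp import VarCompResults

ESTIMATED = "estimated"
MEAN_IMPUTED = "mean_imputed"


@dataclass
class HareMatrix:
    """Gene x haplotype table of cis expression effects.

    ``effects`` columns span the haplotype universe (ascending integer IDs);
    cells for haplotypes never observed at a gene hold that gene's mean
    estimated effect and are flagged ``mean_imputed`` in ``provenance``.
    ``mu`` carries the per-gene intercept so imputed values can be restored
    to the expression scale.
    """

    effects: pd.DataFrame
    mu: pd.Series
    provenance: pd.DataFrame
    model: int
    tissue: str | None = None

    @property
    def genes(self) -> pd.Index:
        return self.effects.index

    @property
    def universe(self) -> np.ndarray:
        return self.effects.columns.to_numpy()


@dataclass
class ImputedExpression:
    """Line x gene matrix of imputed expression for a target panel."""

    values: pd.DataFrame
    tissue: str | None
    source: HareMatrix


def estimate_hare(fit: VarCompResults) -> pd.Series:
    """Per-haplotype expression effects from a fitted per-gene model.

    Model 1 returns the fixed-effect solutions. Models 2/3 return BLUPs
    computed through the marginal covariance at the fitted variances; all
    effects shrink to zero as ``sigma2_cis -> 0``.
    """
    if fit.model == 1:
        if fit.alpha is None:
            raise InputError("model-1 fit carries no fixed effects")
        return fit.alpha.rename("effect")
    mobj = fit.model_obj
    design = getattr(mobj, "design", None)
    if design is None:
        raise InputError(
            "haplotype effects for random models need the fitted design matrix"
        )
    Z = design.Z
    y = mobj.y.to_numpy()
    n = Z.shape[0]
    c = float(np.trace(Z @ Z.T)) / n
    s2c = fit.sigma2_cis
    s2a = s2c / c
    Hc = build_hrm(design).H
    V = s2c * Hc + fit.sigma2_e * np.eye(n)
    if fit.model == 3:
        V = V + fit.sigma2_trans * mobj.Ht
    r = y - fit.mu
    if s2a == 0.0:
        a = np.zeros(Z.shape[1])
    else:
        a = s2a * (Z.T @ linalg.solve(V, r, assume_a="pos"))
    return pd.Series(a, index=design.haplotypes, name="effect")


def build_hare_matrix(
    effects: Mapping[str, pd.Series],
    mu: Mapping[str, float],
    universe: Sequence[int],
    model: int = 3,
    tissue: str | None = None,
) -> HareMatrix:
    """Assemble per-gene effects into a gene x haplotype matrix.

    Haplotypes of ``universe`` with no estimate at a gene get the gene's mean
    estimated effect; genes with no estimates at all are excluded and logged
    via a warning.
    """
    universe = np.array(sorted(int(h) for h in universe))
    rows, prov, mus, genes = [], [], [], []
    skipped = []
    for g, eff in effects.items():
        eff = eff.dropna()
        if len(eff) == 0:
            skipped.append(g)
            continue
        unknown = [h for h in eff.index if h not in universe]
        if unknown:
            raise InputError(f"gene {g}: effects for haplotypes outside universe {unknown}")
        mean_eff = float(eff.mean())
        row = pd.Series(mean_eff, index=universe, dtype=float)
        row[eff.index] = eff.to_numpy(dtype=float)
        flag = pd.Series(MEAN_IMPUTED, index=universe, dtype=object)
        flag[eff.index] = ESTIMATED
        rows.append(row)
        prov.append(flag)
        mus.append(float(mu[g]))
        genes.append(g)
    if skipped:
        warnings.warn(f"genes without any estimated effect excluded: {skipped}", stacklevel=2)
    if not rows:
        raise InputError("no gene has estimated effects")
    return HareMatrix(
        effects=pd.DataFrame(rows, index=pd.Index(genes, name="gene")),
        mu=pd.Series(mus, index=pd.Index(genes, name="gene"), name="mu"),
        provenance=pd.DataFrame(prov, index=pd.Index(genes, name="gene")),
        model=model,
        tissue=tissue,
    )


def hare_from_panel(
    expression: pd.DataFrame,
    panel: HaplotypePanel,
    universe: Sequence[int],
    model: int = 3,
    tissue: str | None = None,
    genes: Sequence[str] | None = None,
) -> HareMatrix:
    """Fit the chosen model per gene on a training panel and assemble the
    HARE matrix in one step."""
    from .haplo import build_design_matrix, build_trans_hrm
    from .varcomp import fit_model1, fit_model2, fit_model3

    genes = list(genes) if genes is not None else list(expression.columns)
    expression = expression.loc[panel.line_ids]
    trans = trans_eig = None
    if model == 3:
        trans = build_trans_hrm(panel)
        d, U = linalg.eigh(trans.H)
        trans_eig = (np.clip(d, 0.0, None), U)
    effects: dict[str, pd.Series] = {}
    mus: dict[str, float] = {}
    for g in genes:
        dm = build_design_matrix(panel, g)
        y = expression[g]
        if model == 1:
            fit = fit_model1(y, dm)
        elif model == 2:
            fit = fit_model2(y, dm)
        else:
            fit = fit_model3(
                y, dm, trans,
                trans_eig=trans_eig if dm.missing_lines.size == 0 else None,
            )
        effects[g] = estimate_hare(fit)
        mus[g] = fit.mu
    return build_hare_matrix(effects, mus, universe, model=model, tissue=tissue)


def impute_expression(hare: HareMatrix, target: HaplotypePanel) -> ImputedExpression:
    """Deterministic lookup of HARE values for every line of a target panel.

    Lines with a missing assignment at a gene receive ``mu_g`` plus the
    gene's mean estimated effect. A haplotype ID outside the universe is an
    error listing the offending (line, range) pairs.
    """
    genes = [g for g in hare.genes if g in target.range_ids]
    absent = [g for g in hare.genes if g not in target.range_ids]
    if absent:
        raise InputError(f"target panel lacks ranges for genes: {absent[:5]}")
    universe = hare.universe
    eff = hare.effects.to_numpy()
    out = np.empty((target.n_lines, len(genes)))
    offending: list[tuple[str, str]] = []
    est_mask = (hare.provenance == ESTIMATED).to_numpy()
    for j, g in enumerate(genes):
        ids = target.assignments[g].to_numpy()
        present = ids != MISSING
        pos = np.searchsorted(universe, ids[present])
        bad = (pos >= len(universe)) | (universe[np.clip(pos, 0, len(universe) - 1)] != ids[present])
        if bad.any():
            for li in np.asarray(target.line_ids)[present][bad][:10]:
                offending.append((str(li), g))
            continue
        row = eff[hare.genes.get_loc(g)]
        mean_eff = float(row[est_mask[hare.genes.get_loc(g)]].mean())
        vals = np.full(len(ids), hare.mu[g] + mean_eff)
        vals[present] = hare.mu[g] + row[pos]
        out[:, j] = vals
    if offending:
        raise InputError(
            f"haplotype IDs outside the universe at (line, range): {offending}"
        )
    return ImputedExpression(
        values=pd.DataFrame(out, index=target.line_ids, columns=genes),
        tissue=hare.tissue,
        source=hare,
    )


def integrate_tissues(
    matrices: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    mode: str = "mean",
) -> pd.DataFrame:
    """Element-wise mean or max of per-tissue line x gene matrices."""
    mats = list(matrices.values()) if isinstance(matrices, Mapping) else list(matrices)
    if not mats:
        raise InputError("no matrices to integrate")
    ref = mats[0]
    for m in mats[1:]:
        if not (m.index.equals(ref.index) and m.columns.equals(ref.columns)):
            raise InputError("tissue matrices must share identical line and gene frames")
    stack = np.stack([m.to_numpy() for m in mats])
    if mode == "mean":
        out = stack.mean(axis=0)
    elif mode == "max":
        out = stack.max(axis=0)
    else:
        raise InputError(f"unknown integration mode: {mode}")
    return pd.DataFrame(out, index=ref.index, columns=ref.columns)


def _pearson_by_gene(A: pd.DataFrame, B: pd.DataFrame) -> pd.Series:
    genes = A.columns.intersection(B.columns)
    lines = A.index.intersection(B.index)
    if len(lines) < 3:
        raise InputError("need at least 3 shared lines for per-gene correlation")
    X = A.loc[lines, genes].to_numpy()
    Y = B.loc[lines, genes].to_numpy()
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * Yc).sum(axis=0) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan  # zero-variance genes: undefined
    return pd.Series(r, index=genes, name="r")


def cross_tissue_correlation(A: pd.DataFrame, B: pd.DataFrame) -> pd.Series:
    """Per-gene Pearson correlation across lines between two tissues'
    line x gene matrices (NaN where either gene has zero variance)."""
    return _pearson_by_gene(A, B)


def cross_tissue_summary(
    matrices: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Median per-gene correlation for every unordered tissue pair."""
    rows = []
    for t1, t2 in tissue_pairs(list(matrices)):
        r = cross_tissue_correlation(matrices[t1], matrices[t2])
        rows.append(
            {"tissue_a": t1, "tissue_b": t2,
             "median_r": float(r.median()), "n_genes": int(r.notna().sum())}
        )
    return pd.DataFrame(rows)


def hare_vs_measured_correlation(
    imputed: pd.DataFrame, measured: pd.DataFrame
) -> pd.Series:
    """Per-gene Pearson correlation between HARE-imputed and measured
    expression across shared lines."""
    return _pearson_by_gene(imputed, measured)
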