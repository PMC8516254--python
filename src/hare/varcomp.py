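"""Per-gene partitioning of expression variance into cis, trans and error.

Three models of a gene's expression ``y`` over inbred lines:

1. ``y = 1 mu + Z a + e`` — cis haplotype effects fixed (one-way ANOVA);
2. ``y = 1 mu + u_cis + e`` — cis effects random, ``u_cis ~ N(0, H_cis s2c)``;
3. ``y = 1 mu + u_cis + u_trans + e`` — additionally a genome-wide random
   effect ``u_trans ~ N(0, H_trans s2t)`` absorbing trans regulation.

Random models are fitted by restricted maximum likelihood (REML). Model 2
profiles the restricted likelihood over the variance ratio using the
eigendecomposition of ``H_cis``. Model 3 maximises over log-variances with
a bounded quasi-Newton search; when the cis kernel is supplied as a design
matrix the marginal covariance is inverted through a low-rank (Woodbury)
update of the eigendecomposition of ``H_trans``, which makes per-gene fits
cheap even for hundreds of lines. An EM-style fallback refines fits the
quasi-Newton search fails to converge.

The decomposition reported from model 3 follows the standard shares:
``h2_cis = s2c / (s2c + s2t + s2e)``, heritable proportion
``(s2c + s2t) / total`` and cis share of heritable variance
``s2c / (s2c + s2t)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from ._errors import InputError, NumericalError
from .haplo import DesignMatrix, RelationshipMatrix, build_hrm

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VarianceDecomposition:
    """Variance shares from a model-3 fit (``None`` when undefined)."""

    h2_cis: float | None
    h2_trans: float | None
    heritable_prop: float | None
    cis_share_of_heritable: float | None


@dataclass
class VarCompResults:
    """REML (or least-squares) solution for one gene.

    ``sigma2_cis``/``sigma2_trans`` are ``None`` for models that do not
    include the component. ``alpha`` carries the fixed haplotype effects for
    model 1. ``loglik`` is the restricted log-likelihood for models 2/3 and
    the residual log-likelihood for model 1.
    """

    model: int
    mu: float
    sigma2_cis: float | None
    sigma2_trans: float | None
    sigma2_e: float
    loglik: float
    converged: bool
    n_used: int
    alpha: pd.Series | None = None
    flags: tuple[str, ...] = ()
    model_obj: object | None = None

    def decompose(self) -> VarianceDecomposition:
        """Variance shares; requires a model-3 fit."""
        if self.model != 3:
            raise InputError("decompose requires a model-3 fit")
        s2c, s2t, s2e = self.sigma2_cis, self.sigma2_trans, self.sigma2_e
        total = s2c + s2t + s2e
        if total <= 0:
            return VarianceDecomposition(None, None, None, None)
        heritable = s2c + s2t
        return VarianceDecomposition(
            h2_cis=s2c / total,
            h2_trans=s2t / total,
            heritable_prop=heritable / total,
            cis_share_of_heritable=(s2c / heritable) if heritable > 0 else None,
        )

    def haplotype_effects(self) -> pd.Series:
        """Per-haplotype expression effects (model 1: fixed-effect solutions;
        models 2/3: BLUPs). See :func:`hare.effects.estimate_hare`."""
        from .effects import estimate_hare

        return estimate_hare(self)

    def summary(self) -> str:
        lines = [
            f"Variance components (model {self.model}), n = {self.n_used}",
            f"  mu          {self.mu:12.6g}",
        ]
        if self.sigma2_cis is not None:
            lines.append(f"  sigma2_cis  {self.sigma2_cis:12.6g}")
        if self.sigma2_trans is not None:
            lines.append(f"  sigma2_trans{self.sigma2_trans:12.6g}")
        lines.append(f"  sigma2_e    {self.sigma2_e:12.6g}")
        lines.append(f"  loglik      {self.loglik:12.6g}   converged: {self.converged}")
        if self.model == 3:
            d = self.decompose()
            if d.heritable_prop is not None:
                lines.append(
                    f"  heritable   {d.heritable_prop:8.4f}   "
                    f"cis share of heritable: "
                    + (
                        f"{d.cis_share_of_heritable:8.4f}"
                        if d.cis_share_of_heritable is not None
                        else "undefined"
                    )
                )
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def _as_series(y, line_ids=None) -> pd.Series:
    if isinstance(y, pd.Series):
        return y.astype(float)
    y = np.asarray(y, dtype=float).ravel()
    idx = line_ids if line_ids is not None else pd.RangeIndex(len(y))
    return pd.Series(y, index=idx)


# ---------------------------------------------------------------------------
# model 1: cis fixed effects
# ---------------------------------------------------------------------------

class CisFixedModel:
    """One-way fixed-effects model of expression on cis haplotypes."""

    def __init__(self, y, design: DesignMatrix) -> None:
        y = _as_series(y, design.line_ids)
        keep = design.Z.sum(axis=1) > 0
        self.design = DesignMatrix(
            design.Z[keep],
            design.haplotypes,
            design.line_ids[keep],
            design.range_id,
        )
        self.y = y.loc[self.design.line_ids]
        carriers = self.design.Z.sum(axis=0)
        if (carriers == 0).any():
            cols = carriers > 0
            self.design = DesignMatrix(
                self.design.Z[:, cols],
                self.design.haplotypes[cols],
                self.design.line_ids,
                self.design.range_id,
            )

    def fit(self) -> VarCompResults:
        Z, y = self.design.Z, self.y.to_numpy()
        n, p = Z.shape
        if n <= p:
            raise InputError(
                f"saturated design: {n} lines for {p} haplotypes at "
                f"{self.design.range_id}"
            )
        mu = float(y.mean())  # unweighted grand mean
        group_means = (Z.T @ y) / Z.sum(axis=0)
        alpha = group_means - mu
        fitted = mu + Z @ alpha
        resid = y - fitted
        ssr = float(resid @ resid)
        sigma2_e = ssr / (n - p)
        # Gaussian log-likelihood of the residuals at the MLE scale
        s2_ml = max(ssr / n, 1e-300)
        loglik = -0.5 * n * (LOG2PI + np.log(s2_ml) + 1.0)
        return VarCompResults(
            model=1,
            mu=mu,
            sigma2_cis=None,
            sigma2_trans=None,
            sigma2_e=sigma2_e,
            loglik=loglik,
            converged=True,
            n_used=n,
            alpha=pd.Series(alpha, index=self.design.haplotypes, name="alpha"),
            model_obj=self,
        )


# ---------------------------------------------------------------------------
# model 2: one random component + error
# ---------------------------------------------------------------------------

class CisRandomModel:
    """``y = 1 mu + u + e`` with ``u ~ N(0, H s2c)``, fitted by REML.

    Accepts either a :class:`DesignMatrix` (from which the trace-normalised
    HRM is built) or a ready :class:`RelationshipMatrix`.
    """

    def __init__(self, y, cis: DesignMatrix | RelationshipMatrix) -> None:
        if isinstance(cis, DesignMatrix):
            cis = cis.drop_missing()
            self.design: DesignMatrix | None = cis
            self.hrm = build_hrm(cis)
        else:
            self.design = None
            self.hrm = cis
        self.y = _as_series(y, self.hrm.line_ids).loc[self.hrm.line_ids]
        if len(self.y) < 3:
            raise InputError("model 2 needs at least 3 lines")

    def fit(self, ratio_bounds: tuple[float, float] = (-25.0, 25.0)) -> VarCompResults:
        H = self.hrm.H
        n = H.shape[0]
        try:
            d, U = linalg.eigh(H)
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise NumericalError(f"eigendecomposition of H failed: {exc}") from exc
        if d.min() < -1e-8 * max(1.0, d.max()):
            raise NumericalError("H_cis is not positive semidefinite")
        d = np.clip(d, 0.0, None)

        y = self.y.to_numpy()
        scale = y.std()
        scale = scale if scale > 0 else 1.0
        yt = U.T @ (y / scale)
        xt = U.T @ np.ones(n)

        def negloglik(lg: float) -> float:
            g = np.exp(lg)
            a = g * d + 1.0
            w = 1.0 / a
            xw = float(xt @ (w * xt))
            mu = float(xt @ (w * yt)) / xw
            r = yt - mu * xt
            q = float(r @ (w * r))
            s2e = q / (n - 1)
            if s2e <= 0:
                s2e = 1e-300
            return 0.5 * (
                (n - 1) * (LOG2PI + 1.0)
                + np.log(a).sum()
                + (n - 1) * np.log(s2e)
                + np.log(xw)
            )

        grid = np.linspace(ratio_bounds[0], ratio_bounds[1], 101)
        vals = np.array([negloglik(lg) for lg in grid])
        k = int(vals.argmin())
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            negloglik, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        lg_hat = float(res.x) if res.fun <= vals[k] else float(grid[k])
        converged = bool(res.success)
        at_bound = lg_hat <= ratio_bounds[0] + 1e-6 or lg_hat >= ratio_bounds[1] - 1e-6

        g = np.exp(lg_hat)
        a = g * d + 1.0
        w = 1.0 / a
        xw = float(xt @ (w * xt))
        mu = float(xt @ (w * yt)) / xw
        r = yt - mu * xt
        s2e = float(r @ (w * r)) / (n - 1)
        loglik = -negloglik(lg_hat)
        flags = ("ratio_at_bound",) if at_bound else ()
        return VarCompResults(
            model=2,
            mu=mu * scale,
            sigma2_cis=g * s2e * scale**2,
            sigma2_trans=None,
            sigma2_e=s2e * scale**2,
            loglik=loglik - (n - 1) * np.log(scale),
            converged=converged,
            n_used=n,
            flags=flags,
            model_obj=self,
        )


# ---------------------------------------------------------------------------
# model 3: cis + trans random components + error
# ---------------------------------------------------------------------------

class CisTransModel:
    """``y = 1 mu + u_cis + u_trans + e`` fitted by REML.

    ``cis`` may be a :class:`DesignMatrix` (enabling the fast low-rank path)
    or a dense :class:`RelationshipMatrix`; ``trans`` is the genome-wide HRM.
    A precomputed eigendecomposition of ``H_trans`` can be shared across
    genes via ``trans_eig=(eigenvalues, eigenvectors)``.
    """

    def __init__(
        self,
        y,
        cis: DesignMatrix | RelationshipMatrix,
        trans: RelationshipMatrix | np.ndarray,
        trans_eig: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        Ht = trans.H if isinstance(trans, RelationshipMatrix) else np.asarray(trans)
        if isinstance(cis, DesignMatrix):
            missing = cis.Z.sum(axis=1) == 0
            if missing.any():
                # H_trans rows must align positionally with the design rows
                keep = ~missing
                Ht = Ht[np.ix_(keep, keep)]
                trans_eig = None
                cis = cis.drop_missing()
            self.design: DesignMatrix | None = cis
            self.Hc = None
            line_ids = cis.line_ids
            self.c = float(np.trace(cis.Z @ cis.Z.T)) / cis.n
        else:
            self.design = None
            self.Hc = cis.H
            line_ids = cis.line_ids
            self.c = 1.0
        if Ht.shape[0] != len(line_ids):
            raise InputError("H_trans is not conformable with the cis term")
        self.Ht = Ht
        self.line_ids = line_ids
        self.y = _as_series(y, line_ids).loc[line_ids]
        self._trans_eig = trans_eig
        if len(self.y) < 3:
            raise InputError("model 3 needs at least 3 lines")

    # -- restricted log-likelihood ----------------------------------------
    def _prepare(self):
        if self._trans_eig is None:
            d, U = linalg.eigh(self.Ht)
            if d.min() < -1e-8 * max(1.0, d.max()):
                raise NumericalError("H_trans is not positive semidefinite")
            self._trans_eig = (np.clip(d, 0.0, None), U)
        return self._trans_eig

    def _negloglik_factory(self, y: np.ndarray):
        """Return f(theta) = -restricted loglik at theta = log variances."""
        n = len(y)
        ones = np.ones(n)
        if self.design is not None:
            d, U = self._prepare()
            Z = self.design.Z
            yt, xt, Zt = U.T @ y, U.T @ ones, U.T @ Z
            c = self.c
            p = Z.shape[1]

            def negloglik(theta: np.ndarray) -> float:
                s2c, s2t, s2e = np.exp(theta)
                s2a = s2c / c
                a = s2t * d + s2e
                if a.min() <= 0:
                    return np.inf
                Az = Zt / a[:, None]
                B = Zt.T @ Az
                M = np.eye(p) + s2a * B
                try:
                    cf = linalg.cho_factor(M, lower=True)
                except linalg.LinAlgError:
                    return np.inf
                logdetV = float(np.log(a).sum()) + 2.0 * float(
                    np.log(np.diag(cf[0])).sum()
                )

                def solve(v):
                    u = v / a
                    return u - s2a * (Az @ linalg.cho_solve(cf, Zt.T @ u))

                vy, v1 = solve(yt), solve(xt)
                xvx = float(xt @ v1)
                if xvx <= 0:
                    return np.inf
                mu = float(xt @ vy) / xvx
                q = float(yt @ vy) - mu * float(xt @ vy)
                return 0.5 * ((n - 1) * LOG2PI + logdetV + np.log(xvx) + q)

            return negloglik

        Hc, Ht = self.Hc, self.Ht

        def negloglik_dense(theta: np.ndarray) -> float:
            s2c, s2t, s2e = np.exp(theta)
            V = s2c * Hc + s2t * Ht + s2e * np.eye(n)
            try:
                cf = linalg.cho_factor(V, lower=True)
            except linalg.LinAlgError:
                return np.inf
            logdetV = 2.0 * float(np.log(np.diag(cf[0])).sum())
            vy = linalg.cho_solve(cf, y)
            v1 = linalg.cho_solve(cf, ones)
            xvx = float(ones @ v1)
            mu = float(ones @ vy) / xvx
            q = float(y @ vy) - mu * float(ones @ vy)
            return 0.5 * ((n - 1) * LOG2PI + logdetV + np.log(xvx) + q)

        return negloglik_dense

    def reml_loglik(self, sigma2_cis: float, sigma2_trans: float, sigma2_e: float) -> float:
        """Restricted log-likelihood at the given variance components."""
        y = self.y.to_numpy()
        f = self._negloglik_factory(y)
        return -f(np.log(np.clip([sigma2_cis, sigma2_trans, sigma2_e], 1e-300, None)))

    def _em_refine(self, y, theta, n_iter=50):
        """EM-style fixed-point refinement on the dense representation."""
        n = len(y)
        ones = np.ones(n)
        Hc = self.Hc if self.Hc is not None else build_hrm(self.design).H
        kernels = [Hc, self.Ht, np.eye(n)]
        s2 = np.exp(theta)
        for _ in range(n_iter):
            V = s2[0] * kernels[0] + s2[1] * kernels[1] + s2[2] * kernels[2]
            try:
                Vi = linalg.inv(V)
            except linalg.LinAlgError:
                break
            v1 = Vi @ ones
            P = Vi - np.outer(v1, v1) / float(ones @ v1)
            Py = P @ y
            new = np.empty(3)
            for i, K in enumerate(kernels):
                num = float(Py @ (K @ Py))
                den = float(np.sum(P * K))
                if den <= 0 or num <= 0:
                    new[i] = s2[i]
                else:
                    new[i] = s2[i] * num / den
            if np.allclose(new, s2, rtol=1e-8):
                s2 = new
                break
            s2 = np.clip(new, 1e-12, None)
        return np.log(s2)

    def fit(self, max_iter: int = 200) -> VarCompResults:
        y = self.y.to_numpy()
        scale = y.std()
        scale = scale if scale > 0 else 1.0
        ys = y / scale
        f = self._negloglik_factory(ys)

        # identifiability of the cis/trans split
        Hc = self.Hc if self.Hc is not None else build_hrm(self.design).H
        flags: list[str] = []
        off = ~np.eye(len(ys), dtype=bool)
        a, b = Hc[off], self.Ht[off]
        if a.std() > 0 and b.std() > 0:
            if abs(np.corrcoef(a, b)[0, 1]) > 0.999:
                flags.append("cis_trans_collinear")
                warnings.warn(
                    "H_cis and H_trans are nearly collinear; the cis/trans "
                    "split is not identifiable",
                    stacklevel=2,
                )

        starts = [
            np.log([1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0]),
            np.log([0.55 / 3.0, 0.55 * 2.0 / 3.0, 0.45]),
            np.log([0.05, 0.05, 0.9]),
        ]
        best = None
        n_fail = 0
        bounds = [(-30.0, 6.0)] * 3
        for s in starts:
            res = optimize.minimize(
                f, s, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
            )
            if not res.success:
                n_fail += 1
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success) and np.isfinite(best.fun)
        theta = best.x
        if not converged:
            theta_em = self._em_refine(ys, theta)
            if f(theta_em) < best.fun:
                theta = theta_em
                flags.append("em_refined")
            else:
                flags.append("not_converged")

        s2c, s2t, s2e = np.exp(theta)
        # floor variances that sit at the search boundary to exact zero
        floor = 1e-10
        s2c = 0.0 if s2c < floor else s2c
        s2t = 0.0 if s2t < floor else s2t
        loglik = -f(np.log(np.clip([s2c, s2t, s2e], 1e-300, None)))

        # GLS intercept at the optimum
        n = len(ys)
        V = s2c * Hc + s2t * self.Ht + s2e * np.eye(n)
        ones = np.ones(n)
        v1 = linalg.solve(V, ones, assume_a="pos")
        mu = float(v1 @ ys) / float(v1 @ ones)

        return VarCompResults(
            model=3,
            mu=mu * scale,
            sigma2_cis=s2c * scale**2,
            sigma2_trans=s2t * scale**2,
            sigma2_e=s2e * scale**2,
            loglik=loglik - (n - 1) * np.log(scale),
            converged=converged or "em_refined" in flags,
            n_used=n,
            flags=tuple(flags),
            model_obj=self,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_model1(y, design: DesignMatrix) -> VarCompResults:
    """Fixed-effects (one-way) fit; see :class:`CisFixedModel`."""
    return CisFixedModel(y, design).fit()


def fit_model2(y, cis: DesignMatrix | RelationshipMatrix) -> VarCompResults:
    """Single random cis component REML fit; see :class:`CisRandomModel`."""
    return CisRandomModel(y, cis).fit()


def fit_model3(
    y,
    cis: DesignMatrix | RelationshipMatrix,
    trans: RelationshipMatrix | np.ndarray,
    trans_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarCompResults:
    """cis + trans REML fit; see :class:`CisTransModel`."""
    return CisTransModel(y, cis, trans, trans_eig=trans_eig).fit()


def decompose(fit: VarCompResults) -> VarianceDecomposition:
    """Variance shares from a model-3 fit."""
    return fit.decompose()


def fit_panel(
    expression: pd.DataFrame,
    panel,
    model: int = 3,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit the chosen model for every gene of an expression matrix.

    ``expression`` is lines x genes with gene ids matching range ids of
    ``panel``. Returns a per-gene table of estimates, decomposition (model 3)
    and convergence flags. The trans HRM and its eigendecomposition are
    computed once and shared across genes.
    """
    from .haplo import build_design_matrix, build_trans_hrm

    genes = list(genes) if genes is not None else list(expression.columns)
    unknown = [g for g in genes if g not in panel.range_ids]
    if unknown:
        raise InputError(f"genes without a matching range: {unknown[:5]}")
    expression = expression.loc[panel.line_ids]
    trans = trans_eig = None
    if model == 3:
        trans = build_trans_hrm(panel)
        d, U = linalg.eigh(trans.H)
        trans_eig = (np.clip(d, 0.0, None), U)
    rows = []
    for g in genes:
        dm = build_design_matrix(panel, g)
        y = expression[g]
        try:
            if model == 1:
                res = fit_model1(y, dm)
            elif model == 2:
                res = fit_model2(y, dm)
            elif model == 3:
                if dm.missing_lines.size > 0:
                    res = fit_model3(y, dm, trans)  # subsets H_trans itself
                else:
                    res = fit_model3(y, dm, trans, trans_eig=trans_eig)
            else:
                raise InputError(f"unknown model: {model}")
        except (InputError, NumericalError) as exc:
            rows.append({"gene": g, "status": f"failed: {exc}"})
            continue
        row = {
            "gene": g,
            "status": "ok",
            "model": res.model,
            "mu": res.mu,
            "sigma2_cis": res.sigma2_cis,
            "sigma2_trans": res.sigma2_trans,
            "sigma2_e": res.sigma2_e,
            "loglik": res.loglik,
            "converged": res.converged,
            "n_used": res.n_used,
        }
        if model == 3:
            d3 = res.decompose()
            row.update(
                h2_cis=d3.h2_cis,
                h2_trans=d3.h2_trans,
                heritable_prop=d3.heritable_prop,
                cis_share_of_heritable=d3.cis_share_of_heritable,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
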