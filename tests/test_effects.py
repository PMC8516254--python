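"""Haplotype effect estimation, mean imputation, tissue integration."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from hare import (
    HaplotypePanel,
    InputError,
    VarCompResults,
    build_design_matrix,
    build_hare_matrix,
    build_hrm,
    build_trans_hrm,
    cross_tissue_correlation,
    cross_tissue_summary,
    estimate_hare,
    fit_model1,
    fit_model2,
    fit_model3,
    hare_from_panel,
    hare_vs_measured_correlation,
    impute_expression,
    integrate_tissues,
)
from hare.effects import ESTIMATED, MEAN_IMPUTED

from test_varcomp import make_design


class TestEstimateHare:
    def test_blup_projection_identity(self, diverse_panel, sim_two_tissue):
        # u_cis = Z a_hat, with u_cis recomputed through the H_cis route
        trans = build_trans_hrm(diverse_panel)
        for g in sim_two_tissue.truth.genes[:5]:
            y = sim_two_tissue.expression["tissue0"][g]
            dm = build_design_matrix(diverse_panel, g)
            fit = fit_model3(y, dm, trans)
            a = estimate_hare(fit).to_numpy()
            n = dm.n
            Hc = build_hrm(dm).H
            V = (
                fit.sigma2_cis * Hc
                + fit.sigma2_trans * trans.H
                + fit.sigma2_e * np.eye(n)
            )
            u = fit.sigma2_cis * Hc @ linalg.solve(V, y.to_numpy() - fit.mu)
            np.testing.assert_allclose(dm.Z @ a, u, atol=1e-8)

    def test_infinite_shrinkage_limit_matches_fixed_effects(self):
        # noise-free balanced data drive the REML ratio to the boundary,
        # where the BLUP approaches the group-mean fixed effects
        codes = np.repeat(np.arange(4), 10)
        effects = np.array([-3.0, -1.0, 1.0, 3.0])
        y = effects[codes] + 10.0
        dm = make_design(codes)
        r2 = fit_model2(y, dm)
        assert r2.sigma2_cis / max(r2.sigma2_e, 1e-300) >= 1e4
        a2 = estimate_hare(r2)
        a1 = fit_model1(y, dm).alpha
        np.testing.assert_allclose(a2.to_numpy(), a1.to_numpy(), atol=1e-3)

    def test_zero_cis_variance_full_shrinkage(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 5, size=40)
        dm = make_design(codes)
        y = pd.Series(rng.normal(size=40), index=dm.line_ids)
        from hare.varcomp import CisRandomModel

        m = CisRandomModel(y, dm)
        fit = VarCompResults(2, float(y.mean()), 0.0, None, 1.0, 0.0, True, 40,
                             model_obj=m)
        a = estimate_hare(fit)
        assert (a == 0).all()


class TestHareMatrix:
    def test_mean_imputation_of_unobserved_haplotype(self):
        hm = build_hare_matrix(
            {"g1": pd.Series({0: 1.0, 1: -1.0})}, {"g1": 5.0}, universe=[0, 1, 2]
        )
        assert hm.effects.at["g1", 2] == pytest.approx(0.0)
        assert hm.provenance.at["g1", 2] == MEAN_IMPUTED
        assert (hm.provenance.loc["g1", [0, 1]] == ESTIMATED).all()

    def test_universe_equals_observed_no_imputation(self):
        hm = build_hare_matrix(
            {"g1": pd.Series({0: 2.0, 1: 4.0})}, {"g1": 0.0}, universe=[0, 1]
        )
        assert (hm.provenance == ESTIMATED).to_numpy().all()

    def test_single_observed_haplotype_fills_all(self):
        hm = build_hare_matrix(
            {"g1": pd.Series({3: 1.5})}, {"g1": 0.0}, universe=[0, 1, 2, 3]
        )
        assert (hm.effects.loc["g1"] == 1.5).all()

    def test_imputed_cells_equal_mean_of_estimated(self, diverse_panel, sim_two_tissue):
        hm = hare_from_panel(
            sim_two_tissue.expression["tissue0"],
            diverse_panel,
            universe=range(30),  # larger than the founder set: forces imputation
            model=1,
        )
        est = hm.provenance == ESTIMATED
        for g in hm.genes:
            mean_est = hm.effects.loc[g][est.loc[g]].mean()
            imputed = hm.effects.loc[g][~est.loc[g]]
            if len(imputed):
                np.testing.assert_allclose(imputed, mean_est, atol=1e-12)

    def test_adding_unobserved_haplotype_preserves_estimates(self):
        eff = {"g1": pd.Series({0: 1.0, 1: 3.0})}
        a = build_hare_matrix(eff, {"g1": 0.0}, universe=[0, 1])
        b = build_hare_matrix(eff, {"g1": 0.0}, universe=[0, 1, 9])
        pd.testing.assert_series_equal(
            a.effects.loc["g1", [0, 1]], b.effects.loc["g1", [0, 1]]
        )

    def test_gene_without_estimates_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            hm = build_hare_matrix(
                {"g1": pd.Series({0: 1.0}), "g2": pd.Series(dtype=float)},
                {"g1": 0.0, "g2": 0.0},
                universe=[0],
            )
        assert list(hm.genes) == ["g1"]


class TestImputeExpression:
    def test_shared_haplotype_identical_values(self):
        hm = build_hare_matrix(
            {"rr0": pd.Series({0: 1.0, 1: -1.0})}, {"rr0": 2.0}, universe=[0, 1]
        )
        panel = HaplotypePanel(
            pd.DataFrame({"rr0": [0, 0, 1]}, index=["a", "b", "c"])
        )
        imp = impute_expression(hm, panel).values
        assert imp.at["a", "rr0"] == imp.at["b", "rr0"] == pytest.approx(3.0)
        assert imp.at["c", "rr0"] == pytest.approx(1.0)

    def test_round_trip_reproduces_noise_free_expression(self, founders):
        from hare import SimScenario, simulate_diverse_panel, simulate_expression

        panel = simulate_diverse_panel(founders, 100, 8.0, seed=13)
        sim = simulate_expression(
            panel, SimScenario(n_genes=8, cis_share=1.0, heritability=1.0, seed=14)
        )
        expr = sim.expression["tissue0"]
        hm = hare_from_panel(expr, panel, founders.haplotype_universe, model=1)
        imp = impute_expression(hm, panel).values
        np.testing.assert_allclose(imp.to_numpy(), expr[imp.columns].to_numpy(), atol=1e-10)

    def test_duplicate_line_gets_training_line_vector(self, diverse_panel, sim_two_tissue):
        hm = hare_from_panel(
            sim_two_tissue.expression["tissue0"].iloc[:, :5],
            diverse_panel,
            universe=range(26),
            model=1,
        )
        twin = HaplotypePanel(
            diverse_panel.assignments.iloc[[0]].rename(index={"D0000": "twin"}),
        )
        imp_train = impute_expression(hm, diverse_panel).values
        imp_twin = impute_expression(hm, twin).values
        np.testing.assert_allclose(imp_twin.loc["twin"], imp_train.iloc[0], atol=1e-12)

    def test_deterministic_and_order_equivariant(self, diverse_panel, sim_two_tissue):
        hm = hare_from_panel(
            sim_two_tissue.expression["tissue0"].iloc[:, :4],
            diverse_panel,
            universe=range(26),
            model=1,
        )
        a = impute_expression(hm, diverse_panel).values
        b = impute_expression(hm, diverse_panel).values
        pd.testing.assert_frame_equal(a, b)
        rev = diverse_panel.subset_lines(diverse_panel.line_ids[::-1])
        c = impute_expression(hm, rev).values
        pd.testing.assert_frame_equal(c, a.iloc[::-1])

    def test_unknown_haplotype_errors_with_location(self):
        hm = build_hare_matrix(
            {"rr0": pd.Series({0: 1.0})}, {"rr0": 0.0}, universe=[0]
        )
        panel = HaplotypePanel(pd.DataFrame({"rr0": [0, 99]}, index=["a", "b"]))
        with pytest.raises(InputError, match="b.*rr0"):
            impute_expression(hm, panel)

    def test_missing_assignment_gets_mean_effect(self):
        from hare import MISSING

        hm = build_hare_matrix(
            {"rr0": pd.Series({0: 2.0, 1: 4.0})}, {"rr0": 1.0}, universe=[0, 1]
        )
        panel = HaplotypePanel(pd.DataFrame({"rr0": [0, MISSING]}, index=["a", "b"]))
        imp = impute_expression(hm, panel).values
        assert imp.at["b", "rr0"] == pytest.approx(1.0 + 3.0)


class TestIntegrateTissues:
    def test_single_tissue_identity(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["g1", "g2"])
        pd.testing.assert_frame_equal(integrate_tissues([m], "mean"), m)
        pd.testing.assert_frame_equal(integrate_tissues([m], "max"), m)

    def test_mean_and_max_of_two(self):
        a = pd.DataFrame([[1.0]], index=["l"], columns=["g"])
        b = pd.DataFrame([[3.0]], index=["l"], columns=["g"])
        assert integrate_tissues([a, b], "mean").iat[0, 0] == 2.0
        assert integrate_tissues([a, b], "max").iat[0, 0] == 3.0

    def test_mean_never_exceeds_max(self, sim_two_tissue):
        mats = list(sim_two_tissue.expression.values())
        mean = integrate_tissues(mats, "mean")
        mx = integrate_tissues(mats, "max")
        assert (mean.to_numpy() <= mx.to_numpy() + 1e-12).all()

    def test_frame_mismatch_errors(self):
        a = pd.DataFrame([[1.0]], index=["l"], columns=["g"])
        b = pd.DataFrame([[1.0]], index=["x"], columns=["g"])
        with pytest.raises(InputError):
            integrate_tissues([a, b], "mean")


class TestCorrelations:
    def test_self_correlation_is_one(self, sim_two_tissue):
        A = sim_two_tissue.expression["tissue0"]
        r = cross_tissue_correlation(A, A)
        np.testing.assert_allclose(r.to_numpy(), 1.0, atol=1e-12)

    def test_zero_variance_gene_reported_missing(self):
        A = pd.DataFrame({"g": [1.0, 1.0, 1.0]}, index=list("abc"))
        B = pd.DataFrame({"g": [1.0, 2.0, 3.0]}, index=list("abc"))
        assert cross_tissue_correlation(A, B).isna().all()

    def test_summary_enumerates_all_pairs(self):
        mats = {
            f"t{i}": pd.DataFrame(
                np.random.default_rng(i).normal(size=(5, 3)),
                index=list("abcde"),
                columns=["g1", "g2", "g3"],
            )
            for i in range(7)
        }
        summary = cross_tissue_summary(mats)
        assert len(summary) == 21

    def test_hare_more_transferable_than_measured(self, diverse_panel, sim_two_tissue):
        # shared cis, independent trans: imputed effects carry only cis,
        # so their cross-tissue correlation must beat measured expression
        hms = {
            t: hare_from_panel(
                sim_two_tissue.expression[t], diverse_panel, range(26), model=1, tissue=t
            )
            for t in sim_two_tissue.tissues
        }
        imputed = {
            t: impute_expression(hms[t], diverse_panel).values for t in hms
        }
        r_hare = cross_tissue_correlation(imputed["tissue0"], imputed["tissue1"])
        r_meas = cross_tissue_correlation(
            sim_two_tissue.expression["tissue0"], sim_two_tissue.expression["tissue1"]
        )
        assert r_hare.median() > r_meas.median()

    def test_hare_vs_measured_in_plausible_band(self, diverse_panel, sim_two_tissue):
        hm = hare_from_panel(
            sim_two_tissue.expression["tissue0"], diverse_panel, range(26), model=1
        )
        imp = impute_expression(hm, diverse_panel).values
        r = hare_vs_measured_correlation(imp, sim_two_tissue.expression["tissue0"])
        assert 0.3 < r.median() < 0.7
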