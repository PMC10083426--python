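"""REML estimation: closed-form ratios, oracle checks, recovery, invariances."""

import numpy as np
import pandas as pd
import pytest

from safgp import qc, reml, sim
from conftest import make_panel


class TestHeritability:
    @pytest.mark.parametrize(
        "sA,se,expect",
        [(9.621, 3.594, 0.728), (0.0, 1.0, 0.0), (1.0, 1.0, 0.5)],
    )
    def test_values(self, sA, se, expect):
        assert reml.heritability(sA, se) == pytest.approx(expect, abs=5e-4)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            reml.heritability(0.0, 0.0)


class TestCorrelation:
    @pytest.mark.parametrize(
        "cov,vx,vy,expect",
        [(0.0, 4, 9, 0.0), (3.0, 4, 9, 0.5), (6.5, 4, 9, 0.999)],
    )
    def test_values(self, cov, vx, vy, expect):
        assert reml.correlation_from_cov(cov, vx, vy) == pytest.approx(expect)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            reml.correlation_from_cov(1.0, 0.0, 1.0)


def _uv_blues(y, ids):
    return pd.DataFrame({"accession": ids, "estimate": y})


class TestUnivariate:
    def test_constant_phenotype_floors(self):
        G = qc.GRM([f"L{i}" for i in range(12)], np.eye(12))
        comps, gebv = reml.fit_univariate(_uv_blues(np.full(12, 3.0), G.line_ids), G)
        assert comps.sigma2_A <= 1e-6
        assert np.all(np.abs(gebv["gebv"]) < 1e-8)

    def test_matches_grid_oracle_small(self):
        # brute-force profile of the variance ratio on a dense grid, n = 20
        rng = np.random.default_rng(42)
        A = rng.standard_normal((20, 40))
        G = qc.condition_grm(qc.GRM([f"L{i}" for i in range(20)],
                                    (A @ A.T) / 40))
        L = np.linalg.cholesky(G.values)
        y = L @ rng.standard_normal(20) + rng.standard_normal(20)
        comps, _ = reml.fit_univariate(_uv_blues(y, G.line_ids), G)

        X = np.ones((20, 1))

        def dense_ll(lam):
            # profile out sigma2_e at fixed ratio lam = sA2/se2
            V0 = lam * G.values + np.eye(20)
            Lc = np.linalg.cholesky(V0)
            Xs = np.linalg.solve(Lc, X)
            ys = np.linalg.solve(Lc, y)
            xtx = float(Xs[:, 0] @ Xs[:, 0])
            beta = float(Xs[:, 0] @ ys) / xtx
            r = ys - Xs[:, 0] * beta
            se2 = float(r @ r) / 19
            return -0.5 * (
                20 * np.log(se2) + 2 * np.log(np.diag(Lc)).sum()
                + np.log(xtx) - np.log(se2) + 19
            )

        grid = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 200))
        best = max(dense_ll(lam) for lam in grid)
        assert comps.log_likelihood >= best - 1e-4
        assert comps.log_likelihood <= best + 1.0  # same criterion scale

    def test_h2_recovery_mean_over_seeds(self):
        h2s = []
        for seed in range(20):
            _, geno, eff, means, grm = make_panel(
                seed, 300, 2000, ("y",), [[4.0]], [[4.0]]
            )
            sub = means.rename(columns={"y": "estimate"})
            comps, _ = reml.fit_univariate(sub[["accession", "estimate"]], grm)
            h2s.append(comps.h2)
        assert abs(np.mean(h2s) - 0.5) < 0.1

    def test_scale_invariance(self):
        _, geno, eff, means, grm = make_panel(7, 150, 600, ("y",), [[2.0]], [[2.0]])
        sub = means.rename(columns={"y": "estimate"})[["accession", "estimate"]]
        c1, _ = reml.fit_univariate(sub, grm)
        c2, _ = reml.fit_univariate(sub.assign(estimate=sub["estimate"] * 10), grm)
        assert c2.sigma2_A == pytest.approx(100 * c1.sigma2_A, rel=1e-4)
        assert c2.h2 == pytest.approx(c1.h2, abs=1e-6)

    def test_gebv_shrinkage_and_centering(self):
        _, geno, eff, means, grm = make_panel(3, 150, 600, ("y",), [[2.0]], [[2.0]])
        sub = means.rename(columns={"y": "estimate"})
        comps, gebv = reml.fit_univariate(sub[["accession", "estimate"]], grm)
        u = gebv["gebv"].to_numpy()
        assert abs(u.mean()) < 1e-6 * max(u.std(), 1e-12)
        assert u.var(ddof=1) <= comps.sigma2_A * np.diag(grm.values).max() + 1e-9


@pytest.fixture(scope="module")
def biv(bivariate_panel):
    params, geno, eff, means, grm = bivariate_panel
    long = means.melt(id_vars=["site", "accession"], var_name="trait",
                      value_name="estimate")
    return params, means, long, grm


class TestMultitrait:
    def test_duplicated_trait_hits_correlation_boundary(self, biv):
        _, means, _, grm = biv
        dup = means.assign(t2=means["t1"])
        long = dup.melt(id_vars=["site", "accession"], var_name="trait",
                        value_name="estimate")
        comps, _, corrs = reml.fit_multitrait(long, grm, traits=["t1", "t2"])
        assert corrs[0].r_A >= 0.99

    def test_independent_traits_near_zero_correlation(self):
        ras = []
        for seed in (1, 2, 3):
            _, _, _, means, grm = make_panel(
                seed, 300, 2000, ("a", "b"), np.diag([3.0, 7.0]), np.diag([7.0, 3.0])
            )
            long = means.melt(id_vars=["site", "accession"], var_name="trait",
                              value_name="estimate")
            _, _, corrs = reml.fit_multitrait(long, grm, traits=["a", "b"])
            ras.append(corrs[0].r_A)
        assert abs(np.mean(ras)) < 0.15

    def test_canonical_and_dense_routes_agree(self, biv):
        _, means, long, grm = biv
        comps, _, _ = reml.fit_multitrait(long, grm, traits=["t1", "t2"])
        # dense engine on identical (complete) records
        wide = means.set_index("accession")[["t1", "t2"]]
        ids = list(wide.index)
        sub = grm.subset(ids)
        rec_unit = np.repeat(np.arange(len(ids)), 2)
        rec_trait = np.tile([0, 1], len(ids))
        y = wide.to_numpy().reshape(-1)
        X = np.zeros((len(y), 2))
        X[np.arange(len(y)), rec_trait] = 1.0
        term = reml.VarTerm("additive", sub.values, rec_unit, "full")
        fit = reml.dense_reml(y, X, rec_trait, rec_unit, [term], 2)
        assert fit.log_likelihood == pytest.approx(comps.log_likelihood, abs=1e-3)
        np.testing.assert_allclose(term.theta, comps.T, atol=0.05)

    def test_likelihood_monotone_across_iterations(self, biv):
        _, _, long, grm = biv
        comps, _, _ = reml.fit_multitrait(long, grm, traits=["t1", "t2"],
                                          track_ll=True)
        path = np.array(comps.ll_path)
        assert np.all(np.diff(path) >= -1e-9)

    def test_diagonal_constraint_reproduces_univariate(self, biv):
        _, means, long, grm = biv
        comps, _, _ = reml.fit_multitrait(long, grm, traits=["t1", "t2"],
                                          diagonal=True)
        for j, tr in enumerate(["t1", "t2"]):
            sub = means.rename(columns={tr: "estimate"})[["accession", "estimate"]]
            uv, _ = reml.fit_univariate(sub, grm)
            assert comps.T[j, j] == pytest.approx(uv.sigma2_A, abs=1e-4 * (1 + uv.sigma2_A))
            assert comps.Rres[j, j] == pytest.approx(uv.sigma2_e, abs=1e-4 * (1 + uv.sigma2_e))

    def test_scale_invariance_multitrait(self, biv):
        _, _, long, grm = biv
        c1, _, corr1 = reml.fit_multitrait(long, grm, traits=["t1", "t2"])
        scaled = long.assign(estimate=long["estimate"] * 3.0)
        c2, _, corr2 = reml.fit_multitrait(scaled, grm, traits=["t1", "t2"])
        np.testing.assert_allclose(c2.T, 9.0 * c1.T, rtol=1e-3, atol=1e-5)
        assert corr2[0].r_A == pytest.approx(corr1[0].r_A, abs=1e-3)

    def test_rowcol_plot_level_fit_runs(self):
        p = sim.SimParams(n_lines=40, n_markers=200, seed=6, traits=("a", "b"),
                          T_target=np.diag([2.0, 2.0]), R_target=np.diag([1.0, 1.0]),
                          sigma2_row=0.3, sigma2_col=0.3, n_reps=2,
                          layout_rows=8, layout_cols=10)
        g = sim.simulate_genotypes(p)
        eff = sim.simulate_true_effects(g, p)
        trial = sim.simulate_trial(g, eff, p)
        grm = qc.condition_grm(qc.vanraden_grm(qc.impute_missing(g)))
        comps, gebv, _ = reml.fit_multitrait(
            None, grm, traits=["a", "b"], include_rowcol=True, plots=trial
        )
        assert comps.sigma2_row is not None and (comps.sigma2_row >= 0).all()
        assert set(gebv["trait"]) == {"a", "b"}


class TestGxE:
    def test_duplicated_site_floors_interaction(self):
        _, _, _, means, grm = make_panel(5, 120, 500, ("y",), [[1.0]], [[1.0]])
        one = means[means["site"] == "S1"]
        both = pd.concat([one, one.assign(site="S2")], ignore_index=True)
        long = both.melt(id_vars=["site", "accession"], var_name="trait",
                         value_name="estimate")
        comps, _ = reml.fit_gxe(long, grm, trait="y")
        assert comps["sigma2_gxe"] < 1e-4

    def test_single_site_rejected(self):
        _, _, _, means, grm = make_panel(5, 120, 500, ("y",), [[1.0]], [[1.0]])
        long = means.melt(id_vars=["site", "accession"], var_name="trait",
                          value_name="estimate")
        with pytest.raises(ValueError, match="fit_univariate"):
            reml.fit_gxe(long, grm, trait="y")

    def test_single_site_nested_model_equals_univariate(self):
        # the engine restricted to one site with no interaction term matches
        # the eigen-path univariate likelihood exactly (interior optimum;
        # at a zero-variance boundary the two routes regularize differently)
        _, _, _, means, grm = make_panel(0, 100, 400, ("y",), [[1.5]], [[1.0]])
        df = means[means["site"] == "S1"].reset_index(drop=True)
        sub = grm.subset(sorted(df["accession"].unique()))
        pos = {a: i for i, a in enumerate(sub.line_ids)}
        acc = df["accession"].map(pos).to_numpy()
        term = reml.VarTerm("additive", sub.values, acc, "full")
        n = len(df)
        fit = reml.dense_reml(df["y"].to_numpy(), np.ones((n, 1)),
                              np.zeros(n, int), np.arange(n), [term], 1)
        uv, _ = reml.fit_univariate(df.rename(columns={"y": "estimate"}), sub)
        assert fit.log_likelihood == pytest.approx(uv.log_likelihood, abs=1e-6)

    def test_interaction_ratio_recovery(self):
        rats = []
        for seed in range(10):
            _, _, _, means, grm = make_panel(
                seed, 200, 1000, ("y",), [[1.0]], [[1.0]], n_sites=3,
                sigma2_gxe=0.5, site_means=[[3.0], [2.0], [1.5]],
            )
            long = means.melt(id_vars=["site", "accession"], var_name="trait",
                              value_name="estimate")
            comps, _ = reml.fit_gxe(long, grm, trait="y")
            rats.append(comps["sigma2_gxe"] / comps["sigma2_A"])
        assert abs(np.mean(rats) - 0.5) < 0.2

    def test_gebv_table_structure(self):
        _, _, _, means, grm = make_panel(4, 80, 300, ("y",), [[1.0]], [[1.0]],
                                         n_sites=2, sigma2_gxe=0.3)
        long = means.melt(id_vars=["site", "accession"], var_name="trait",
                          value_name="estimate")
        comps, gebv = reml.fit_gxe(long, grm, trait="y")
        main = gebv[gebv["site"].isna()]
        assert len(main) == 80
        assert abs(main["gebv"].mean()) < 1e-6 * max(main["gebv"].std(), 1e-12)
        assert len(gebv[gebv["site"] == "S1"]) == 80
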