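"""Generator contracts: determinism, moment targeting, field structure."""

import numpy as np
import pandas as pd
import pytest

from safgp import sim


def _params(**kw):
    base = dict(n_lines=50, n_markers=40, seed=3)
    base.update(kw)
    return sim.SimParams(**base)


class TestSimulateGenotypes:
    def test_no_missing_when_rate_zero(self):
        g = sim.simulate_genotypes(_params(missing_rate=0.0))
        assert not g.missing_mask.any()

    def test_same_seed_bit_identical(self):
        p = _params(missing_rate=0.2)
        a = sim.simulate_genotypes(p)
        b = sim.simulate_genotypes(p)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.missing_mask, b.missing_mask)

    def test_different_seed_differs(self):
        a = sim.simulate_genotypes(_params(seed=1))
        b = sim.simulate_genotypes(_params(seed=2))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_realized_frequency_near_target(self):
        # Binomial sampling: at 1000 lines the realized frequency of a marker
        # drawn at p = 0.3 stays within +-0.05 (>3 sigma of sqrt(pq/2n))
        p = _params(n_lines=1000, n_markers=200, maf_range=(0.3, 0.3))
        g = sim.simulate_genotypes(p)
        freqs = g.dosages.mean(axis=0) / 2.0
        assert np.all(np.abs(freqs - 0.3) < 0.05)

    @pytest.mark.parametrize(
        "bad",
        [dict(maf_range=(0.0, 0.5)), dict(maf_range=(0.2, 0.6)),
         dict(n_lines=1), dict(missing_rate=1.5), dict(rho_row=1.0)],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            _params(**bad)


class TestTrueEffects:
    def test_gxe_exactly_zero_without_interaction(self):
        p = _params(sigma2_gxe=0.0, n_sites=2)
        g = sim.simulate_genotypes(p)
        eff = sim.simulate_true_effects(g, p)
        for site in p.site_names:
            assert np.all(eff.gE[site] == 0.0)

    def test_realized_covariance_matches_target_exactly(self):
        # marker effects are rescaled so the sample covariance hits T exactly
        T = np.array([[4.0, 3.0], [3.0, 9.0]])
        p = _params(n_lines=500, n_markers=400, traits=("a", "b"),
                    T_target=T, R_target=np.eye(2))
        g = sim.simulate_genotypes(p)
        eff = sim.simulate_true_effects(g, p)
        C = np.cov(eff.g, rowvar=False, ddof=1)
        np.testing.assert_allclose(C, T, atol=1e-8)
        r = C[0, 1] / np.sqrt(C[0, 0] * C[1, 1])
        assert abs(r - 0.5) < 1e-10

    def test_gxe_variance_targets(self):
        p = _params(n_lines=400, n_markers=300, sigma2_gxe=0.8, n_sites=3)
        g = sim.simulate_genotypes(p)
        eff = sim.simulate_true_effects(g, p)
        for site in p.site_names:
            assert eff.gE[site].var(ddof=1) == pytest.approx(0.8, rel=1e-8)

    def test_non_pd_target_rejected(self):
        with pytest.raises(ValueError):
            _params(traits=("a", "b"), T_target=[[1.0, 2.0], [2.0, 1.0]],
                    R_target=np.eye(2))


class TestSimulateTrial:
    def test_all_variances_zero_gives_site_mean(self):
        p = _params(n_lines=12, T_target=[[1e-6]], R_target=[[0.0]],
                    site_means=[[5.0]], n_reps=2, layout_rows=4, layout_cols=6)
        g = sim.simulate_genotypes(p)
        eff = sim.simulate_true_effects(g, p)
        eff.g[:] = 0.0  # silence the (tiny) genetic part as well
        trial = sim.simulate_trial(g, eff, p)
        np.testing.assert_allclose(trial["GY"], 5.0)

    def test_plot_coordinates_unique_and_reps_complete(self):
        p = _params(n_lines=20, n_reps=2, layout_rows=5, layout_cols=8)
        g = sim.simulate_genotypes(p)
        eff = sim.simulate_true_effects(g, p)
        trial = sim.simulate_trial(g, eff, p)
        assert not trial.duplicated(subset=["site", "row", "col"]).any()
        counts = trial.groupby(["site", "accession"]).size()
        assert (counts == 2).all()

    def test_determinism(self):
        p = _params(n_lines=15, n_reps=2, layout_rows=4, layout_cols=8,
                    rho_row=0.4, rho_col=0.3)
        g = sim.simulate_genotypes(p)
        eff = sim.simulate_true_effects(g, p)
        a = sim.simulate_trial(g, eff, p)
        b = sim.simulate_trial(g, eff, p)
        pd.testing.assert_frame_equal(a, b)

    def test_uncorrelated_residuals_when_rho_zero(self):
        # neighbouring-plot residual correlation ~ 0 at 1000+ plots
        p = _params(n_lines=500, n_markers=30, T_target=[[1e-8]], R_target=[[1.0]],
                    rho_row=0.0, rho_col=0.0, n_reps=2,
                    layout_rows=25, layout_cols=40)
        g = sim.simulate_genotypes(p)
        eff = sim.simulate_true_effects(g, p)
        eff.g[:] = 0.0
        trial = sim.simulate_trial(g, eff, p).sort_values(["site", "row", "col"])
        wide = trial.pivot(index="row", columns="col", values="GY").to_numpy()
        r = np.corrcoef(wide[:, :-1].ravel(), wide[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_layout_too_small_rejected(self):
        with pytest.raises(ValueError):
            _params(n_lines=30, n_reps=2, layout_rows=3, layout_cols=8)


class TestAccessionMeans:
    def test_shape_and_determinism(self):
        p = _params(n_sites=2, traits=("a", "b"), T_target=np.eye(2),
                    R_target=np.eye(2))
        g = sim.simulate_genotypes(p)
        eff = sim.simulate_true_effects(g, p)
        m1 = sim.simulate_accession_means(g, eff, p)
        m2 = sim.simulate_accession_means(g, eff, p)
        pd.testing.assert_frame_equal(m1, m2)
        assert len(m1) == 2 * p.n_lines
        assert set(m1.columns) == {"site", "accession", "a", "b"}
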