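"""Selection indices, truncation selection and response arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from safgp import indices


class TestStandardize:
    def test_simple(self):
        z = indices.standardize(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        z = indices.standardize(pd.Series([0.3, -1.2, 2.0, 0.1]))
        np.testing.assert_allclose(indices.standardize(z), z, atol=1e-12)

    @given(
        a=st.floats(-50, 50),
        b=st.floats(0.01, 50),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b):
        x = pd.Series([0.0, 1.0, 5.0, -2.0])
        np.testing.assert_allclose(
            indices.standardize(a + b * x), indices.standardize(x), atol=1e-8
        )

    def test_degenerate_scores(self):
        with pytest.raises(ValueError):
            indices.standardize(pd.Series([2.0, 2.0, 2.0]))


class TestSmithHazel:
    def test_identity_p(self):
        np.testing.assert_allclose(
            indices.smith_hazel_weights(np.eye(2), [0.5, 0.2]), [0.5, 0.2]
        )

    def test_diagonal_p(self):
        np.testing.assert_allclose(
            indices.smith_hazel_weights(np.diag([2.0, 4.0]), [1.0, 2.0]), [0.5, 0.5]
        )

    def test_correlated_p_closed_form(self):
        b = indices.smith_hazel_weights(np.array([[1.0, 0.5], [0.5, 1.0]]), [1.0, 0.0])
        np.testing.assert_allclose(b, [4.0 / 3.0, -2.0 / 3.0], atol=1e-10)

    def test_singular_p(self):
        with pytest.raises(np.linalg.LinAlgError):
            indices.smith_hazel_weights(np.ones((2, 2)), [1.0, 1.0])


class TestBuildIndex:
    def _scores(self):
        return pd.DataFrame(
            {"GY": [1.0, 2.0, 3.0], "OL": [3.0, 2.0, 1.0]}, index=list("abc")
        )

    def test_unit_weight_passthrough(self):
        spec = indices.IndexSpec("MTGS2", ("GY", "OL"), (1.0, 0.0), False, "GEBV_UV")
        out = indices.build_index(self._scores(), spec)
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_equal_weight_standardized(self):
        spec = indices.IndexSpec("MTGS1", ("GY", "OL"), (1.0, 1.0), True, "GEBV_UV")
        scores = pd.DataFrame({"GY": [0.0, 1.0], "OL": [0.0, 1.0]}, index=list("ab"))
        with pytest.raises(ValueError):
            # two points standardize fine, but make z = (1,1) explicit instead
            indices.build_index(pd.DataFrame({"GY": [1, 1], "OL": [1, 1]},
                                             index=list("ab")), spec)
        out = indices.build_index(scores, spec)
        # each trait standardizes to (-x, x); equal weights double it
        assert out["b"] == pytest.approx(2 * indices.standardize(scores["GY"])["b"])

    def test_linearity_in_weights(self):
        s1 = indices.IndexSpec("MTGS2", ("GY", "OL"), (0.4, -0.2), False, "GEBV_UV")
        s2 = indices.IndexSpec("MTGS2", ("GY", "OL"), (0.8, -0.4), False, "GEBV_UV")
        a = indices.build_index(self._scores(), s1)
        b = indices.build_index(self._scores(), s2)
        np.testing.assert_allclose(b, 2 * a, atol=1e-12)

    def test_missing_trait_score(self):
        spec = indices.IndexSpec("MTGS1", ("GY", "OL"), (1.0, 1.0), True, "GEBV_UV")
        scores = self._scores()
        scores.loc["b", "OL"] = np.nan
        with pytest.raises(ValueError, match="b"):
            indices.build_index(scores, spec)


class TestSelectTop:
    def test_top_one_of_five(self):
        idx = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        assert indices.select_top_fraction(idx, 0.2) == ["e"]

    def test_349_gives_69(self):
        idx = pd.Series(np.arange(349.0), index=[f"a{i:03d}" for i in range(349)])
        assert len(indices.select_top_fraction(idx, 0.2)) == 69

    def test_tie_broken_by_id(self):
        idx = pd.Series([5.0, 5.0, 1.0, 0.0, 0.0], index=["zz", "aa", "mm", "b", "c"])
        assert indices.select_top_fraction(idx, 0.2) == ["aa"]

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            indices.select_top_fraction(pd.Series([1.0, 2.0]), 0.2)


class TestResponse:
    def test_breeders_equation(self):
        pop = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        rep = indices.selection_response(pop, ["e"], h2=0.5)
        assert rep.S == pytest.approx(2.0)
        assert rep.R == pytest.approx(1.0)

    def test_select_all_zero_differential(self):
        pop = pd.Series([1.0, 2, 3], index=list("abc"))
        rep = indices.selection_response(pop, list("abc"), h2=0.7)
        assert rep.S == 0.0 and rep.R == 0.0

    def test_percent_gain_definition(self):
        pop = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        rep = indices.selection_response(pop, ["e"], h2=0.5, site_mean=3.0)
        assert rep.percent_gain == pytest.approx(100.0 / 3.0)

    def test_ps_is_maximal_on_its_own_criterion(self):
        rng = np.random.default_rng(12)
        ids = [f"a{i}" for i in range(50)]
        blues = pd.Series(rng.standard_normal(50), index=ids)
        other = pd.Series(rng.standard_normal(50), index=ids)
        sel_ps = indices.select_top_fraction(blues, 0.2)
        sel_other = indices.select_top_fraction(other, 0.2)
        S_ps = blues.loc[sel_ps].mean() - blues.mean()
        S_other = blues.loc[sel_other].mean() - blues.mean()
        assert S_ps >= S_other

    def test_cross_site_translation_invariance(self):
        rng = np.random.default_rng(3)
        ids = [f"a{i}" for i in range(40)]
        sel_vals = pd.Series(rng.standard_normal(40), index=ids)
        shifted = sel_vals + 4.0
        reports = indices.cross_site_response(
            "here", sel_vals, {"here": sel_vals, "there": shifted},
            {"here": 0.5, "there": 0.5}, 0.2,
        )
        assert reports[0].S == pytest.approx(reports[1].S, abs=1e-12)

    def test_cross_site_uncorrelated_small_differential(self):
        rng = np.random.default_rng(21)
        ids = [f"a{i}" for i in range(300)]
        sel_vals = pd.Series(rng.standard_normal(300), index=ids)
        other = pd.Series(rng.standard_normal(300), index=ids)
        reports = indices.cross_site_response(
            "here", sel_vals, {"there": other}, {"there": 0.5}, 0.2,
        )
        # S at an uncorrelated site ~ N(0, sigma/sqrt(60)): +-2 SE band
        assert abs(reports[0].S) < 2 * 1.0 / np.sqrt(60) * 1.5

    def test_missing_accessions_counted(self):
        pop = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        rep = indices.selection_response(pop, ["c", "zz"], h2=0.5)
        assert rep.n_excluded == 1
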