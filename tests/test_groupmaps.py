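"""Difference maps, BH-FDR, weight correlations, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import brainpad as bp
from brainpad.groupmaps import (
    bh_fdr,
    correlate_weights_tmap,
    partial_corr,
    regression_tmap,
    roi_ttest_map,
    top_feature_overlap,
)


def _features(values, n_subjects):
    return pd.DataFrame(values, index=[f"s{i}" for i in range(n_subjects)],
                        columns=[f"R{j:03d}" for j in range(values.shape[1])])


class TestTTestMap:
    def test_identical_groups_give_null_map(self, rng):
        block = rng.standard_normal((10, 5))
        f = _features(np.vstack([block, block]), 20)
        groups = np.array(["MDD"] * 10 + ["HC"] * 10)
        tm = roi_ttest_map(f, groups)
        assert np.allclose(tm.t, 0.0)
        assert np.allclose(tm.p, 1.0)
        assert not tm.significant.any()

    def test_sign_convention_thinning_negative(self, rng):
        mdd = 1.0 + 0.01 * rng.standard_normal((10, 3))
        hc = 2.0 + 0.01 * rng.standard_normal((10, 3))
        tm = roi_ttest_map(_features(np.vstack([mdd, hc]), 20),
                           np.array(["MDD"] * 10 + ["HC"] * 10))
        assert (tm.t < -10).all()

    def test_three_vs_three_textbook_formula(self):
        mdd = np.array([2.0, 2.1, 1.9])
        hc = np.array([2.4, 2.5, 2.3])
        tm = roi_ttest_map(_features(np.concatenate([mdd, hc])[:, None], 6),
                           np.array(["MDD"] * 3 + ["HC"] * 3))
        sp = np.sqrt((2 * mdd.var(ddof=1) + 2 * hc.var(ddof=1)) / 4)
        expected = (mdd.mean() - hc.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert tm.t[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_region_flagged(self, rng):
        vals = rng.standard_normal((20, 3))
        vals[:, 1] = 4.2
        with pytest.warns(RuntimeWarning, match="undefined"):
            tm = roi_ttest_map(_features(vals, 20),
                               np.array(["MDD"] * 10 + ["HC"] * 10))
        assert tm.excluded[1] and not tm.excluded[0]
        assert np.isnan(tm.q[1]) and not tm.significant[1]


class TestBHFDR:
    def test_stepup_hand_example(self):
        q, rej = bh_fdr([0.01, 0.02, 0.03, 0.04], 0.05)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_all_ones(self):
        q, rej = bh_fdr(np.ones(7), 0.05)
        assert np.allclose(q, 1.0) and not rej.any()

    def test_single_p_identity(self):
        q, rej = bh_fdr([0.04], 0.05)
        assert q[0] == pytest.approx(0.04) and rej[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_p_dominates_raw(self, ps):
        q, _ = bh_fdr(ps, 0.05)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)

    def test_empirical_fdr_controlled(self, rng):
        """500 mixture simulations (80% true nulls): empirical FDR <= q + 0.02."""
        fdrs = []
        for _ in range(500):
            p_null = rng.uniform(size=40)
            p_alt = rng.beta(0.1, 8, size=10)
            p = np.concatenate([p_null, p_alt])
            is_null = np.arange(50) < 40
            _, rej = bh_fdr(p, 0.05)
            if rej.any():
                fdrs.append(np.sum(rej & is_null) / rej.sum())
            else:
                fdrs.append(0.0)
        assert np.mean(fdrs) <= 0.05 + 0.02


class TestRegressionMap:
    def test_agrees_with_ttest_when_unconfounded(self, geometry60):
        # no age-driven variance heterogeneity: the two routes measure the
        # same contrast and should agree almost exactly
        cohort = bp.make_cohort(150, 150, n_sites=3, seed=30)
        f, _ = bp.simulate_thickness(cohort, geometry60, seed=31, n_age_regions=0,
                                     n_affected=10, site_shift_sd=0.0,
                                     site_scale_sd=0.0)
        meta = cohort.set_index("subject_id")
        groups = meta["group"].to_numpy()
        tm_t = roi_ttest_map(f, groups)
        tm_r = regression_tmap(f, groups, meta[["age", "sex", "site"]])
        r = np.corrcoef(tm_t.t, tm_r.t)[0, 1]
        assert r > 0.99

    def test_group_confounded_with_site_rejected(self, rng):
        vals = rng.standard_normal((40, 5))
        groups = np.array(["MDD"] * 20 + ["HC"] * 20)
        cov = pd.DataFrame(
            {"age": rng.uniform(20, 60, 40), "sex": rng.integers(0, 2, 40),
             "site": np.array(["A"] * 20 + ["B"] * 20)}
        )
        with pytest.raises(ValueError, match="collinear"):
            regression_tmap(_features(vals, 40), groups, cov)

    def test_specific_under_pure_age_effect(self, geometry60):
        """Age slopes but no group effect: the group coefficient should be
        rejected at q<0.05 at no more than the nominal rate."""
        total, rejected = 0, 0
        for seed in range(100):
            cohort = bp.make_cohort(40, 30, n_sites=2, seed=seed)
            f, _ = bp.simulate_thickness(
                cohort, geometry60, seed=seed + 9000, n_age_regions=30,
                n_affected=0, effect_amplitude_mm=0.0,
            )
            meta = cohort.set_index("subject_id")
            tm = regression_tmap(f, meta["group"].to_numpy(),
                                 meta[["age", "sex", "site"]])
            total += len(tm.t)
            rejected += tm.significant.sum()
        assert rejected / total <= 0.05


class TestWeightCorrelation:
    def _tmap(self, t):
        n = len(t)
        return bp.TMap([f"R{i}" for i in range(n)], np.asarray(t, float),
                       np.full(n, 0.5), np.full(n, 0.5), np.zeros(n, bool),
                       np.zeros(n, bool))

    def test_self_and_anti_correlation(self, rng):
        t = rng.standard_normal(50)
        tm = self._tmap(t)
        assert correlate_weights_tmap(t, tm)[0] == pytest.approx(1.0)
        assert correlate_weights_tmap(-t, tm)[0] == pytest.approx(-1.0)

    def test_independent_weights_centre_on_zero(self, rng):
        t = rng.standard_normal(200)
        tm = self._tmap(t)
        rs = [correlate_weights_tmap(rng.standard_normal(200), tm)[0]
              for _ in range(500)]
        assert np.mean(rs) == pytest.approx(0.0, abs=0.02)

    def test_length_mismatch_rejected(self, rng):
        tm = self._tmap(rng.standard_normal(10))
        with pytest.raises(ValueError, match="mismatch"):
            correlate_weights_tmap(np.ones(9), tm)


class TestTopFeatureOverlap:
    def test_full_k_recovers_all_significant(self):
        scores = pd.Series([3.0, -2.0, 1.0, 0.5], index=list("abcd"))
        sig = [True, False, True, False]
        count, hits = top_feature_overlap(scores, sig, k=4)
        assert count == 2 and hits == ["a", "c"]

    def test_disjoint_sets_give_zero(self):
        scores = pd.Series([3.0, 2.0, 0.1, 0.2], index=list("abcd"))
        sig = [False, False, True, True]
        assert top_feature_overlap(scores, sig, k=2)[0] == 0

    def test_ties_broken_lexicographically(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=["b", "a", "c"])
        sig = pd.Series([True, True, True], index=["b", "a", "c"])
        count, hits = top_feature_overlap(scores, sig, k=2)
        assert hits == ["a", "b"]

    def test_k_bounds(self):
        scores = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            top_feature_overlap(scores, [True], k=-1)
        with pytest.raises(ValueError):
            top_feature_overlap(scores, [True], k=2)


class TestPartialCorr:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.standard_normal((2, 40))
        r, p = partial_corr(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)

    def test_covariate_driven_association_removed(self, rng):
        c = rng.standard_normal(50)
        x = 2.0 * c + rng.standard_normal(50)
        y = -3.0 * c  # exactly a linear function of the covariate
        r, _ = partial_corr(x, y, c)
        assert abs(r) < 1e-10

    def test_two_step_residual_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        c = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        D = np.column_stack([np.ones(6), c])
        rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
        ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        expected = np.corrcoef(rx, ry)[0, 1]
        r, _ = partial_corr(x, y, c)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.standard_normal(30)
        cov = rng.standard_normal((30, 2))
        y = 0.3 * x + cov @ [0.5, -0.2] + rng.standard_normal(30)
        r, p = partial_corr(x, y, cov)
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_insufficient_df_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_corr(np.ones(4), np.ones(4), rng.standard_normal((4, 2)))
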