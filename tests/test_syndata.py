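"""Generators: geometry, cohort, thickness, receptor maps, expression."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import brainpad as bp
from brainpad.syndata import DEFAULT_RECEPTOR_SPEC, ThicknessParams


class TestGeometry:
    def test_single_region_distance_matrix_is_zero(self):
        g = bp.make_geometry(1)
        assert g.dist.shape == (1, 1) and g.dist[0, 0] == 0.0

    def test_metric_bounds_on_unit_sphere(self):
        g = bp.make_geometry(100, seed=4)
        assert np.allclose(g.dist, g.dist.T)
        assert np.allclose(np.diag(g.dist), 0.0)
        assert g.dist.max() <= np.pi + 1e-12
        off = g.dist[~np.eye(100, dtype=bool)]
        assert off.min() > 0

    def test_distances_match_haversine_oracle(self):
        g = bp.make_geometry(4, seed=9)
        lat = np.arcsin(np.clip(g.coords[:, 2], -1, 1))
        lon = np.arctan2(g.coords[:, 1], g.coords[:, 0])
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                dlat, dlon = lat[i] - lat[j], lon[i] - lon[j]
                h = np.sin(dlat / 2) ** 2 + np.cos(lat[i]) * np.cos(lat[j]) * np.sin(dlon / 2) ** 2
                expected = 2 * np.arcsin(np.sqrt(h))
                assert g.dist[i, j] == pytest.approx(expected, abs=1e-10)

    def test_invalid_region_count_rejected(self):
        with pytest.raises(ValueError):
            bp.make_geometry(0)


class TestCohort:
    def test_study_scale_group_counts(self):
        cohort = bp.make_cohort(437, 233, n_sites=5, seed=1)
        assert len(cohort) == 670
        assert (cohort["group"] == "MDD").sum() == 233
        assert (cohort["group"] == "HC").sum() == 437

    def test_degenerate_all_hc(self):
        cohort = bp.make_cohort(20, 0, n_sites=2, seed=1)
        assert (cohort["group"] == "HC").all()

    def test_age_range_respected(self):
        cohort = bp.make_cohort(50, 50, n_sites=3, age_range=(18, 80), seed=7)
        assert cohort["age"].min() >= 18 and cohort["age"].max() <= 80

    def test_groups_age_matched(self):
        cohort = bp.make_cohort(300, 200, n_sites=5, seed=11)
        hc = cohort.loc[cohort["group"] == "HC", "age"]
        mdd = cohort.loc[cohort["group"] == "MDD", "age"]
        assert abs(hc.mean() - mdd.mean()) < 1.0

    def test_at_least_two_subjects_per_site(self):
        cohort = bp.make_cohort(7, 6, n_sites=5, seed=3)
        assert cohort["site"].value_counts().min() >= 2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bp.make_cohort(-1, 5)
        with pytest.raises(ValueError):
            bp.make_cohort(3, 0, n_sites=2)
        with pytest.raises(ValueError):
            bp.make_cohort(10, 10, age_range=(50, 50))


class TestThickness:
    def test_deterministic_limit(self, geometry60):
        cohort = bp.make_cohort(10, 10, n_sites=2, seed=5)
        f, truth = bp.simulate_thickness(
            cohort, geometry60, seed=6, noise_sd=0.0, site_shift_sd=0.0,
            site_scale_sd=0.0, effect_amplitude_mm=0.0, n_affected=0,
            n_age_regions=30,
        )
        # reconstruct baseline and slope per region by exact 2-point algebra
        ages = cohort["age"].to_numpy()
        v = f.to_numpy()
        slope = (v[1] - v[0]) / (ages[1] - ages[0])
        baseline = v[0] - slope * ages[0]
        recon = baseline[None, :] + np.outer(ages, slope)
        assert np.allclose(recon, v, atol=1e-10)

    def test_affected_regions_are_most_negative_group_difference(self, geometry60):
        cohort = bp.make_cohort(100, 100, n_sites=2, seed=8)
        f, truth = bp.simulate_thickness(
            cohort, geometry60, seed=9, noise_sd=0.0, site_shift_sd=0.0,
            site_scale_sd=0.0, effect_amplitude_mm=-0.2, n_affected=10,
            n_age_regions=30,
        )
        groups = cohort["group"].to_numpy()
        diff = (f.to_numpy()[groups == "MDD"].mean(axis=0)
                - f.to_numpy()[groups == "HC"].mean(axis=0))
        most_negative = set(np.argsort(diff)[:10])
        assert most_negative == set(np.flatnonzero(truth.affected_mask))

    def test_affected_cluster_is_contiguous(self, small_dataset, geometry60):
        _, _, truth = small_dataset
        affected = set(np.flatnonzero(truth.affected_mask))
        k = len(affected)
        # nearest-neighbour growth: the cluster is the k nearest regions of
        # (at least) one of its members
        assert any(
            set(np.argsort(geometry60.dist[m], kind="stable")[:k]) == affected
            for m in affected
        )

    def test_null_construction(self, geometry60):
        cohort = bp.make_cohort(10, 10, n_sites=2, seed=5)
        _, truth = bp.simulate_thickness(cohort, geometry60, seed=6, n_affected=0,
                                         n_age_regions=30)
        assert not truth.effect.any()

    def test_same_seed_byte_identical(self, geometry60):
        cohort = bp.make_cohort(20, 15, n_sites=3, seed=4)
        out = []
        for _ in range(2):
            f, _ = bp.simulate_thickness(cohort, geometry60, seed=42, n_age_regions=30)
            buf = _io.StringIO()
            f.to_csv(buf, sep="\t")
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_null_group_tstats_are_t_distributed(self, geometry60):
        """Under zero injected effect (and no age-driven variance) the
        per-region two-sample t-tests reject at the nominal 5% rate; with
        age slopes present the age-matched groups make the test conservative,
        never anti-conservative."""
        rates, rates_sloped = [], []
        for seed in range(200):
            cohort = bp.make_cohort(40, 40, n_sites=2, seed=seed)
            g = cohort["group"].to_numpy()
            for n_age, acc in ((0, rates), (30, rates_sloped)):
                f, _ = bp.simulate_thickness(
                    cohort, geometry60, seed=seed + 1000, effect_amplitude_mm=0.0,
                    n_affected=0, site_shift_sd=0.0, site_scale_sd=0.0,
                    n_age_regions=n_age,
                )
                _, p = stats.ttest_ind(
                    f.to_numpy()[g == "MDD"], f.to_numpy()[g == "HC"], axis=0
                )
                acc.append(np.mean(p < 0.05))
        assert 0.03 <= np.mean(rates) <= 0.07
        assert np.mean(rates_sloped) <= 0.07

    def test_site_effects_detectable_before_harmonization(self, geometry60):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cohort = bp.make_cohort(60, 40, n_sites=3, seed=seed)
            f, _ = bp.simulate_thickness(
                cohort, geometry60, seed=seed + 2000, site_shift_sd=0.1,
                noise_sd=0.05, n_affected=0, effect_amplitude_mm=0.0,
                n_age_regions=30,
            )
            sites = cohort["site"].to_numpy()
            vals = f.to_numpy()
            ps = [
                stats.f_oneway(*[vals[sites == s, j] for s in np.unique(sites)]).pvalue
                for j in range(vals.shape[1])
            ]
            hits += np.median(ps) < 0.01
        assert hits / n_seeds >= 0.95

    def test_invalid_parameters_rejected(self, geometry60):
        cohort = bp.make_cohort(10, 10, n_sites=2, seed=5)
        with pytest.raises(ValueError):
            bp.simulate_thickness(cohort, geometry60, n_affected=1000)
        with pytest.raises(ValueError):
            bp.simulate_thickness(cohort, geometry60, noise_sd=-0.1, n_age_regions=30)
        with pytest.raises(ValueError):
            bp.simulate_thickness(cohort, geometry60, baseline_mm=np.inf, n_age_regions=30)


class TestReceptorMaps:
    def test_pure_signal_limit(self, geometry60, small_dataset):
        _, _, truth = small_dataset
        maps = bp.simulate_receptor_maps(
            geometry60, truth, spec=[("x", 1.0, 0.5)], seed=1
        )
        assert bp.spearman_rho(maps["x"], truth.effect) == pytest.approx(1.0)

    def test_default_battery_has_nine_maps(self, geometry60, small_dataset):
        _, _, truth = small_dataset
        maps = bp.simulate_receptor_maps(geometry60, truth, seed=2)
        assert list(maps.columns) == [name for name, _, _ in DEFAULT_RECEPTOR_SPEC]
        assert maps.shape == (60, 9)

    def test_target_rho_controls_correlation(self, geometry100):
        cohort = bp.make_cohort(30, 30, n_sites=2, seed=0)
        _, truth = bp.simulate_thickness(cohort, geometry100, seed=1, n_affected=15,
                                         n_age_regions=50)
        for rho in (0.0, 0.6, -0.4):
            vals = []
            for seed in range(100):
                m = bp.simulate_receptor_maps(
                    geometry100, truth, spec=[("m", rho, 0.5)], seed=seed
                )
                vals.append(np.corrcoef(m["m"], truth.effect)[0, 1])
            assert np.mean(vals) == pytest.approx(rho, abs=0.05)

    def test_invalid_rho_rejected(self, geometry60, small_dataset):
        _, _, truth = small_dataset
        with pytest.raises(ValueError):
            bp.simulate_receptor_maps(geometry60, truth, spec=[("m", 1.5, 0.5)])


class TestExpression:
    def test_noiseless_signal_genes_perfectly_correlated(self, geometry60, small_dataset):
        _, _, truth = small_dataset
        expr, risk, _ = bp.simulate_expression(
            geometry60, truth, n_genes=50, n_signal=10, noise_sd=0.0, n_terms=5, seed=3
        )
        for gid in expr.attrs["signal_genes"]:
            r = np.corrcoef(expr[gid], truth.effect)[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_risk_list_is_signal_plus_equal_decoys(self, geometry60, small_dataset):
        _, _, truth = small_dataset
        expr, risk, _ = bp.simulate_expression(
            geometry60, truth, n_genes=300, n_signal=30, n_terms=10, seed=4
        )
        signal = set(expr.attrs["signal_genes"])
        assert len(risk) == 60 and signal <= set(risk)

    def test_enriched_term_is_mostly_signal(self, geometry60, small_dataset):
        _, _, truth = small_dataset
        expr, _, genesets = bp.simulate_expression(
            geometry60, truth, n_genes=300, n_signal=20, n_terms=10, seed=5
        )
        signal = set(expr.attrs["signal_genes"])
        term = genesets["T0000"]
        assert len(term.genes & signal) / len(term.genes) >= 0.8

    def test_null_expression_correlations_exchangeable(self, geometry60, small_dataset):
        """With no planted signal, gene-map correlations are exchangeable
        with those of an independently generated noise batch (KS test), and
        no gene approaches the |r| = 1 of a noiseless signal gene."""
        _, _, truth = small_dataset
        z = (truth.effect - truth.effect.mean()) / truth.effect.std()
        batches = []
        for seed in (6, 7):
            expr, _, _ = bp.simulate_expression(
                geometry60, truth, n_genes=200, n_signal=0, n_terms=5, seed=seed
            )
            batches.append(np.abs(np.corrcoef(expr.to_numpy().T, z)[:-1, -1]))
        assert stats.ks_2samp(batches[0], batches[1]).pvalue > 0.01
        assert max(batches[0].max(), batches[1].max()) < 0.9

    def test_signal_exceeding_genes_rejected(self, geometry60, small_dataset):
        _, _, truth = small_dataset
        with pytest.raises(ValueError):
            bp.simulate_expression(geometry60, truth, n_genes=10, n_signal=11)
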