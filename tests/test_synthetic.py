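"""Synthetic landscape generator: determinism, class guarantees, clustering."""

import numpy as np
import pytest
from scipy import stats

from ecodegrade.density import gi_star, rasterize_density
from ecodegrade.errors import EmptyValidationError, SimulationSpecError
from ecodegrade.features import DEGRADED
from ecodegrade.forest import pixel_trend
from ecodegrade.grassland import score_parcel
from ecodegrade.grid import make_grid
from ecodegrade.io import load_bundled_scheme, write_features
from ecodegrade.scoring import batch_score
from ecodegrade.synthetic import (SimulationSpec, simulate_canopy_series,
                                  simulate_features, simulate_grassland,
                                  simulate_validation_truth)
from ecodegrade.validation import extract_model_at_points, roc_auc

YEARS = list(range(2000, 2014))


class TestSpecValidation:
    def test_prevalence_outside_unit_interval(self):
        with pytest.raises(SimulationSpecError):
            SimulationSpec(prevalence={"grassland": 1.5})

    def test_negative_feature_count(self):
        with pytest.raises(SimulationSpecError):
            SimulationSpec(n_features={"cave": -1})

    def test_degenerate_extent(self):
        with pytest.raises(SimulationSpecError):
            SimulationSpec(extent=(0, 0, 0, 100))


class TestGrasslandGeneration:
    def test_prevalence_zero_all_parcels_natural_di(self):
        spec = SimulationSpec(n_features={"grassland": 120},
                              prevalence={"grassland": 0.0}, seed=3)
        for f in simulate_grassland(spec):
            assert score_parcel(f.attributes).di <= 30

    def test_prevalence_one_all_parcels_degraded_di(self):
        spec = SimulationSpec(n_features={"grassland": 120},
                              prevalence={"grassland": 1.0}, seed=3)
        for f in simulate_grassland(spec):
            assert score_parcel(f.attributes).di >= 65

    def test_empirical_prevalence_within_binomial_interval(self):
        spec = SimulationSpec(n_features={"grassland": 500},
                              prevalence={"grassland": 0.4}, seed=3)
        frac = np.mean([f.true_class == DEGRADED for f in simulate_grassland(spec)])
        lo, hi = stats.binom.interval(0.95, 500, 0.4)
        assert lo / 500 <= frac <= hi / 500
        assert abs(frac - 0.4) <= 0.05

    def test_scored_class_equals_hidden_truth(self):
        spec = SimulationSpec(n_features={"grassland": 200},
                              prevalence={"grassland": 0.5}, seed=9)
        feats, _ = batch_score(simulate_grassland(spec),
                               load_bundled_scheme("grassland"))
        for f in feats:
            assert (f.degradation_class == DEGRADED) == (f.true_class == DEGRADED)


@pytest.mark.parametrize("kind", ["cave", "river", "lake", "coastal"])
def test_generated_features_recover_truth_for_every_kind(kind):
    spec = SimulationSpec(n_features={kind: 150}, prevalence={kind: 0.35}, seed=5)
    scheme = load_bundled_scheme("coastal_terrestrial" if kind == "coastal" else kind)
    feats, _ = batch_score(simulate_features(kind, spec), scheme)
    assert len(feats) == 150
    for f in feats:
        assert (f.degradation_class == DEGRADED) == (f.true_class == DEGRADED)


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        for run in ("a", "b"):
            spec = SimulationSpec(n_features={"grassland": 60, "cave": 40},
                                  prevalence={"grassland": 0.3, "cave": 0.3}, seed=11)
            write_features(simulate_grassland(spec), tmp_path / f"g_{run}.geojson")
            write_features(simulate_features("cave", spec), tmp_path / f"c_{run}.geojson")
        assert (tmp_path / "g_a.geojson").read_bytes() == (tmp_path / "g_b.geojson").read_bytes()
        assert (tmp_path / "c_a.geojson").read_bytes() == (tmp_path / "c_b.geojson").read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_grassland(SimulationSpec(n_features={"grassland": 30}, seed=1))
        b = simulate_grassland(SimulationSpec(n_features={"grassland": 30}, seed=2))
        assert any(fa.geometry != fb.geometry for fa, fb in zip(a, b))


class TestParameterRecovery:
    def test_recovered_share_converges_with_n(self):
        """Pipeline-estimated degraded share approaches the requested
        prevalence; the tolerance halves from n=200 to n=2000."""
        p = 0.3
        for n, tol in ((200, 0.10), (2000, 0.05)):
            spec = SimulationSpec(n_features={"lake": n}, prevalence={"lake": p},
                                  seed=21)
            feats, tally = batch_score(simulate_features("lake", spec),
                                       load_bundled_scheme("lake"))
            assert abs(tally[DEGRADED] / n - p) <= tol


class TestCanopySeries:
    def test_fewer_than_three_epochs_rejected(self):
        with pytest.raises(SimulationSpecError):
            simulate_canopy_series(SimulationSpec(), [2000, 2001])

    def test_noise_free_drop_recovers_exact_slope(self):
        spec = SimulationSpec(prevalence={"forest": 0.5}, seed=2)
        sim = simulate_canopy_series(spec, YEARS, shape=(10, 10),
                                     drop_range=(20.0, 20.0), noise_sd=0.0)
        res = pixel_trend(sim.years, sim.canopy, canopy_range=None)
        total = res.total_change[sim.true_degraded]
        np.testing.assert_allclose(total, -20.0, atol=1e-9)

    def test_noise_free_intact_forest_flags_nothing(self):
        spec = SimulationSpec(prevalence={"forest": 0.0}, seed=2)
        sim = simulate_canopy_series(spec, YEARS, shape=(10, 10), noise_sd=0.0)
        res = pixel_trend(sim.years, sim.canopy)
        assert not res.degraded.any()

    def test_noisy_fifteen_point_drop_detected_with_high_power(self):
        """sd-2 noise, 14 annual epochs, 15-point drop: at least 95% of truly
        degraded pixels are flagged by the >10-point rule (normal-theory
        power of the OLS slope test is ~99.8% here)."""
        spec = SimulationSpec(prevalence={"forest": 0.3}, seed=4, noise_sd=2.0)
        sim = simulate_canopy_series(spec, YEARS, shape=(40, 40),
                                     drop_range=(15.0, 15.0))
        res = pixel_trend(sim.years, sim.canopy, canopy_range=None)
        sensitivity = res.degraded[sim.true_degraded].mean()
        assert sensitivity >= 0.95


class TestValidationTruth:
    def _scored(self, seed=6, n=250, prev=0.3):
        spec = SimulationSpec(n_features={"grassland": n},
                              prevalence={"grassland": prev}, seed=seed)
        feats, _ = batch_score(simulate_grassland(spec),
                               load_bundled_scheme("grassland"))
        return spec, feats

    def test_perfect_model_gives_auc_one(self):
        spec, feats = self._scored()
        pts = simulate_validation_truth(feats, spec, n_points=100)
        ex = extract_model_at_points(list(zip(pts.x, pts.y)), feats)
        keep = ex.in_buffer.to_numpy()
        truth = pts.truth.to_numpy()[keep]
        assert len(set(truth)) == 2
        assert roc_auc(truth, ex.model_score.to_numpy()[keep]).auc == pytest.approx(1.0)

    def test_shuffled_labels_give_chance_auc(self):
        spec, feats = self._scored()
        pts = simulate_validation_truth(feats, spec, n_points=100)
        ex = extract_model_at_points(list(zip(pts.x, pts.y)), feats)
        keep = ex.in_buffer.to_numpy()
        scores = ex.model_score.to_numpy()[keep]
        truth = pts.truth.to_numpy()[keep].copy()
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(200):
            rng.shuffle(truth)
            if len(set(truth)) == 2:
                aucs.append(roc_auc(truth, scores).auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_zero_points_rejected(self):
        spec, feats = self._scored()
        with pytest.raises(EmptyValidationError):
            simulate_validation_truth(feats, spec, n_points=0)

    def test_no_features_rejected(self):
        with pytest.raises(EmptyValidationError):
            simulate_validation_truth([], SimulationSpec(), n_points=10)


class TestClusteringControl:
    def _hotspot_fraction(self, cluster_count, seed=13):
        spec = SimulationSpec(
            extent=(0, 0, 20_000, 20_000),
            n_features={"cave": 2000},
            prevalence={"cave": 1.0},
            cluster_count=cluster_count,
            cluster_sd=1200.0,
            seed=seed,
        )
        feats, _ = batch_score(simulate_features("cave", spec),
                               load_bundled_scheme("cave"))
        grid = make_grid(spec.extent, 1000.0)
        dens = rasterize_density(feats, grid, "count")
        res = gi_star(dens, 2000.0)
        return res

    def test_single_cluster_yields_hot99_cells(self):
        res = self._hotspot_fraction(cluster_count=1)
        assert (res.bins.values == 3).sum() >= 1

    def test_uniform_landscape_stays_near_nominal_significance(self):
        """With clustering disabled the degraded features are spatially
        uniform Poisson noise; the |z| > 1.96 fraction stays below 5%
        on average across replicate landscapes."""
        fracs = []
        for seed in range(10):
            res = self._hotspot_fraction(cluster_count=0, seed=seed)
            z = res.z.values
            fracs.append((np.abs(z) > 1.96).mean())
        assert np.mean(fracs) < 0.05
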