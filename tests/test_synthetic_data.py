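import numpy as np
import pytest
from scipy.integrate import quad

from pollendiv.io_core import partition_datasets, read_plant_survey, \
    read_pollen_counts, read_ppe_table
from pollendiv.spatial_scaling import cumulative_richness
from pollendiv.synthetic_data import (
    SyntheticConfig,
    band_kernel_mass,
    effective_source_radius,
    generate_landscape,
    lambda_for_source_radius,
    make_fixture_suite,
    preset_config,
    simulate_plant_survey,
    simulate_pollen,
    simulate_study,
)


class TestKernel:
    def test_source_radius_matches_numerical_integration(self):
        for lam in (20.0, 44.2, 120.0):
            total = quad(lambda r: r * np.exp(-r / lam), 0, 1000)[0]
            target = 0.85 * total
            r_eff = effective_source_radius(lam)
            got = quad(lambda r: r * np.exp(-r / lam), 0, r_eff)[0]
            assert got == pytest.approx(target, rel=1e-8)

    def test_lambda_inversion_round_trip(self):
        for r in (50.0, 150.0, 400.0):
            lam = lambda_for_source_radius(r)
            assert effective_source_radius(lam) == pytest.approx(r, abs=1e-6)

    def test_r_eff_strictly_increasing_in_lambda(self):
        lams = [10.0, 30.0, 60.0, 120.0, 300.0]
        r = [effective_source_radius(l) for l in lams]
        assert all(a < b for a, b in zip(r, r[1:]))

    def test_band_masses_sum_to_total(self):
        edges = np.array([10.0, 100.0, 1000.0])
        masses = band_kernel_mass(edges, 44.2)
        total = quad(lambda r: 2 * np.pi * r * np.exp(-r / 44.2), 0, 1000)[0]
        assert masses.sum() == pytest.approx(total, rel=1e-9)


class TestConfig:
    def test_preset_defaults_match_study_design(self):
        cfg = preset_config("two-region")
        assert sum(cfg.n_sites.values()) == 60
        assert cfg.pollen_sum >= 943

    def test_strong_signal_kernel_targets_150m(self):
        cfg = preset_config("strong-signal")
        assert effective_source_radius(cfg.dispersal_lambda) == \
            pytest.approx(150.0, abs=1e-6)

    @pytest.mark.parametrize("field,value", [
        ("background_fraction", 1.2), ("dispersal_lambda", -1.0),
        ("pollen_sum", 100), ("canopy_interception", 0.0)])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            SyntheticConfig(**{field: value})


class TestLandscape:
    def test_zero_mosaic_grain_pure_central_habitat(self):
        cfg = SyntheticConfig(mosaic_grain={"region_poor": 0.0,
                                            "region_rich": 0.0})
        land = generate_landscape(cfg, seed=0)
        for i, site in enumerate(land.sites):
            own = ("forest", "open").index(site.habitat)
            assert (land.weights[i, :, own] == 1.0).all()

    def test_central_bands_pure_own_habitat(self):
        land = generate_landscape(preset_config("two-region"), seed=1)
        central = land.band_edges <= 10.0
        for i, site in enumerate(land.sites):
            own = ("forest", "open").index(site.habitat)
            assert (land.weights[i, central, own] == 1.0).all()

    def test_rich_region_has_finer_habitat_mosaic(self):
        # Shannon entropy of band habitat weights, averaged over seeds
        def mean_entropy(region):
            vals = []
            for seed in range(30):
                land = generate_landscape(preset_config("two-region"), seed)
                for i, s in enumerate(land.sites):
                    if s.region != region:
                        continue
                    w = land.weights[i]
                    w = np.clip(w, 1e-12, None)
                    vals.append(float((-w * np.log(w)).sum(axis=1).mean()))
            return np.mean(vals)

        assert mean_entropy("region_rich") > mean_entropy("region_poor")


class TestSurvey:
    def test_fine_scale_fraction_calibration(self):
        # no randomness in commonness/patchiness, no mosaic: the expected
        # fraction of own-habitat species appearing <= 10 m equals the
        # fine-scale richness parameter
        cfg = SyntheticConfig(commonness_sigma=0.0, patchiness_sigma=0.0,
                              mosaic_grain={"region_poor": 0.0,
                                            "region_rich": 0.0},
                              n_canopy_species=0, fine_scale_richness=0.3)
        land = generate_landscape(cfg, seed=3)
        real = simulate_plant_survey(land, cfg, seed=3)
        df = real.survey.records
        fracs = []
        for site in land.sites:
            own_prefix = f"sp_{site.region}_{site.habitat}"
            pool = [s for s in land.pool.names if s.startswith(own_prefix)]
            sub = df[(df.site_id == site.site_id)
                     & df.species.str.startswith(own_prefix)]
            fracs.append((sub.first_distance_m <= 10).sum() / len(pool))
        assert np.mean(fracs) == pytest.approx(0.3, abs=0.03)

    def test_cumulative_richness_conserved_at_1km(self, two_region_study):
        _, survey, _, _ = two_region_study
        curve = cumulative_richness(survey, [1000.0])
        per_site = survey.records.groupby("site_id").size()
        for site, n in per_site.items():
            assert curve.loc[site, 1000.0] == n

    def test_majority_of_species_appear_within_100m(self):
        # the rich open-habitat stratum accumulates more than half of its
        # recorded species within the first 100 m, averaged over seeds
        fracs = []
        for seed in range(10):
            pollen, survey, _, _ = simulate_study("two-region", seed=seed)
            part = partition_datasets(pollen)
            rec = survey.records[
                survey.records.site_id.isin(part["region_rich_open"])]
            fracs.append((rec.first_distance_m <= 100).mean())
        assert np.mean(fracs) > 0.5


class TestPollen:
    def test_counts_sum_to_pollen_sum(self, two_region_study):
        pollen, _, _, _ = two_region_study
        assert (pollen.totals == preset_config("two-region").pollen_sum).all()

    def test_canopy_interception_raises_open_taxa_share_in_forest(self):
        # stronger interception mixes more regional (open-rich) background
        # into forest samples
        def forest_open_share(interception, seed):
            cfg = preset_config("two-region")
            cfg.canopy_interception = interception
            pollen, _, _, _ = simulate_study(cfg, seed=seed)
            shares = []
            for i, site in enumerate(pollen.sites):
                if site.habitat != "forest":
                    continue
                p = pollen.counts[i] / pollen.counts[i].sum()
                open_cols = [j for j, t in enumerate(pollen.taxa)
                             if t.endswith("_open")]
                shares.append(p[open_cols].sum())
            return np.mean(shares)

        lo = np.mean([forest_open_share(0.05, s) for s in range(8)])
        hi = np.mean([forest_open_share(0.95, s) for s in range(8)])
        assert hi > lo

    def test_deterministic_given_seed(self):
        a = simulate_study("two-region", seed=5)[0]
        b = simulate_study("two-region", seed=5)[0]
        np.testing.assert_array_equal(a.counts, b.counts)


class TestFixtureSuite:
    def test_files_pass_io_validation(self, tmp_path):
        paths = make_fixture_suite("two-region", seed=2, outdir=tmp_path)
        pollen = read_pollen_counts(paths["pollen"])
        survey = read_plant_survey(paths["plants"])
        ppe = read_ppe_table(paths["ppe"])
        assert pollen.n_sites == 60
        assert len(ppe.ppe) == 25
        assert len(survey) > 0
        sizes = partition_datasets(pollen).sizes()
        assert sizes["region_poor_complete"] == 21
        assert sizes["region_rich_complete"] == 39

    def test_same_seed_byte_identical(self, tmp_path):
        p1 = make_fixture_suite("two-region", seed=4, outdir=tmp_path / "a")
        p2 = make_fixture_suite("two-region", seed=4, outdir=tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
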