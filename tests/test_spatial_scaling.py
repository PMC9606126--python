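import numpy as np
import pandas as pd
import pytest

from pollendiv.beta_diversity import bd_total_at_radius
from pollendiv.io_core import PlantSurvey, partition_datasets
from pollendiv.spatial_scaling import (
    DEFAULT_RADIUS_GRID,
    adjusted_r2,
    bd_total_scan,
    completeness_ratio,
    cumulative_richness,
    fit_scaling_regressions,
    lcbd_scan,
    new_species_by_band,
    validate_radius_grid,
)


def _survey(rows):
    return PlantSurvey(records=pd.DataFrame(
        rows, columns=["site_id", "species", "first_distance_m", "habitat"]))


class TestRadiusGrid:
    def test_default_grid_valid(self):
        g = validate_radius_grid(DEFAULT_RADIUS_GRID)
        assert g[0] == 0.5 and g[-1] == 1000

    @pytest.mark.parametrize("grid", [[10, 10, 20], [100, 50], [0.1, 10],
                                      [10, 2000]])
    def test_bad_grids_rejected(self, grid):
        with pytest.raises(ValueError):
            validate_radius_grid(grid)


class TestCumulativeRichness:
    def test_worked_example(self):
        survey = _survey([("s", "a", 0.5, "open"), ("s", "b", 40, "open"),
                          ("s", "c", 900, "open")])
        curve = cumulative_richness(survey, [10, 100, 1000])
        assert curve.loc["s"].tolist() == [1, 2, 3]

    def test_radius_below_first_distance_is_zero(self):
        survey = _survey([("s", "a", 50, "open")])
        assert cumulative_richness(survey, [10, 100]).loc["s"].tolist() == [0, 1]

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(4)
        rows = [(f"s{rng.integers(3)}", f"sp{k}",
                 float(rng.uniform(0.5, 1000)), "open") for k in range(120)]
        survey = _survey(rows)
        curve = cumulative_richness(survey, DEFAULT_RADIUS_GRID)
        df = survey.records
        for site in curve.index:
            for r in (6, 150, 550):
                naive = df[(df.site_id == site) & (df.first_distance_m <= r)]
                assert curve.loc[site, float(r)] == len(naive)

    def test_non_decreasing(self):
        rng = np.random.default_rng(8)
        rows = [("s0", f"sp{k}", float(rng.uniform(0.5, 1000)), "open")
                for k in range(60)]
        curve = cumulative_richness(_survey(rows), DEFAULT_RADIUS_GRID)
        assert (np.diff(curve.to_numpy(), axis=1) >= 0).all()


class TestNewSpeciesByBand:
    def test_single_species_in_band(self):
        survey = _survey([("s", "a", 70, "open")])
        table = new_species_by_band(survey, [10, 100])
        assert table.loc["<= 100 m", "open"] == 1

    def test_band_totals_conserved(self, toy_survey):
        table = new_species_by_band(toy_survey, DEFAULT_RADIUS_GRID)
        assert int(table.to_numpy().sum()) == len(toy_survey)


class TestRegression:
    def test_closed_form_ols_on_four_points(self):
        # hand least-squares: Sxy = 7, Sxx = 5, Syy = 10
        survey = _survey([(f"s{i}", f"sp{k}", 5.0, "open")
                          for i, n in enumerate([1, 2, 3, 4])
                          for k in range(n)])
        pollen = {"s0": 2.0, "s1": 3.0, "s2": 5.0, "s3": 6.0}
        res = fit_scaling_regressions(pollen, survey, [10.0])
        s = res.summaries[0]
        assert s.slope == pytest.approx(1.4)
        assert s.intercept == pytest.approx(0.5)
        assert s.r2 == pytest.approx(0.98)
        assert s.adj_r2 == pytest.approx(1 - (1 - 0.98) * 3 / 2)

    def test_perfect_collinearity(self):
        survey = _survey([(f"s{i}", f"sp{k}", 5.0, "open")
                          for i in range(5) for k in range(i + 1)])
        pollen = {f"s{i}": 2.0 * (i + 1) + 1 for i in range(5)}
        s = fit_scaling_regressions(pollen, survey, [10.0]).summaries[0]
        assert s.r2 == pytest.approx(1.0)
        assert s.adj_r2 == pytest.approx(1.0)
        assert s.p_value < 1e-6

    def test_adjusted_r2_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 2 * x + rng.normal(size=20)
        from scipy.stats import linregress

        r2 = linregress(x, y).rvalue ** 2
        r2b = linregress(3 * x - 7, 0.1 * y + 4).rvalue ** 2
        assert adjusted_r2(r2, 20) == pytest.approx(adjusted_r2(r2b, 20))

    def test_source_area_at_planted_radius(self):
        # pollen values equal plant richness at 150 m exactly; the scan must
        # put the source area there
        rng = np.random.default_rng(0)
        rows = []
        for i in range(12):
            for k in range(rng.integers(5, 30)):
                rows.append((f"s{i}", f"sp{k}", float(rng.uniform(0.5, 1000)),
                             "open"))
        survey = _survey(rows)
        curve = cumulative_richness(survey, DEFAULT_RADIUS_GRID)
        pollen = dict(zip(curve.index, curve[150.0].astype(float)))
        res = fit_scaling_regressions(pollen, survey)
        assert res.source_area_m == 150.0

    def test_zero_variance_radius_excluded_from_argmax(self):
        # every site has the same single species at 1 m: no variance at any
        # radius >= 1, variance only through the planted 500 m differences
        rows = [(f"s{i}", "common", 1.0, "open") for i in range(6)]
        rows += [(f"s{i}", f"extra{k}", 500.0, "open")
                 for i in range(6) for k in range(i)]
        survey = _survey(rows)
        pollen = {f"s{i}": float(i) for i in range(6)}
        res = fit_scaling_regressions(pollen, survey, [10.0, 600.0])
        assert np.isnan(res.summaries[0].adj_r2)
        assert res.source_area_m == 600.0

    def test_too_few_sites_rejected(self):
        survey = _survey([("s0", "a", 1.0, "open")])
        with pytest.raises(ValueError, match=">= 4 sites"):
            fit_scaling_regressions({"s0": 1.0}, survey, [10.0])


class TestBdTotalScan:
    def test_planted_linear_relation_at_150m(self, two_region_study):
        pollen, survey, ppe, truth = two_region_study
        partition = partition_datasets(pollen)
        # plant pollen BD as an exact affine image of plant BD at 150 m
        plant150 = {k: bd_total_at_radius(survey, partition[k], 150.0).bd_total
                    for k in partition.datasets}
        pollen_bd = {k: 0.05 + 0.8 * v for k, v in plant150.items()}
        res = bd_total_scan(pollen_bd, survey, partition)
        assert res.source_area_m == 150.0
        at150 = [s for s in res.summaries if s.radius == 150.0][0]
        assert at150.n == 6
        assert at150.adj_r2 == pytest.approx(1.0)

    def test_too_few_datasets_rejected(self, two_region_study):
        pollen, survey, _, _ = two_region_study
        partition = partition_datasets(pollen)
        with pytest.raises(ValueError, match=">= 3 datasets"):
            bd_total_scan({"region_poor_complete": 0.2}, survey, partition)


class TestLcbdScan:
    def test_identical_vectors_perfect_fit(self, two_region_study):
        from pollendiv.beta_diversity import beta_div_presence, presence_at_radius

        pollen, survey, _, _ = two_region_study
        sites = sorted(pollen.site_ids)[:10]
        y, _ = presence_at_radius(survey, sites, 200.0)
        plant_lcbd = beta_div_presence(y).lcbd
        pollen_lcbd = dict(zip(sites, plant_lcbd))
        res = lcbd_scan(pollen_lcbd, survey, sites, [200.0])
        assert res.summaries[0].adj_r2 == pytest.approx(1.0)

    def test_permuted_vector_no_signal(self, two_region_study):
        from pollendiv.beta_diversity import beta_div_presence, presence_at_radius

        pollen, survey, _, _ = two_region_study
        sites = sorted(pollen.site_ids)[:20]
        y, _ = presence_at_radius(survey, sites, 200.0)
        plant_lcbd = beta_div_presence(y).lcbd
        rng = np.random.default_rng(17)
        pollen_lcbd = dict(zip(sites, plant_lcbd[rng.permutation(len(sites))]))
        res = lcbd_scan(pollen_lcbd, survey, sites, [200.0])
        assert res.summaries[0].adj_r2 < 0.3
        assert not res.summaries[0].significant


class TestCompleteness:
    @pytest.mark.parametrize("recorded,reference,expected", [
        (799, 1477, 54.1), (1098, 2045, 53.7), (500, 500, 100.0)])
    def test_ratio(self, recorded, reference, expected):
        assert completeness_ratio(recorded, reference) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            completeness_ratio(10, 0)
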