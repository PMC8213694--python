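import itertools

import numpy as np
import pytest
from scipy import stats

from vegcoupling import coupling as cpl
from vegcoupling.grid import make_cube, monthly_index
from vegcoupling.indices import monthly_zscore


class TestSpearman:
    def test_monotone_relationships_are_extreme(self, rng):
        x = rng.standard_normal(30)
        rho_up, p_up, n = cpl.spearman(x, np.exp(x))
        rho_dn, _, _ = cpl.spearman(x, -(x**3))
        assert rho_up == pytest.approx(1.0)
        assert rho_dn == pytest.approx(-1.0)
        assert n == 30

    def test_all_orderings_match_rank_pearson(self):
        x = np.arange(5, dtype=float)
        for perm in itertools.permutations(range(5)):
            y = np.asarray(perm, dtype=float)
            rho, _, _ = cpl.spearman(x, y, min_n=3)
            rx, ry = np.argsort(np.argsort(x)), np.argsort(np.argsort(y))
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_too_few_pairs_is_invalid_not_error(self, rng):
        rho, p, n = cpl.spearman(rng.normal(size=5), rng.normal(size=5), min_n=10)
        assert np.isnan(rho) and np.isnan(p)
        assert n == 5

    def test_invariance_under_increasing_transform(self, rng):
        x, y = rng.standard_normal((2, 50))
        r1, _, _ = cpl.spearman(x, y)
        r2, _, _ = cpl.spearman(np.exp(x), y**3)  # odd power keeps order
        assert r1 == pytest.approx(r2)

    def test_vectorized_path_matches_scipy(self, rng):
        x = rng.standard_normal((40, 3, 4))
        y = 0.5 * x + rng.standard_normal((40, 3, 4))
        y[5, 1, 2] = np.nan  # one ragged cell exercises the fallback
        rho, p, n = cpl.spearman_maps(x, y)
        for iy in range(3):
            for ix in range(4):
                ok = np.isfinite(x[:, iy, ix]) & np.isfinite(y[:, iy, ix])
                r_ref, p_ref = stats.spearmanr(x[ok, iy, ix], y[ok, iy, ix])
                assert rho[iy, ix] == pytest.approx(r_ref, abs=1e-10)
                assert p[iy, ix] == pytest.approx(p_ref, abs=1e-8)
                assert n[iy, ix] == ok.sum()


class TestSeasonPairs:
    def test_default_growing_season_pair_count(self, small_dataset):
        anom = monthly_zscore(small_dataset.vegetation)
        x, y = cpl.season_pairs(anom, small_dataset.spei[3])
        assert x.shape[0] == 7 * 34  # 238 monthly pairs

    def test_summer_window_pair_count(self, small_dataset):
        anom = monthly_zscore(small_dataset.vegetation)
        x, _ = cpl.season_pairs(
            anom, small_dataset.spei[3], season=(6, 7, 8), year_range=(1990, 1994)
        )
        assert x.shape[0] == 15

    def test_annual_layout_one_pair_per_year(self, small_dataset):
        anom = monthly_zscore(small_dataset.vegetation)
        x, _ = cpl.season_pairs(anom, small_dataset.spei[3], layout="annual")
        assert x.shape[0] == 34

    def test_invalid_months_reduce_n(self, small_dataset):
        anom = monthly_zscore(small_dataset.vegetation).copy()
        anom.values[100, 0, 0] = np.nan  # a growing-season month (May)
        assert anom["time"].dt.month.values[100] in cpl.GROWING_SEASON
        x, y = cpl.season_pairs(anom, small_dataset.spei[3])
        _, _, n = cpl.spearman_maps(x, y)
        assert n[0, 0] == 237


class TestClassify:
    @pytest.mark.parametrize(
        "rho,p,expected",
        [
            (0.4, 0.01, "deficit"),
            (-0.4, 0.01, "surplus"),
            (0.4, 0.2, "none"),
            (-0.4, 0.051, "none"),
        ],
    )
    def test_classification_rules(self, rho, p, expected):
        cls = cpl.classify(np.array([[rho]]), np.array([[p]]), np.array([[100]]))
        assert cls[0, 0] == cpl.CLASS_CODES[expected]

    def test_low_n_is_invalid(self):
        cls = cpl.classify(np.array([[0.9]]), np.array([[0.001]]), np.array([[5]]))
        assert cls[0, 0] == cpl.CLASS_CODES["invalid"]

    def test_never_both_deficit_and_surplus(self, rng):
        rho = rng.uniform(-1, 1, size=(10, 10))
        p = rng.uniform(0, 1, size=(10, 10))
        n = np.full((10, 10), 50)
        cls = cpl.classify(rho, p, n)
        assert set(np.unique(cls)) <= set(cpl.CLASS_CODES.values())


class TestMovingWindows:
    def test_1982_2015_five_year_gives_30_windows(self, small_dataset):
        anom = monthly_zscore(small_dataset.vegetation)
        win = cpl.moving_windows(anom, small_dataset.spei[3], window_years=5)
        assert win.start_years.size == 30
        assert win.start_years[0] == 1982 and win.start_years[-1] == 2011

    def test_fifteen_year_gives_20_windows(self, small_dataset):
        anom = monthly_zscore(small_dataset.vegetation)
        win = cpl.moving_windows(anom, small_dataset.spei[3], window_years=15)
        assert win.start_years.size == 20

    def test_window_longer_than_record_rejected(self, small_dataset):
        anom = monthly_zscore(small_dataset.vegetation)
        with pytest.raises(ValueError):
            cpl.moving_windows(anom, small_dataset.spei[3], window_years=40)

    def test_window_pair_count(self, small_dataset):
        anom = monthly_zscore(small_dataset.vegetation)
        win = cpl.moving_windows(anom, small_dataset.spei[3], window_years=5)
        valid = small_dataset.valid
        assert np.all(win.n[:, valid] == 35)


class TestAreaFraction:
    def test_all_deficit_is_one(self):
        cls = np.full((4, 5), cpl.CLASS_CODES["deficit"], dtype=np.uint8)
        assert cpl.area_fraction(cls, "deficit") == 1.0

    def test_quarter_fraction(self):
        cls = np.full((10, 10), cpl.CLASS_CODES["none"], dtype=np.uint8)
        cls[:5, :5] = cpl.CLASS_CODES["deficit"]
        assert cpl.area_fraction(cls, "deficit") == pytest.approx(0.25)

    def test_partition_sums_to_one_per_window(self, small_dataset):
        anom = monthly_zscore(small_dataset.vegetation)
        win = cpl.moving_windows(anom, small_dataset.spei[3], window_years=10)
        total = sum(
            cpl.area_fraction(win.cls, regime, small_dataset.valid)
            for regime in ("deficit", "surplus", "none")
        )
        assert np.allclose(total, 1.0)
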