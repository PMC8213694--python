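import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vegcoupling import indices as idx
from vegcoupling.grid import make_cube, monthly_index


def _cube_from(values_3d, start_year=2000):
    values_3d = np.asarray(values_3d, dtype=float)
    end_year = start_year + values_3d.shape[0] // 12 - 1
    return make_cube(values_3d, monthly_index(start_year, end_year))


class TestMonthlyZscore:
    def test_climatology_means_give_zero_anomalies(self, rng):
        vals = rng.normal(5, 2, size=(36, 2, 2))
        cube = _cube_from(vals)
        clim = idx.Climatology.from_cube(cube)
        # replace every month by its own climatological mean -> anomaly 0
        months = cube["time"].dt.month.values
        flat = clim.mean[months - 1]
        anom = idx.monthly_zscore(cube.copy(data=flat), clim)
        assert np.allclose(anom.values, 0.0)

    def test_three_year_toy_series_sample_sd(self):
        # per calendar month the three years hold {1,2,3}: sample sd 1 -> {-1,0,1}
        vals = np.zeros((36, 1, 1))
        for year in range(3):
            vals[year * 12 : (year + 1) * 12, 0, 0] = year + 1
        anom = idx.monthly_zscore(_cube_from(vals))
        assert np.allclose(anom.values[:12, 0, 0], -1.0)
        assert np.allclose(anom.values[12:24, 0, 0], 0.0)
        assert np.allclose(anom.values[24:, 0, 0], 1.0)

    def test_constant_cell_marked_invalid_not_infinite(self):
        vals = np.ones((24, 1, 2))
        vals[:, 0, 1] = np.arange(24)
        anom = idx.monthly_zscore(_cube_from(vals))
        assert np.isnan(anom.values[:, 0, 0]).all()
        assert np.isfinite(anom.values[:, 0, 1]).all()

    def test_grid_mismatch_raises(self, rng):
        cube = _cube_from(rng.normal(size=(24, 2, 2)))
        clim = idx.Climatology.from_cube(_cube_from(rng.normal(size=(24, 3, 3))))
        with pytest.raises(ValueError, match="grid"):
            idx.monthly_zscore(cube, clim)


class TestWaterBalanceAggregation:
    def test_water_balance_arithmetic_and_mask(self):
        p = _cube_from(np.full((24, 1, 1), 50.0))
        pet = _cube_from(np.full((24, 1, 1), 80.0))
        pet.values[3, 0, 0] = np.nan
        d = idx.water_balance(p, pet)
        assert d.values[0, 0, 0] == pytest.approx(-30.0)
        assert np.isnan(d.values[3, 0, 0])

    def test_aggregate_k_running_sum(self):
        d = _cube_from(np.arange(1, 25, dtype=float).reshape(24, 1, 1))
        d3 = idx.aggregate_k(d, 3)
        assert np.isnan(d3.values[:2, 0, 0]).all()
        assert d3.values[2, 0, 0] == pytest.approx(6.0)  # 1+2+3
        assert d3.values[3, 0, 0] == pytest.approx(9.0)  # 2+3+4

    @pytest.mark.parametrize("k", [1, 5, 24])
    def test_leading_invalid_count_is_k_minus_1(self, rng, k):
        d = _cube_from(rng.normal(size=(48, 1, 1)))
        dk = idx.aggregate_k(d, k)
        assert int(np.isnan(dk.values[:, 0, 0]).sum()) == k - 1

    def test_out_of_range_k_rejected(self, rng):
        d = _cube_from(rng.normal(size=(24, 1, 1)))
        with pytest.raises(ValueError):
            idx.aggregate_k(d, 25)


class TestLogLogisticFit:
    def test_parameter_recovery_from_large_sample(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(size=100_000)
        x = 10.0 * (u / (1 - u)) ** (1 / 3.0)  # alpha=10, beta=3, gamma=0
        a, b, g = idx.fit_loglogistic(x)
        assert a == pytest.approx(10.0, rel=0.02)
        assert b == pytest.approx(3.0, rel=0.02)
        assert abs(g) < 0.02 * 10.0

    def test_fitted_cdf_at_sample_median_is_half(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(size=10_000)
        x = 5.0 + 4.0 * (u / (1 - u)) ** (1 / 2.5)
        a, b, g = idx.fit_loglogistic(x)
        assert idx.loglogistic_cdf(np.median(x), a, b, g) == pytest.approx(0.5, abs=0.02)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(idx.DegenerateFitError):
            idx.fit_loglogistic(np.full(30, 4.2))

    def test_left_skewed_sample_gets_mirrored_branch(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(size=20_000)
        x = -(u / (1 - u)) ** (1 / 3.0)  # mirrored log-logistic
        a, b, g = idx.fit_loglogistic(x)
        assert a < 0 and b < 0
        # still a valid CDF: monotone, 0.5 at the median
        assert idx.loglogistic_cdf(np.median(x), a, b, g) == pytest.approx(0.5, abs=0.02)
        grid = np.linspace(np.min(x), np.max(x), 50)
        f = idx.loglogistic_cdf(grid, a, b, g)
        assert np.all(np.diff(f) >= 0)


class TestComputeSpei:
    def test_monotone_in_dk_within_slot(self, rng):
        vals = rng.normal(0, 20, size=(480, 1, 1))
        d = _cube_from(vals, start_year=1970)
        d.attrs["timescale_months"] = 1
        params = idx.fit_loglogistic_slots(d)
        spei = idx.compute_spei(d, params)
        months = d["time"].dt.month.values
        for j in (1, 7):
            dk = vals[months == j, 0, 0]
            z = spei.values[months == j, 0, 0]
            order = np.argsort(dk)
            assert np.all(np.diff(z[order]) >= 0)

    def test_translation_invariance(self, rng):
        vals = rng.normal(5, 15, size=(480, 1, 1))
        a = _cube_from(vals, start_year=1970)
        b = _cube_from(vals + 123.4, start_year=1970)
        for c in (a, b):
            c.attrs["timescale_months"] = 1
        za = idx.compute_spei(a, idx.fit_loglogistic_slots(a))
        zb = idx.compute_spei(b, idx.fit_loglogistic_slots(b))
        assert np.allclose(za.values, zb.values, atol=1e-8)

    def test_values_clipped_to_range(self, rng):
        vals = rng.normal(0, 10, size=(480, 2, 2))
        d = _cube_from(vals, start_year=1970)
        d.attrs["timescale_months"] = 1
        spei = idx.compute_spei(d, idx.fit_loglogistic_slots(d), clip=2.0)
        assert np.nanmax(np.abs(spei.values)) <= 2.0


class TestAridityAndDrought:
    @pytest.mark.parametrize(
        "ai,expected",
        [
            (0.1, "arid"),
            (0.3, "semi-arid"),
            (0.5, "sub-humid"),  # shared boundary: upper class wins
            (0.6, "sub-humid"),
            (0.65, "humid"),
            (0.7, "humid"),
        ],
    )
    def test_class_boundaries(self, ai, expected):
        assert idx.classify_aridity(ai) == expected

    @given(st.floats(0.0, 10.0))
    @settings(max_examples=300, deadline=None)
    def test_partition_of_nonnegative_axis(self, ai):
        assert idx.classify_aridity(ai) in idx.ARIDITY_CLASSES

    def test_negative_ai_rejected(self):
        with pytest.raises(ValueError):
            idx.classify_aridity(-0.1)

    @pytest.mark.parametrize(
        "spei03,scpdsi,expect_spei,expect_pdsi",
        [
            (-1.5, -2.0, True, True),
            (-1.28, -1.0, False, False),  # strict thresholds
            (-0.5, -0.5, False, False),
            (-2.0, 0.5, True, False),
        ],
    )
    def test_drought_thresholds_strict(self, spei03, scpdsi, expect_spei, expect_pdsi):
        by_spei, by_pdsi = idx.flag_drought(spei03, scpdsi)
        assert by_spei is expect_spei
        assert by_pdsi is expect_pdsi

    def test_nonfinite_never_flagged(self):
        by_spei, _ = idx.flag_drought(np.nan)
        assert by_spei is False
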