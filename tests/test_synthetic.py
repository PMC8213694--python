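import numpy as np
import pytest

from vegcoupling import synthetic as syn
from vegcoupling.indices import classify_aridity, monthly_zscore
from vegcoupling.coupling import full_period_coupling


class TestConfigValidation:
    def test_zero_size_grid_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.SyntheticConfig(ny=0, nx=4)

    def test_too_short_span_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.SyntheticConfig(start_year=2000, end_year=2005)

    def test_out_of_range_coupling_magnitude_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.SyntheticConfig(b_start=1.5)

    def test_mismatched_planted_field_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.SyntheticConfig(ny=4, nx=4, coupling_k=np.ones((3, 3), int))


class TestMakeDomain:
    def test_gradient_row_spans_all_aridity_classes(self):
        cfg = syn.SyntheticConfig(ny=1, nx=4, aridity_mode="gradient",
                                  aridity_range=(0.1, 0.8), mask_fraction=0.0)
        ai, valid = syn.make_domain(cfg)
        classes = [classify_aridity(v) for v in ai.values[0]]
        assert classes == ["arid", "semi-arid", "sub-humid", "humid"]

    def test_zero_mask_fraction_keeps_all_cells(self):
        cfg = syn.SyntheticConfig(ny=5, nx=5, mask_fraction=0.0)
        _, valid = syn.make_domain(cfg)
        assert valid.all()

    def test_deterministic_under_seed(self):
        cfg = syn.SyntheticConfig(ny=5, nx=5, seed=3, aridity_mode="random")
        a1, v1 = syn.make_domain(cfg)
        a2, v2 = syn.make_domain(cfg)
        assert np.array_equal(a1.values, a2.values)
        assert np.array_equal(v1, v2)


class TestSimulateClimate:
    def test_support_constraints(self, small_dataset):
        assert np.nanmin(small_dataset.precip.values) >= 0
        assert np.nanmin(small_dataset.pet.values) > 0
        assert np.all(np.diff(small_dataset.co2) > 0)

    def test_shared_monthly_calendar(self, small_dataset):
        for cube in (small_dataset.pet, small_dataset.temp, small_dataset.rad):
            assert cube["time"].equals(small_dataset.precip["time"])

    def test_stationary_monthly_means_without_trends(self):
        # two disjoint decades should differ only by sampling noise
        cfg = syn.SyntheticConfig(ny=8, nx=8, seed=5, temp_trend=0.0, rad_trend=0.0,
                                  mask_fraction=0.0)
        dom = syn.make_domain(cfg)
        truth = syn.plant_truth(cfg, dom[1])
        _, _, temp, _, _, _ = syn.simulate_climate(cfg, dom, truth)
        years = temp["time"].dt.year.values
        months = temp["time"].dt.month.values
        from scipy import stats

        n_ok = 0
        n_tests = 0
        for j in (1, 7):
            a = temp.values[(months == j) & (years <= 1991)]
            b = temp.values[(months == j) & (years >= 2006)]
            _, pvals = stats.ttest_ind(a, b, axis=0)
            n_ok += int((pvals > 0.01).sum())
            n_tests += pvals.size
        assert n_ok / n_tests >= 0.95


class TestSimulateVegetation:
    def test_noise_free_deficit_cell_has_perfect_rank_correlation(self):
        cfg = syn.SyntheticConfig(ny=2, nx=2, seed=1, regime="deficit", noise_sd=0.0,
                                  b_start=0.8, b_end=0.8, mask_fraction=0.0,
                                  coupling_fluct=0.0)
        ds = syn.generate_dataset(cfg, timescales=[3, 9])
        anom = monthly_zscore(ds.vegetation)
        cm = full_period_coupling(anom, ds.spei[3])
        assert np.all(cm.rho > 0.999)

    def test_surplus_cells_anticorrelate(self):
        cfg = syn.SyntheticConfig(ny=3, nx=3, seed=2, regime="surplus", noise_sd=0.3,
                                  mask_fraction=0.0, coupling_fluct=0.0)
        ds = syn.generate_dataset(cfg, timescales=[3, 9])
        anom = monthly_zscore(ds.vegetation)
        cm = full_period_coupling(anom, ds.spei[3])
        assert np.all(cm.rho < 0)

    def test_missing_planted_timescale_raises(self):
        cfg = syn.SyntheticConfig(ny=2, nx=2, seed=1, regime="deficit", coupling_k=5)
        dom = syn.make_domain(cfg)
        truth = syn.plant_truth(cfg, dom[1])
        fam = syn.make_independent_index_family(cfg, timescales=[1, 3])
        with pytest.raises(syn.ConfigurationError, match="5"):
            syn.simulate_vegetation(cfg, fam, truth)

    def test_bit_identical_under_same_seed(self):
        cfg = syn.SyntheticConfig(ny=4, nx=4, seed=9)
        d1 = syn.generate_dataset(cfg, timescales=[3, 9])
        d2 = syn.generate_dataset(cfg, timescales=[3, 9])
        assert np.array_equal(d1.vegetation.values, d2.vegetation.values, equal_nan=True)
        assert np.array_equal(d1.precip.values, d2.precip.values, equal_nan=True)


class TestTruth:
    def test_round_trips_through_json(self):
        cfg = syn.SyntheticConfig(ny=4, nx=5, seed=2)
        dom = syn.make_domain(cfg)
        truth = syn.plant_truth(cfg, dom[1])
        back = syn.SyntheticTruth.from_json(truth.to_json())
        for field in ("regime", "coupling_k", "drift_sign", "dominant_driver", "valid"):
            assert np.array_equal(getattr(truth, field), getattr(back, field))
        assert back.seed == truth.seed

    def test_mixed_regime_fractions_roughly_honoured(self):
        cfg = syn.SyntheticConfig(ny=30, nx=30, seed=4, deficit_frac=0.5, surplus_frac=0.3)
        dom = syn.make_domain(cfg)
        truth = syn.plant_truth(cfg, dom[1])
        frac_def = np.mean(truth.regime == syn.REGIME_CODES["deficit"])
        assert frac_def == pytest.approx(0.5, abs=0.06)
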