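import itertools

import numpy as np
import pytest

from vegcoupling import attribution as att
from vegcoupling.coupling import spearman


class TestScreenModel:
    def test_perfect_fit_has_tiny_p(self, rng):
        X = rng.standard_normal((30, 4))
        y = 2.0 * X[:, 1]
        p, r2 = att.screen_model(y, X)
        assert p < 1e-6
        assert r2 == pytest.approx(1.0)

    def test_constant_response_invalid(self, rng):
        X = rng.standard_normal((30, 4))
        p, r2 = att.screen_model(np.ones(30), X)
        assert np.isnan(p) and np.isnan(r2)

    def test_null_rejection_rate_near_alpha(self, rng):
        hits = 0
        reps = 2000
        for _ in range(reps):
            y = rng.standard_normal(30)
            X = rng.standard_normal((30, 4))
            p, _ = att.screen_model(y, X)
            hits += p < 0.05
        assert 0.03 < hits / reps < 0.07


class TestPartialSpearman:
    def test_empty_conditioning_set_equals_plain_spearman(self, rng):
        y = rng.standard_normal(40)
        x = rng.standard_normal((40, 1))
        partial = att.partial_spearman(y, x, 0, method="residual")
        plain, _, _ = spearman(y, x[:, 0])
        assert partial == pytest.approx(plain, abs=1e-10)

    @pytest.mark.parametrize("n", [20, 30, 50])
    def test_dual_algorithms_agree(self, rng, n):
        for _ in range(20):
            y = rng.standard_normal(n)
            X = rng.standard_normal((n, 4))
            for j in range(4):
                a = att.partial_spearman(y, X, j, method="residual")
                b = att.partial_spearman(y, X, j, method="precision")
                assert a == pytest.approx(b, abs=1e-10)

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        y = rng.standard_normal(40)
        X = rng.standard_normal((40, 3))
        df = pd.DataFrame({"y": y, "x0": X[:, 0], "x1": X[:, 1], "x2": X[:, 2]})
        ref = pingouin.partial_corr(
            df, x="x0", y="y", covar=["x1", "x2"], method="spearman"
        )["r"].iloc[0]
        ours = att.partial_spearman(y, X, 0)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_single_driver_construction(self, rng):
        Z = rng.standard_normal((60, 4))
        Q, _ = np.linalg.qr(Z - Z.mean(axis=0))
        y = Q[:, 0]  # noise-free function of driver 0, orthogonal others
        # y duplicates driver 0 in rank space: the precision route flags the
        # singular correlation matrix, the residual route resolves it to 1
        partials = [att.partial_spearman(y, Q, j, method="residual") for j in range(4)]
        assert abs(partials[0]) > 0.95
        assert all(abs(p) < 0.3 for p in partials[1:])
        assert np.isnan(att.partial_spearman(y, Q, 0, method="precision"))

    def test_collinear_conditioning_set_invalid(self, rng):
        y = rng.standard_normal(30)
        x = rng.standard_normal(30)
        X = np.column_stack([x, x, rng.standard_normal(30)])
        assert np.isnan(att.partial_spearman(y, X, 2, method="precision"))


class TestDominantFactor:
    def test_largest_absolute_partial_wins(self):
        name, tie = att.dominant_factor([0.6, -0.7, 0.1, 0.2], model_p=0.01)
        assert name == att.DRIVERS[1]
        assert not tie

    def test_insignificant_model_gives_none(self):
        name, _ = att.dominant_factor([0.6, -0.7, 0.1, 0.2], model_p=0.5)
        assert name == "none"

    def test_exact_tie_breaks_by_fixed_order_and_flags(self):
        name, tie = att.dominant_factor([0.5, -0.5, 0.1, 0.0], model_p=0.01)
        assert name == att.DRIVERS[0]
        assert tie


class TestLmgImportance:
    def test_single_predictor_share_equals_r2(self, rng):
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 1))
        shares, r2 = att.lmg_importance(y, X)
        assert shares[0] == pytest.approx(r2, abs=1e-12)

    def test_shares_sum_to_r2_and_nonnegative(self, rng):
        for _ in range(20):
            y = rng.standard_normal(30)
            X = rng.standard_normal((30, 4))
            shares, r2 = att.lmg_importance(y, X)
            assert shares.sum() == pytest.approx(r2, abs=1e-10)
            assert np.all(shares >= -1e-12)

    def test_orthogonal_predictors_give_squared_simple_correlations(self, rng):
        Z = rng.standard_normal((64, 4))
        Q, _ = np.linalg.qr(Z - Z.mean(axis=0))
        y = Q @ np.array([0.8, 0.4, -0.2, 0.1]) + 0.1 * rng.standard_normal(64)
        shares, _ = att.lmg_importance(y, Q)
        simple = np.array([np.corrcoef(y, Q[:, j])[0, 1] ** 2 for j in range(4)])
        assert np.allclose(shares, simple, atol=1e-10)

    def test_matches_explicit_all_orderings_enumeration(self, rng):
        y = rng.standard_normal(25)
        X = rng.standard_normal((25, 4))
        shares, r2 = att.lmg_importance(y, X)

        def r2_of(cols):
            if not cols:
                return 0.0
            Xc = X[:, list(cols)] - X[:, list(cols)].mean(axis=0)
            yc = y - y.mean()
            coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
            resid = yc - Xc @ coef
            return 1.0 - (resid @ resid) / (yc @ yc)

        oracle = np.zeros(4)
        orders = list(itertools.permutations(range(4)))
        for order in orders:
            for pos, j in enumerate(order):
                oracle[j] += r2_of(order[: pos + 1]) - r2_of(order[:pos])
        oracle /= len(orders)
        assert np.allclose(shares, oracle, atol=1e-10)
        assert r2 == pytest.approx(r2_of((0, 1, 2, 3)), abs=1e-12)


class TestDominantAreaSummary:
    def test_uniform_dominance_gives_unit_fraction(self):
        from vegcoupling.coupling import CLASS_CODES

        amap = att.AttributionMap(
            model_p=np.full((3, 3), 0.01),
            partial=np.zeros((4, 3, 3)),
            dominant=np.full((3, 3), att.DRIVER_CODES["precipitation"], dtype=np.uint8),
            tie=np.zeros((3, 3), bool),
            lmg=np.zeros((4, 3, 3)),
            r2=np.zeros((3, 3)),
            alpha=0.05,
        )
        cls = np.full((3, 3), CLASS_CODES["deficit"], dtype=np.uint8)
        summary = att.dominant_area_summary(amap, cls)
        assert summary["deficit"]["precipitation"] == 1.0
        assert summary["surplus"]["precipitation"] is None  # empty regime
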