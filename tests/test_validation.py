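import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micelle_qspr.mlr import fit_mlr, predict
from micelle_qspr.validation import (
    loo_cv,
    r2_pred,
    r_squared,
    rm2_metrics,
    rmse,
    validate_model,
    y_randomization,
)

from conftest import make_table


class TestRSquared:
    def test_perfect_and_null(self, rng):
        y = rng.standard_normal(10)
        assert r_squared(y, y, float(y.mean())) == pytest.approx(1.0)
        ref = np.full_like(y, y.mean())
        assert r_squared(y, ref, float(y.mean())) == pytest.approx(0.0)

    def test_shift_invariance(self, rng):
        y = rng.standard_normal(15)
        p = y + 0.1 * rng.standard_normal(15)
        base = r_squared(y, p, float(y.mean()))
        shifted = r_squared(y + 7, p + 7, float(y.mean()) + 7)
        assert shifted == pytest.approx(base)

    def test_constant_observations_rejected(self):
        with pytest.raises(ZeroDivisionError):
            r_squared([1.0, 1.0, 1.0], [1.0, 1.1, 0.9], 1.0)


class TestRmse:
    def test_values(self):
        assert rmse([1, 2], [1, 2]) == 0.0
        # residuals 3 and 4 -> sqrt((9+16)/2)
        assert rmse([3, 4], [0, 0]) == pytest.approx(np.sqrt(12.5))

    def test_scale_and_shift(self, rng):
        y = rng.standard_normal(20)
        p = y + rng.standard_normal(20)
        base = rmse(y, p)
        assert rmse(y + 3, p + 3) == pytest.approx(base)
        assert rmse(5 * y, 5 * p) == pytest.approx(5 * base)


class TestLooCv:
    def test_exact_linear_data(self):
        x = np.arange(10, dtype=float)
        table = make_table(x.reshape(-1, 1), response=2 * x - 1,
                           names=["x"], scale="ln")
        r2cv, pred = loo_cv(table, ["x"])
        assert r2cv == pytest.approx(1.0)
        np.testing.assert_allclose(pred, 2 * x - 1, atol=1e-10)

    def test_equals_brute_force_refits(self, rng):
        """Hat-matrix shortcut must equal the naive n-refit oracle exactly."""
        X = rng.standard_normal((18, 4))
        y = X @ [1.0, -1.0, 0.5, 0.0] + rng.standard_normal(18)
        table = make_table(X, response=y, scale="ln")
        subset = table.descriptor_names[:3]
        _, fast = loo_cv(table, subset)
        naive = np.empty(18)
        for i in range(18):
            keep = [j for j in range(18) if j != i]
            sub = table.select_samples([table.sample_ids[j] for j in keep])
            model = fit_mlr(sub, subset)
            naive[i] = predict(model, table)[i]
        np.testing.assert_allclose(fast, naive, rtol=1e-10, atol=1e-10)

    def test_r2cv_below_r2(self, rng):
        X = rng.standard_normal((20, 3))
        y = X[:, 0] + rng.standard_normal(20)
        table = make_table(X, response=y, scale="ln")
        model = fit_mlr(table, table.descriptor_names)
        r2 = r_squared(y, predict(model, table), float(y.mean()))
        r2cv, _ = loo_cv(table, table.descriptor_names)
        assert r2cv <= r2 + 1e-12


class TestR2Pred:
    def test_perfect_predictions(self, rng):
        y = rng.standard_normal(6)
        assert r2_pred(y, y, 0.3) == pytest.approx(1.0)

    def test_training_mean_reference(self, rng):
        y = rng.standard_normal(6)
        mean = 0.42
        assert r2_pred(y, np.full(6, mean), mean) == pytest.approx(0.0)


class TestRm2:
    def test_perfect(self, rng):
        y = rng.standard_normal(8)
        rm2, rm2p, bar, delta = rm2_metrics(y, y)
        assert rm2 == pytest.approx(1.0)
        assert rm2p == pytest.approx(1.0)
        assert delta == pytest.approx(0.0)

    def test_frozen_oracle_values(self):
        # computed with an independent script doing explicit through-origin
        # regressions of observed-on-predicted and predicted-on-observed
        rm2, rm2p, bar, delta = rm2_metrics([1, 2, 3], [1.1, 1.9, 3.2])
        assert rm2 == pytest.approx(0.9497678, abs=1e-6)
        assert rm2p == pytest.approx(0.9671654, abs=1e-6)
        assert bar == pytest.approx(0.9584666, abs=1e-6)
        assert delta == pytest.approx(0.0173976, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_bounded_by_r2(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(10)
        p = 0.8 * y + 0.3 * rng.standard_normal(10) + rng.uniform(-1, 1)
        rm2, rm2p, _, _ = rm2_metrics(y, p)
        r2 = np.corrcoef(y, p)[0, 1] ** 2
        assert rm2 <= r2 + 1e-12
        assert rm2p <= r2 + 1e-12

    def test_equality_iff_r0_matches(self, rng):
        # through-origin fit coincides with the Pearson fit when the data lie
        # on a line through the origin
        y = np.array([1.0, 2.0, 3.0, 4.0])
        p = 2.0 * y
        rm2, rm2p, _, _ = rm2_metrics(y, p)
        r2 = np.corrcoef(y, p)[0, 1] ** 2
        assert rm2 == pytest.approx(r2)
        assert rm2p == pytest.approx(r2)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            rm2_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestYRandomization:
    def test_identity_permutation_reproduces_original_fit(self, rng):
        X = rng.standard_normal((20, 4))
        y = X[:, 0] - X[:, 2] + 0.3 * rng.standard_normal(20)
        table = make_table(X, response=y, scale="ln")
        subset = table.descriptor_names
        model = fit_mlr(table, subset)
        r2_orig = r_squared(y, predict(model, table), float(y.mean()))
        mean_r2, mean_r2cv, _ = y_randomization(
            table, subset, permutations=[np.arange(20)]
        )
        assert mean_r2 == pytest.approx(r2_orig, rel=1e-10)

    def test_null_mean_matches_closed_form(self, rng):
        """Mean R2 of refits on exchangeable noise converges to p/(n-1)."""
        n, p = 22, 5
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        table = make_table(X, response=y, scale="ln")
        mean_r2, mean_r2cv, reliable = y_randomization(
            table, table.descriptor_names, iterations=5000, seed=123
        )
        assert mean_r2 == pytest.approx(p / (n - 1), abs=0.03)
        assert mean_r2cv < mean_r2
        assert reliable

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((15, 3))
        table = make_table(X, response=rng.standard_normal(15), scale="ln")
        a = y_randomization(table, table.descriptor_names, iterations=50, seed=9)
        b = y_randomization(table, table.descriptor_names, iterations=50, seed=9)
        assert a == b


class TestValidateModel:
    def test_full_battery_consistency(self, rng):
        X = rng.standard_normal((30, 6))
        y = X[:, 0] + 0.5 * X[:, 1] + 0.1 * rng.standard_normal(30)
        table = make_table(X, response=y, scale="ln")
        train = table.select_samples(table.sample_ids[:22])
        test = table.select_samples(table.sample_ids[22:])
        report = validate_model(train, test, table.descriptor_names[:2],
                                y_rand_iterations=100, seed=4)
        assert report.rm2_bar == pytest.approx((report.rm2 + report.rm2_prime) / 2)
        assert report.delta_rm2 == pytest.approx(abs(report.rm2 - report.rm2_prime))
        assert report.r2cv <= report.r2 + 1e-12
        assert report.r2 <= 1 and report.r2_pred <= 1
        assert report.verdicts["y_randomization_reliable"]
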