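import numpy as np
import pytest

import composkern as ck
from composkern.errors import InvalidInputError, ZeroHandlingError
from composkern.simulate import (
    LogContrastModel,
    block_dgp,
    example_logcontrast,
    logcontrast_response,
    sample_logistic_normal,
    zero_inflate,
)
from composkern.weights import Partition


class TestLogContrastModel:
    def test_beta_must_sum_to_zero(self):
        with pytest.raises(InvalidInputError):
            LogContrastModel(np.array([1.0, 0.5]))

    def test_evaluation(self):
        m = LogContrastModel(np.array([1.0, -1.0]))
        assert m(np.array([[0.8, 0.2]]))[0] == pytest.approx(np.log(4.0))

    def test_zeros_rejected(self):
        m = LogContrastModel(np.array([1.0, -1.0]))
        with pytest.raises(ZeroHandlingError):
            m(np.array([[1.0, 0.0]]))


class TestSampleLogisticNormal:
    def test_rows_on_simplex_strictly_positive(self):
        X = sample_logistic_normal(50, 6, seed=0)
        assert np.all(X.values > 0)
        np.testing.assert_allclose(X.values.sum(axis=1), 1.0, atol=1e-9)

    def test_degenerate_sigma(self):
        mu = np.array([1.0, 0.0, -1.0])
        X = sample_logistic_normal(5, 3, mu=mu, sigma=np.zeros((3, 3)), seed=1)
        expected = np.exp(mu) / np.exp(mu).sum()
        np.testing.assert_allclose(X.values, np.tile(expected, (5, 1)), atol=1e-12)

    def test_seed_reproducibility(self):
        X1 = sample_logistic_normal(20, 4, seed=9)
        X2 = sample_logistic_normal(20, 4, seed=9)
        np.testing.assert_array_equal(X1.values, X2.values)
        X3 = sample_logistic_normal(20, 4, seed=10)
        assert not np.array_equal(X1.values, X3.values)

    def test_non_psd_sigma_rejected(self):
        sigma = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(InvalidInputError):
            sample_logistic_normal(5, 2, sigma=sigma)


class TestZeroInflate:
    def test_depth_one_gives_vertices(self):
        X = sample_logistic_normal(20, 5, seed=2)
        Z = zero_inflate(X, depth=1, seed=3)
        assert np.all(np.sort(Z.values, axis=1)[:, :-1] == 0)
        assert np.all(np.sort(Z.values, axis=1)[:, -1] == 1)

    def test_large_depth_recovers_input(self):
        X = sample_logistic_normal(10, 4, seed=4)
        Z = zero_inflate(X, depth=10 ** 6, seed=5)
        assert np.mean(np.abs(Z.values - X.values)) < 1e-3

    def test_zero_probability_matches_binomial(self):
        # component at rel. abundance 0.01, depth 100: P(zero) ~ 0.99^100
        p_small = 0.01
        V = np.tile([p_small, (1 - p_small) / 2, (1 - p_small) / 2], (4000, 1))
        Z = zero_inflate(ck.CompositionTable(V), depth=100, seed=6)
        frac_zero = np.mean(Z.values[:, 0] == 0)
        assert frac_zero == pytest.approx((1 - p_small) ** 100, abs=0.03)

    def test_rows_remain_on_simplex(self):
        X = sample_logistic_normal(30, 6, seed=7)
        Z = zero_inflate(X, depth=50, seed=8)
        np.testing.assert_allclose(Z.values.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_depth(self):
        X = sample_logistic_normal(5, 3, seed=0)
        with pytest.raises(InvalidInputError):
            zero_inflate(X, depth=0)


class TestLogcontrastResponse:
    def test_zero_beta_zero_noise(self):
        X = sample_logistic_normal(10, 3, seed=1)
        y = logcontrast_response(X, LogContrastModel(np.zeros(3), 0.0), seed=2)
        np.testing.assert_allclose(y, 0.0)

    def test_example_beta_cfi(self):
        """CFI of the true generating function equals beta on any table."""
        X = sample_logistic_normal(60, 4, seed=3)
        model = example_logcontrast(4)
        res = ck.cfi(lambda rows: model(np.atleast_2d(rows)), X)
        np.testing.assert_allclose(res.cfi, model.beta, atol=1e-6)

    def test_psi_doubling_changes_y_by_beta_log2(self):
        """Multiplying component 1 by 2 changes the noiseless response by
        beta_1 * log(2) exactly (zero-sum beta cancels the closure)."""
        X = sample_logistic_normal(10, 4, seed=4)
        model = LogContrastModel(np.array([2.0, -1.0, -1.0, 0.0]), 0.0)
        y0 = model(X)
        from composkern.simplex import psi_perturb_rows
        y1 = model(ck.CompositionTable(psi_perturb_rows(X.values, 0, 2.0)))
        np.testing.assert_allclose(y1 - y0, 2.0 * np.log(2.0), atol=1e-12)

    def test_noise_sd(self):
        X = sample_logistic_normal(4000, 3, seed=5)
        y = logcontrast_response(X, LogContrastModel(np.zeros(3), 2.0), seed=6)
        assert np.std(y) == pytest.approx(2.0, rel=0.1)

    def test_zeros_rejected(self):
        V = np.array([[0.5, 0.5, 0.0], [0.2, 0.4, 0.4]])
        with pytest.raises(ZeroHandlingError):
            logcontrast_response(ck.CompositionTable(V),
                                 LogContrastModel(np.zeros(3)), seed=0)


class TestBlockDgp:
    @pytest.fixture
    def setup(self):
        p = 12
        part = Partition([[0, 1, 2, 3], [4, 5, 6, 7], [8, 9, 10, 11]])
        X = sample_logistic_normal(50, p, seed=11)
        return X, part

    def test_dgp1_constant_within_blocks(self, setup):
        X, part = setup
        ds = block_dgp(X, part, 2.0, -1.0, variant="dgp1", seed=1)
        beta = ds.truth.beta
        assert np.ptp(beta[[0, 1, 2, 3]]) == 0
        assert np.ptp(beta[[4, 5, 6, 7]]) == 0
        assert abs(beta.sum()) < 1e-9

    def test_dgp2_block_sums_zero_before_recentering(self, setup):
        X, part = setup
        ds = block_dgp(X, part, 2.0, -1.0, variant="dgp2", seed=1)
        # even designated blocks: the +/- split sums to zero per block,
        # so no recentering happened and block sums are exactly zero
        beta = ds.truth.beta
        assert abs(beta[[0, 1, 2, 3]].sum()) < 1e-12
        assert abs(beta[[4, 5, 6, 7]].sum()) < 1e-12

    def test_dgp2_small_block_rejected(self):
        X = sample_logistic_normal(10, 4, seed=0)
        part = Partition([[0], [1], [2, 3]])
        with pytest.raises(InvalidInputError):
            block_dgp(X, part, 1.0, 1.0, variant="dgp2")

    def test_deterministic(self, setup):
        X, part = setup
        d1 = block_dgp(X, part, 2.0, -1.0, variant="dgp1", seed=5)
        d2 = block_dgp(X, part, 2.0, -1.0, variant="dgp1", seed=5)
        np.testing.assert_array_equal(d1.y, d2.y)

    def test_weighting_helps_dgp1_hurts_dgp2(self):
        """Matching block weights improve test RMSE under the
        block-constant DGP and hurt under the +/- split DGP
        (mean over 20 seeds)."""
        p = 30
        blocks = [list(range(0, 8)), list(range(8, 16)), list(range(16, 30))]
        part = Partition(blocks)
        W = ck.partition_weights(part, p)
        base = ck.KernelSpec("aitchison", c=1e-3)
        wspec = ck.apply_weights(base, W)
        cfg = ck.CVConfig(n_outer=2, n_inner=5, seed=0)

        def rmse(variant):
            diffs = []
            for seed in range(20):
                Xtr = sample_logistic_normal(100, p, seed=seed)
                Xte = sample_logistic_normal(100, p, seed=seed + 1000)
                dtr = block_dgp(Xtr, part, 2.0, -1.5, variant=variant,
                                noise_sd=0.5, seed=seed)
                dte = block_dgp(Xte, part, 2.0, -1.5, variant=variant,
                                noise_sd=0.5, seed=seed + 2000)
                out = {}
                for name, spec in (("unw", base), ("wgt", wspec)):
                    _, m = ck.refit_lambda(Xtr, dtr.y, spec, cfg)
                    pred = ck.predict(m, ck.CompositionTable(
                        Xte.values, component_labels=Xtr.component_labels))
                    out[name] = np.sqrt(np.mean((pred - dte.y) ** 2))
                diffs.append(out)
            return (np.mean([d["unw"] for d in diffs]),
                    np.mean([d["wgt"] for d in diffs]))

        unw1, wgt1 = rmse("dgp1")
        assert wgt1 < unw1  # informative weights help
        unw2, wgt2 = rmse("dgp2")
        assert wgt2 > unw2  # adversarial weights hurt
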