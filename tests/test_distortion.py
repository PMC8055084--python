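"""Distortion-model family: scales, LLO/BLO forward models, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freqtrack import (BLO_SPEC, LLO_SPEC, MODEL_REGISTRY, MODEL_SPACE,
                       BLOParams, LLOParams, inverse_scale_transform,
                       kernel_smooth, llo_median, neg_log_likelihood,
                       sampling_variance, scale_transform)
from freqtrack.distortion import (blo_median, get_model, llo_params_to_model,
                                  model_median, llo_sample)


class TestScales:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(p=st.floats(0.001, 0.999),
           scale=st.sampled_from(["logodds", "prelec", "linear"]))
    def test_round_trip(self, p, scale):
        assert inverse_scale_transform(scale_transform(p, scale), scale) == \
            pytest.approx(p, abs=1e-12)

    def test_known_values(self):
        assert scale_transform(0.5, "logodds") == pytest.approx(0.0)
        assert scale_transform(0.9, "logodds") == pytest.approx(np.log(9))
        assert scale_transform(np.exp(-1), "prelec") == pytest.approx(0.0)

    @pytest.mark.parametrize("scale", ["logodds", "prelec"])
    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_domain_errors(self, scale, p):
        with pytest.raises(ValueError):
            scale_transform(p, scale)

    def test_unknown_scale(self):
        with pytest.raises(ValueError):
            scale_transform(0.5, "sqrt")


class TestLLO:
    def test_identity_when_gamma_one(self):
        params = LLOParams(gamma=1.0, p0=0.7, sigma_lambda=0.1)
        assert llo_median(0.3, params) == pytest.approx(0.3)

    def test_crossover(self):
        params = LLOParams(gamma=0.6, p0=0.4, sigma_lambda=0.1)
        assert llo_median(0.4, params) == pytest.approx(0.4)

    def test_inverted_s_overestimates_small_p(self):
        # sigma(0.6 * logit(0.1)) computed directly
        params = LLOParams(gamma=0.6, p0=0.5, sigma_lambda=0.1)
        assert llo_median(0.1, params) == pytest.approx(0.21110, abs=1e-4)
        assert llo_median(0.1, params) > 0.1  # overestimation of small p

    def test_monotone_in_p(self):
        params = LLOParams(gamma=0.6, p0=0.4, sigma_lambda=0.1)
        grid = np.linspace(0.01, 0.99, 99)
        med = llo_median(grid, params)
        assert np.all(np.diff(med) > 0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LLOParams(gamma=-1, p0=0.5, sigma_lambda=0.1)
        with pytest.raises(ValueError):
            LLOParams(gamma=1, p0=1.5, sigma_lambda=0.1)


class TestSamplingVariance:
    def test_zero_at_certainty(self):
        assert sampling_variance(0.0, 50, a=0.42, b=1.91) == 0.0
        assert sampling_variance(1.0, 50, a=0.42, b=1.91) == 0.0

    def test_clamped_when_sample_exceeds_population(self):
        # ns = 5 + 10^1 = 15 > N = 10 -> negative raw value clamped
        assert sampling_variance(0.5, 10, a=1.0, b=5.0) == 0.0

    def test_median_subject_value(self):
        # direct evaluation at the reported median sample-size law
        v = sampling_variance(0.5, 20, a=0.42, b=1.91)
        assert v == pytest.approx(0.035314, abs=1e-5)

    def test_unimodal_in_numerosity(self):
        N = np.arange(10, 901)
        v = sampling_variance(0.5, N, a=0.42, b=1.91)
        peak = N[np.argmax(v)]
        assert 15 <= peak <= 30  # rises from N=10 to a max near 20...
        assert v[0] < v.max()
        assert np.all(np.diff(v[N >= 30]) < 0)  # ...then decreases to 900

    def test_degenerate_n(self):
        assert sampling_variance(0.5, 1, a=0.42, b=1.91) == 0.0
        with pytest.raises(ValueError):
            sampling_variance(0.5, 0, a=0.42, b=1.91)


class TestBLO:
    PARAMS = BLOParams(delta_minus=-1.5, delta_plus=1.5, a=0.42, b=1.91,
                       eta=0.9, lambda0=0.2, alpha=20.0, sigma_lambda=0.3)

    def test_truncation_flattens_extremes(self):
        # all p whose log-odds fall below delta_minus share the truncated
        # representation, hence (absent variance compensation, alpha = 0)
        # the same response distribution
        params = BLOParams(delta_minus=-1.5, delta_plus=1.5, a=0.42, b=1.91,
                           eta=0.9, lambda0=0.2, alpha=0.0, sigma_lambda=0.3)
        lo = inverse_scale_transform(-1.5, "logodds")
        p_below = np.array([0.05, 0.10, 0.15])
        assert np.all(scale_transform(p_below, "logodds") < -1.5)
        med = blo_median(p_below, 50, params)
        assert np.allclose(med, med[0])
        assert blo_median(lo * 1.5, 50, params) > med[0]

    def test_alpha_zero_removes_compensation(self):
        params = BLOParams(delta_minus=-4, delta_plus=4, a=0.42, b=1.91,
                           eta=0.9, lambda0=1.0, alpha=0.0, sigma_lambda=0.3)
        # omega = 1: anchor has no influence, median = sigma(eta * logit(p))
        expect = inverse_scale_transform(0.9 * scale_transform(0.3, "logodds"),
                                         "logodds")
        assert blo_median(0.3, 50, params) == pytest.approx(expect)

    def test_median_nondecreasing_in_p(self):
        grid = np.linspace(0.02, 0.98, 97)
        med = blo_median(grid, 50, self.PARAMS)
        assert np.all(np.diff(med) >= -1e-12)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            BLOParams(delta_minus=2, delta_plus=-2, a=0.4, b=1, eta=1,
                      lambda0=0, alpha=1, sigma_lambda=0.3)


class TestModelSpace:
    def test_enumerates_18_distinct_models(self):
        assert len(MODEL_SPACE) == 18
        assert len({m.key for m in MODEL_SPACE}) == 18

    @pytest.mark.parametrize("key,k", [
        ("logodds-bounded-vnspow", 8),   # full BLO
        ("logodds-bounded-vnsconst", 7),
        ("logodds-bounded-vconst", 5),
        ("logodds-free-vnspow", 6),
        ("logodds-free-vconst", 3),      # LLO
        ("prelec-free-vconst", 3),       # two-parameter Prelec
    ])
    def test_free_parameter_counts(self, key, k):
        assert MODEL_REGISTRY[key].n_free_params == k

    def test_llo_nesting_identical_likelihood(self, rng):
        """The bounds-free log-odds constant-variance cell evaluates to the
        same likelihood as LLO under the parameter mapping, on any data."""
        llo = LLOParams(gamma=0.65, p0=0.4, sigma_lambda=0.3)
        p = rng.uniform(0.1, 0.9, 100)
        data = {"p": p, "N": np.full(100, 50.0), "pi": llo_sample(p, llo, rng)}
        mapped = llo_params_to_model(llo)
        nll_cell = neg_log_likelihood(data, LLO_SPEC, mapped)
        lam = llo.gamma * scale_transform(p, "logodds") \
            + (1 - llo.gamma) * scale_transform(llo.p0, "logodds")
        med = inverse_scale_transform(lam, "logodds")
        assert np.allclose(model_median(p, 50, LLO_SPEC, mapped), med)
        # direct LLO likelihood oracle
        from freqtrack.distortion import clip_responses, _log_jacobian
        z = scale_transform(clip_responses(data["pi"]), "logodds")
        sig = llo.sigma_lambda
        nll_direct = (0.5 * len(p) * np.log(2 * np.pi * sig ** 2)
                      + np.sum((z - lam) ** 2) / (2 * sig ** 2)
                      - np.sum(_log_jacobian(clip_responses(data["pi"]),
                                             "logodds")))
        assert nll_cell == pytest.approx(nll_direct, abs=1e-9)


class TestLikelihood:
    def test_value_at_mode(self):
        data = {"p": [0.3], "N": [50], "pi": [0.3]}
        spec = LLO_SPEC
        params = {"eta": 1.0, "lambda0": 0.0, "sigma_lambda": 0.5}
        nll = neg_log_likelihood(data, spec, params, include_jacobian=False)
        assert nll == pytest.approx(np.log(0.5 * np.sqrt(2 * np.pi)))

    def test_doubling_sigma_with_zero_residuals(self):
        p = np.linspace(0.2, 0.8, 10)
        data = {"p": p, "N": np.full(10, 50), "pi": p}
        base = {"eta": 1.0, "lambda0": 0.0, "sigma_lambda": 0.4}
        double = dict(base, sigma_lambda=0.8)
        n1 = neg_log_likelihood(data, LLO_SPEC, base)
        n2 = neg_log_likelihood(data, LLO_SPEC, double)
        assert n2 - n1 == pytest.approx(10 * np.log(2))

    def test_truth_beats_wrong_slope(self, rng):
        llo = LLOParams(gamma=0.6, p0=0.5, sigma_lambda=0.3)
        p = rng.uniform(0.1, 0.9, 100)
        data = {"p": p, "N": np.full(100, 50), "pi": llo_sample(p, llo, rng)}
        nll_truth = neg_log_likelihood(data, LLO_SPEC, llo_params_to_model(llo))
        wrong = llo_params_to_model(LLOParams(gamma=1.0, p0=0.5,
                                              sigma_lambda=0.3))
        assert nll_truth < neg_log_likelihood(data, LLO_SPEC, wrong)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            neg_log_likelihood({"p": [], "N": [], "pi": []}, LLO_SPEC,
                               {"eta": 1, "lambda0": 0, "sigma_lambda": 0.3})


class TestKernelSmooth:
    def test_constant_observations(self):
        out = kernel_smooth([0.2, 0.5, 0.8], [0.1, 0.4, 0.9], [2.0, 2.0, 2.0])
        assert np.allclose(out, 2.0)

    def test_infinite_bandwidth_gives_mean(self):
        y = [1.0, 2.0, 6.0]
        out = kernel_smooth([0.3], [0.1, 0.5, 0.9], y, h=1e6)
        assert out == pytest.approx(np.mean(y))

    def test_two_point_closed_form(self):
        # at x=0.2 the weight of the far point is exp(-0.5*(0.6/0.03)^2)
        out = kernel_smooth(0.2, [0.2, 0.8], [0.0, 1.0], h=0.03)
        assert out == pytest.approx(0.0, abs=1e-80)

    def test_dead_query_flagged(self):
        with pytest.warns(RuntimeWarning):
            out = kernel_smooth([50.0], [0.0], [1.0], h=0.01)
        assert np.isnan(out[0])

    def test_bad_bandwidth(self):
        with pytest.raises(ValueError):
            kernel_smooth([0.5], [0.5], [1.0], h=0.0)
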