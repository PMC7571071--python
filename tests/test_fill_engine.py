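"""Recursive window-push filling and the three bidirectional fusions."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemfill import (
    FillResult,
    FillTrainConfig,
    GapSpec,
    MinMaxTransform,
    Series,
    combine_decreasing,
    combine_equal,
    combine_segmented,
    decreasing_weight_schedule,
    fill_all_schemes,
    fill_bidirectional,
    fill_directional,
    mask_gap,
    stacked_architecture,
)
from conftest import pure_sinusoid


class OracleModel:
    """One-step predictor defined by a function of the current window."""

    def __init__(self, fn, window_length, transform=None):
        self.architecture = SimpleNamespace(
            window_length=window_length, input_features=1
        )
        self.transform = transform
        self._fn = fn

    def predict(self, windows):
        return np.array([self._fn(np.asarray(w)[:, 0]) for w in windows])


def sinusoid_oracle(base, period=144):
    """Exact one-step recurrence of a sinusoid: x_{t+1} − B =
    2cos(ω)(x_t − B) − (x_{t−1} − B)."""
    k = 2.0 * np.cos(2.0 * np.pi / period)

    def fn(window):
        return base + k * (window[-1] - base) - (window[-2] - base)

    return fn


@pytest.fixture
def sinusoid_gap():
    truth = pure_sinusoid(n_days=7)
    gap = GapSpec(start=500, length=200)
    return truth, mask_gap(truth, gap), gap


def _result(values, scheme="forward", start=0):
    values = np.asarray(values, dtype=float)
    return FillResult(scheme=scheme, gap=GapSpec(start=start, length=values.size),
                      filled=values)


class TestDirectionalFill:
    def test_constant_oracle_closed_form(self, sinusoid_gap):
        truth, masked, gap = sinusoid_gap
        tr = MinMaxTransform(lo=40.0, hi=60.0)
        model = OracleModel(lambda w: 0.25, window_length=20, transform=tr)
        res = fill_directional(model, masked, gap, "forward")
        np.testing.assert_allclose(res.filled, tr.invert(0.25))

    def test_constant_oracle_without_transform(self, sinusoid_gap):
        truth, masked, gap = sinusoid_gap
        model = OracleModel(lambda w: 50.0, window_length=20)
        res = fill_directional(model, masked, gap, "forward")
        np.testing.assert_allclose(res.filled, 50.0)

    def test_perfect_oracle_recovers_sinusoid_forward(self, sinusoid_gap):
        truth, masked, gap = sinusoid_gap
        model = OracleModel(sinusoid_oracle(50.0), window_length=20)
        res = fill_directional(model, masked, gap, "forward")
        np.testing.assert_allclose(
            res.filled, truth.values[gap.start:gap.stop], atol=1e-6
        )

    def test_perfect_oracle_recovers_sinusoid_reverse(self, sinusoid_gap):
        truth, masked, gap = sinusoid_gap
        model = OracleModel(sinusoid_oracle(50.0), window_length=20)
        res = fill_directional(model, masked, gap, "reverse")
        assert res.scheme == "reverse"
        np.testing.assert_allclose(
            res.filled, truth.values[gap.start:gap.stop], atol=1e-6
        )

    def test_fill_length_equals_gap_length(self, sinusoid_gap):
        _, masked, gap = sinusoid_gap
        model = OracleModel(lambda w: 50.0, window_length=20)
        assert fill_directional(model, masked, gap).filled.size == 200

    def test_insufficient_runup_rejected(self):
        truth = pure_sinusoid(n_days=1)
        gap = GapSpec(start=5, length=10)
        masked = mask_gap(truth, gap)
        model = OracleModel(lambda w: 50.0, window_length=20)
        with pytest.raises(ValueError, match="before the gap"):
            fill_directional(model, masked, gap, "forward")

    def test_observed_values_untouched(self, sinusoid_gap):
        truth, masked, gap = sinusoid_gap
        model = OracleModel(lambda w: 50.0, window_length=20)
        res = fill_directional(model, masked, gap)
        filled_series = res.apply_to(masked)
        outside = ~masked.mask
        np.testing.assert_array_equal(
            filled_series.values[outside], masked.values[outside]
        )
        assert filled_series.n_missing == 0


class TestCombineEqual:
    def test_arithmetic_mean(self):
        f = _result([50.0, 50.0])
        r = _result([52.0, 50.0], scheme="reverse")
        z = combine_equal(f, r)
        np.testing.assert_allclose(z.filled, [51.0, 50.0])
        np.testing.assert_allclose(z.weights, [[0.5, 0.5], [0.5, 0.5]])

    def test_identical_inputs_fixed_point(self):
        f = _result([44.0, 45.0, 46.0])
        z = combine_equal(f, _result([44.0, 45.0, 46.0], scheme="reverse"))
        np.testing.assert_allclose(z.filled, f.filled)

    def test_symmetry_in_values(self):
        f = _result([50.0, 51.0])
        r = _result([48.0, 53.0], scheme="reverse")
        np.testing.assert_allclose(
            combine_equal(f, r).filled, combine_equal(r, f).filled
        )

    def test_gap_mismatch_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            combine_equal(_result([1.0, 2.0]), _result([1.0, 2.0], start=5))


class TestDecreasingWeights:
    def test_endpoints_and_sum(self):
        w = decreasing_weight_schedule(200)
        assert tuple(w[0]) == (1.0, 0.0)
        assert w[-1, 0] == pytest.approx(0.05)
        assert w[-1, 1] == pytest.approx(0.95)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_twenty_blocks_of_ten_at_length_200(self):
        w = decreasing_weight_schedule(200)
        a = w[:, 0].reshape(20, 10)
        assert (a == a[:, :1]).all()  # constant within each block
        np.testing.assert_allclose(np.diff(a[:, 0]), -0.05)

    def test_remainder_goes_to_earliest_blocks(self):
        w = decreasing_weight_schedule(23)
        # 23 = 20 blocks, the first 3 of size 2
        assert (w[:2, 0] == 1.0).all()
        assert w[2, 0] == pytest.approx(0.95)

    def test_gradient_must_divide_evenly(self):
        with pytest.raises(ValueError, match="divide"):
            decreasing_weight_schedule(100, gradient=0.04)

    def test_combined_values_and_weights(self):
        L = 40
        f = _result(np.full(L, 50.0))
        r = _result(np.full(L, 52.0), scheme="reverse")
        z = combine_decreasing(f, r)
        assert z.filled[0] == pytest.approx(50.0)  # a=1: pure forward
        assert z.filled[-1] == pytest.approx(0.05 * 50 + 0.95 * 52)
        assert z.weights.shape == (L, 2)


class TestCombineSegmented:
    def test_half_split_at_200(self):
        f = _result(np.full(200, 1.0))
        r = _result(np.full(200, 2.0), scheme="reverse")
        z = combine_segmented(f, r)
        assert (z.filled[:100] == 1.0).all()
        assert (z.filled[100:] == 2.0).all()

    def test_identical_inputs(self):
        f = _result([7.0, 8.0, 9.0])
        z = combine_segmented(f, _result([7.0, 8.0, 9.0], scheme="reverse"))
        np.testing.assert_allclose(z.filled, f.filled)

    def test_length_one_takes_forward(self):
        z = combine_segmented(_result([1.0]), _result([2.0], scheme="reverse"))
        assert z.filled[0] == 1.0


class TestFusionProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_convexity_of_weighted_schemes(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 60))
        f = _result(rng.uniform(40, 60, L))
        r = _result(rng.uniform(40, 60, L), scheme="reverse")
        lo = np.minimum(f.filled, r.filled)
        hi = np.maximum(f.filled, r.filled)
        for combiner in (combine_equal, combine_decreasing):
            z = combiner(f, r)
            assert (z.filled >= lo - 1e-12).all()
            assert (z.filled <= hi + 1e-12).all()

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FillResult(scheme="bidir_equal", gap=GapSpec(0, 2),
                       filled=np.zeros(2), weights=np.array([[0.6, 0.6]] * 2))


@pytest.fixture(scope="module")
def tiny_fills():
    """End-to-end trained fills on a short scenario (shared)."""
    truth = pure_sinusoid(n_days=6)
    gap = GapSpec(start=400, length=48)
    masked = mask_gap(truth, gap)
    arch = stacked_architecture("lstm", (10,), dropout_fraction=None,
                                window_length=36, batch_size=64)
    fills = fill_all_schemes(arch, masked, gap,
                             FillTrainConfig(epochs=12), seed=3)
    return truth, gap, fills


class TestFillBidirectional:
    def test_all_five_schemes_produced(self, tiny_fills):
        _, gap, fills = tiny_fills
        assert set(fills) == {"forward", "reverse", "bidir_equal",
                              "bidir_decreasing", "bidir_segmented"}
        for res in fills.values():
            assert res.filled.size == gap.length
            assert np.isfinite(res.filled).all()

    def test_fusions_consistent_with_directionals(self, tiny_fills):
        _, _, fills = tiny_fills
        np.testing.assert_allclose(
            fills["bidir_equal"].filled,
            0.5 * fills["forward"].filled + 0.5 * fills["reverse"].filled,
        )

    def test_single_scheme_path_matches_all_schemes(self, tiny_fills):
        truth, gap, fills = tiny_fills
        masked = mask_gap(truth, gap)
        arch = stacked_architecture("lstm", (10,), dropout_fraction=None,
                                    window_length=36, batch_size=64)
        solo = fill_bidirectional(arch, masked, gap, "forward",
                                  FillTrainConfig(epochs=12), seed=3)
        np.testing.assert_allclose(solo.filled, fills["forward"].filled)

    def test_deficient_side_named(self):
        truth = pure_sinusoid(n_days=2)
        gap = GapSpec(start=10, length=20)
        masked = mask_gap(truth, gap)
        arch = stacked_architecture("lstm", (4,), window_length=36, batch_size=8)
        with pytest.raises(ValueError, match="pre-gap"):
            fill_bidirectional(arch, masked, gap, "forward",
                               FillTrainConfig(epochs=1), seed=0)

    def test_unknown_scheme_rejected(self, sinusoid_gap=None):
        truth = pure_sinusoid(n_days=2)
        gap = GapSpec(start=100, length=10)
        masked = mask_gap(truth, gap)
        arch = stacked_architecture("lstm", (4,), window_length=12, batch_size=8)
        with pytest.raises(ValueError, match="unknown scheme"):
            fill_bidirectional(arch, masked, gap, "sideways")
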