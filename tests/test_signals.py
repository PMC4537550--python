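"""Synthetic shapes, noise models and benchmark dataset construction."""

import numpy as np
import pytest
from scipy import stats

from sw1pers.signals import (
    ALL_SHAPES,
    GAUSSIAN_ADDITIVE_SDS,
    LAPLACE_ADDITIVE_SPREADS,
    NONPERIODIC_SHAPES,
    PERIODIC_SHAPES,
    NoiseSpec,
    ShapeSpec,
    TimeSeries,
    apply_noise,
    build_benchmark,
    generate_shape,
    match_laplace_spread,
    sample_times,
)


class TestShapeCatalogue:
    def test_ten_periodic_four_nonperiodic(self):
        assert len(PERIODIC_SHAPES) == 10
        assert len(NONPERIODIC_SHAPES) == 4
        assert len(ALL_SHAPES) == 14

    def test_unknown_shape_lists_admissible_names(self):
        with pytest.raises(ValueError, match="cos2"):
            ShapeSpec("wiggle")

    def test_phase_must_be_in_period(self):
        with pytest.raises(ValueError):
            ShapeSpec("cos", phase=100.0)


class TestGenerateShape:
    def test_cos_crest_at_origin(self):
        s = generate_shape(ShapeSpec("cos"), np.array([0.0, 50.0]))
        assert s.values[0] == pytest.approx(50.0)  # A = amplitude/2
        assert s.values[1] == pytest.approx(-50.0)

    def test_flat_is_constant(self, rng):
        t = np.sort(rng.uniform(0, 200, 20))
        s = generate_shape(ShapeSpec("flat"), t)
        assert np.ptp(s.values) == 0.0

    def test_square_duty_cycle(self):
        s = generate_shape(ShapeSpec("square"), np.array([25.0, 75.0]))
        assert s.values[0] == pytest.approx(50.0)
        assert s.values[1] == pytest.approx(-50.0)

    @pytest.mark.parametrize("name", ["cos", "cos2", "peak", "peak2", "saw", "square"])
    def test_pure_periodic_shapes_repeat_exactly(self, name):
        t = np.linspace(0.0, 99.0, 67)
        a = generate_shape(ShapeSpec(name, phase=13.0), t)
        b = generate_shape(ShapeSpec(name, phase=13.0), t + 100.0)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_damp_halves_each_period(self):
        t = np.array([0.0, 100.0, 200.0])
        s = generate_shape(ShapeSpec("damp"), t)
        assert s.values[1] == pytest.approx(s.values[0] / 2)
        assert s.values[2] == pytest.approx(s.values[0] / 4)

    def test_trend_lin_is_cos_plus_ramp(self):
        t = np.linspace(0, 200, 9)
        trend = generate_shape(ShapeSpec("trend_lin"), t)
        cos = generate_shape(ShapeSpec("cos"), t)
        ramp = trend.values - cos.values
        assert np.allclose(np.diff(ramp, 2), 0.0, atol=1e-9)  # linear
        assert ramp[-1] - ramp[0] == pytest.approx(50.0)  # drifts by A

    def test_contract_shortens_cycles(self):
        # zero crossings of the contracting cosine get closer together
        t = np.linspace(0, 200, 20001)
        v = generate_shape(ShapeSpec("contract"), t).values
        crossings = t[1:][np.diff(np.sign(v)) != 0]
        gaps = np.diff(crossings)
        assert gaps[-1] < gaps[0]

    def test_peak_shapes_cover_full_amplitude(self):
        t = np.linspace(0, 200, 4001)
        for name in ("peak", "peak2", "cos2"):
            v = generate_shape(ShapeSpec(name), t).values
            assert np.ptp(v) == pytest.approx(100.0, rel=1e-3)

    def test_deterministic(self):
        t = np.linspace(0, 200, 25)
        a = generate_shape(ShapeSpec("saw", phase=42.0), t)
        b = generate_shape(ShapeSpec("saw", phase=42.0), t)
        assert np.array_equal(a.values, b.values)


class TestApplyNoise:
    def test_level_zero_is_identity(self, cos25, rng):
        for model in (
            "gaussian_additive",
            "laplace_additive",
            "gaussian_multiplicative",
            "laplace_multiplicative",
        ):
            out = apply_noise(cos25, NoiseSpec(model, 0.0), rng)
            assert np.array_equal(out.values, cos25.values)

    def test_gaussian_additive_variance(self):
        r = np.random.default_rng(7)
        base = TimeSeries("z", np.arange(1_000_000.0), np.zeros(1_000_000))
        out = apply_noise(base, NoiseSpec("gaussian_additive", 12.0), r)
        assert np.var(out.values) == pytest.approx(144.0, rel=0.01)

    def test_laplace_variance_matches_gaussian_partner(self):
        r = np.random.default_rng(8)
        base = TimeSeries("z", np.arange(1_000_000.0), np.zeros(1_000_000))
        out = apply_noise(base, NoiseSpec("laplace_additive", 8.49), r)
        assert np.var(out.values) == pytest.approx(2 * 8.49**2, rel=0.01)
        assert 2 * 8.49**2 == pytest.approx(144.0, rel=0.01)

    def test_multiplicative_scales_by_one_plus_eta(self):
        r = np.random.default_rng(9)
        base = TimeSeries("z", np.arange(200_000.0), np.full(200_000, 4.0))
        out = apply_noise(base, NoiseSpec("gaussian_multiplicative", 0.25), r)
        assert np.mean(out.values) == pytest.approx(4.0, rel=0.01)
        assert np.std(out.values) == pytest.approx(1.0, rel=0.02)  # 4 * 0.25

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec("gaussian_additive", -1.0)


class TestMatchLaplaceSpread:
    @pytest.mark.parametrize(
        "sd,b", list(zip(GAUSSIAN_ADDITIVE_SDS, LAPLACE_ADDITIVE_SPREADS))
    )
    def test_printed_grid(self, sd, b):
        assert match_laplace_spread(sd) == pytest.approx(b)

    def test_variance_matching_identity(self):
        for sd, b in zip(GAUSSIAN_ADDITIVE_SDS[1:], LAPLACE_ADDITIVE_SPREADS[1:]):
            assert 2 * b**2 == pytest.approx(sd**2, rel=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            match_laplace_spread(-3.0)


class TestSampleTimes:
    def test_17_samples_spacing(self):
        t = sample_times(17)
        assert np.allclose(np.diff(t), 12.5)
        assert t[0] == 0.0 and t[-1] == 200.0

    def test_two_samples(self):
        assert sample_times(2).tolist() == [0.0, 200.0]

    def test_25_samples_spacing(self):
        assert np.allclose(np.diff(sample_times(25)), 200.0 / 24.0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            sample_times(1)


class TestBuildBenchmark:
    def test_counts_and_labels(self):
        ds = build_benchmark(signals_per_shape=2, samplings=(17,), seed=3)
        assert len(ds) == 28
        periodic = {r.shape for r in ds.records if r.periodic}
        assert periodic == set(PERIODIC_SHAPES)

    def test_seed_reproducibility(self):
        a = build_benchmark(signals_per_shape=1, samplings=(13,), seed=11)
        b = build_benchmark(signals_per_shape=1, samplings=(13,), seed=11)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.series.values, rb.series.values)
            assert ra.phase == rb.phase

    def test_different_seeds_differ(self):
        a = build_benchmark(signals_per_shape=1, samplings=(13,), seed=1)
        b = build_benchmark(signals_per_shape=1, samplings=(13,), seed=2)
        assert not np.array_equal(a.records[0].series.values, b.records[0].series.values)

    def test_phases_uniform_on_period(self):
        ds = build_benchmark(
            shapes=("cos",), signals_per_shape=10_000, samplings=(13,), seed=5
        )
        phases = np.array([r.phase for r in ds.records])
        assert stats.kstest(phases / 100.0, "uniform").pvalue > 0.01

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            build_benchmark(shapes=(), signals_per_shape=1, seed=0)
        with pytest.raises(ValueError):
            build_benchmark(samplings=(), signals_per_shape=1, seed=0)
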