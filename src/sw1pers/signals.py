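"""Synthetic benchmark signals: shapes, noise models, sampling grids.

The benchmark emulates expression time courses over two cycles: period 100
time units, record span 200 units, 10 periodic and 4 non-periodic shapes,
four noise models at matched variances, and three sampling densities
(50, 25, 17 samples).  Signals are zero-baseline with peak-to-trough
amplitude 100, so the additive noise SD grid {0, 12, 25, 37, 50} runs from
0% to 100% of the semi-amplitude.

Closed forms (theta = 2*pi*(t - phase)/period, A = amplitude/2):

========== =================================================================
cos        A*cos(theta)
cos2       cos(theta) + cos(2*theta)/2, rescaled to [-A, A] (two unequal
           extrema per period)
peak       periodic von-Mises-style bump exp(kappa*(cos(theta)-1)),
           kappa = 5, rescaled to [-A, A]
peak2      two bumps per period with height ratio 1 : 0.6, rescaled
trend_lin  A*cos(theta) + (A/span)*t
trend_exp  A*cos(theta) + A*(exp(t*ln3/span) - 1)/2
damp       exp(-t*ln2/period)*A*cos(theta)  (amplitude halves each period)
saw        rising sawtooth over [-A, A]
square     50% duty cycle: +A on the first half-period, -A on the second
contract   cosine whose instantaneous period shrinks linearly from period
           to 0.7*period across the span
flat       constant 0
line       linear ramp from -A to +A across the span
exp_decay  amplitude*exp(-3*t/span)
sigmoid    logistic centred at span/2 with steepness 10/span, in [-A, A]
========== =================================================================

Phase is drawn per signal, uniform on [0, period); it shifts the oscillation
of the periodic shapes and is ignored for the four non-periodic shapes
(a time-shifted ramp would change its range over the fixed record rather
than model a phase).  All per-shape constants live in
``ShapeSpec.shape_params`` and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "PERIODIC_SHAPES",
    "NONPERIODIC_SHAPES",
    "ALL_SHAPES",
    "NOISE_MODELS",
    "GAUSSIAN_ADDITIVE_SDS",
    "LAPLACE_ADDITIVE_SPREADS",
    "GAUSSIAN_MULTIPLICATIVE_SDS",
    "LAPLACE_MULTIPLICATIVE_SPREADS",
    "ShapeSpec",
    "NoiseSpec",
    "TimeSeries",
    "SignalRecord",
    "BenchmarkDataset",
    "generate_shape",
    "apply_noise",
    "match_laplace_spread",
    "sample_times",
    "build_benchmark",
]

PERIODIC_SHAPES = (
    "cos",
    "cos2",
    "peak",
    "peak2",
    "trend_lin",
    "trend_exp",
    "damp",
    "saw",
    "square",
    "contract",
)
NONPERIODIC_SHAPES = ("flat", "line", "exp_decay", "sigmoid")
ALL_SHAPES = PERIODIC_SHAPES + NONPERIODIC_SHAPES

NOISE_MODELS = (
    "gaussian_additive",
    "laplace_additive",
    "gaussian_multiplicative",
    "laplace_multiplicative",
)

#: Noise level grids; the Laplace spreads are the variance-matched partners
#: (SD = sqrt(2)*b) of the Gaussian SDs, rounded to 2 decimals.
GAUSSIAN_ADDITIVE_SDS = (0.0, 12.0, 25.0, 37.0, 50.0)
LAPLACE_ADDITIVE_SPREADS = (0.0, 8.49, 17.68, 26.16, 35.36)
GAUSSIAN_MULTIPLICATIVE_SDS = (0.0, 0.12, 0.25, 0.37, 0.5)
LAPLACE_MULTIPLICATIVE_SPREADS = (0.0, 0.08, 0.18, 0.26, 0.35)

DEFAULT_PERIOD = 100.0
DEFAULT_SPAN = 200.0
DEFAULT_AMPLITUDE = 100.0  # peak-to-trough

_DEFAULT_SHAPE_PARAMS = {
    "peak_kappa": 5.0,
    "peak2_ratio": 0.6,
    "trend_exp_growth": math.log(3.0),
    "damp_halving_periods": 1.0,
    "contract_factor": 0.7,
    "exp_decay_timescale_fraction": 1.0 / 3.0,
    "sigmoid_steepness": 10.0,
    "span": DEFAULT_SPAN,
}


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic waveform."""

    name: str
    period: float = DEFAULT_PERIOD
    amplitude: float = DEFAULT_AMPLITUDE
    phase: float = 0.0
    shape_params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ALL_SHAPES:
            raise ValueError(
                f"unknown shape {self.name!r}; admissible names: {', '.join(ALL_SHAPES)}"
            )
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0 <= self.phase < self.period:
            raise ValueError("phase must lie in [0, period)")
        merged = dict(_DEFAULT_SHAPE_PARAMS)
        merged.update(self.shape_params)
        object.__setattr__(self, "shape_params", merged)

    @property
    def periodic(self) -> bool:
        return self.name in PERIODIC_SHAPES


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model and level (SD for Gaussian, spread b for Laplacian)."""

    model: str
    level: float

    def __post_init__(self) -> None:
        if self.model not in NOISE_MODELS:
            raise ValueError(
                f"unknown noise model {self.model!r}; admissible: {', '.join(NOISE_MODELS)}"
            )
        if self.level < 0:
            raise ValueError("noise level must be nonnegative")


@dataclass(frozen=True)
class TimeSeries:
    """A named series of values at strictly increasing times."""

    id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-d and equally long")
        if t.size < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size


def _rescale(u: np.ndarray, lo: float, hi: float, amplitude: float) -> np.ndarray:
    """Affine map of [lo, hi] onto [-amplitude/2, +amplitude/2]."""
    mid = 0.5 * (hi + lo)
    return (u - mid) * (amplitude / (hi - lo))


def _raw_range(fn, n: int = 20001):
    th = np.linspace(0.0, 2.0 * np.pi, n)
    u = fn(th)
    return float(np.min(u)), float(np.max(u))


def generate_shape(spec: ShapeSpec, times: np.ndarray) -> TimeSeries:
    """Evaluate a noiseless shape at the given times.

    Deterministic given the spec; the record spans ``shape_params['span']``
    time units (default 200, i.e. two cycles of the default period).
    """
    t = np.asarray(times, dtype=float)
    p = spec.shape_params
    T = spec.period
    A = spec.amplitude / 2.0
    span = p["span"]
    theta = 2.0 * np.pi * (t - spec.phase) / T
    name = spec.name

    if name == "cos":
        v = A * np.cos(theta)
    elif name == "cos2":
        fn = lambda th: np.cos(th) + 0.5 * np.cos(2 * th)  # noqa: E731
        lo, hi = -0.75, 1.5  # analytic extrema of cos(th) + cos(2 th)/2
        v = _rescale(fn(theta), lo, hi, spec.amplitude)
    elif name == "peak":
        kappa = p["peak_kappa"]
        fn = lambda th: np.exp(kappa * (np.cos(th) - 1.0))  # noqa: E731
        lo, hi = _raw_range(fn)
        v = _rescale(fn(theta), lo, hi, spec.amplitude)
    elif name == "peak2":
        kappa = p["peak_kappa"]
        r = p["peak2_ratio"]
        fn = lambda th: np.exp(kappa * (np.cos(th) - 1.0)) + r * np.exp(  # noqa: E731
            kappa * (np.cos(th - np.pi) - 1.0)
        )
        lo, hi = _raw_range(fn)
        v = _rescale(fn(theta), lo, hi, spec.amplitude)
    elif name == "trend_lin":
        v = A * np.cos(theta) + (A / span) * t
    elif name == "trend_exp":
        g = p["trend_exp_growth"]
        v = A * np.cos(theta) + A * (np.exp(t * g / span) - 1.0) / 2.0
    elif name == "damp":
        lam = p["damp_halving_periods"] * math.log(2.0) / T
        v = np.exp(-lam * t) * A * np.cos(theta)
    elif name == "saw":
        frac = np.mod((t - spec.phase) / T, 1.0)
        v = A * (2.0 * frac - 1.0)
    elif name == "square":
        frac = np.mod((t - spec.phase) / T, 1.0)
        v = np.where(frac < 0.5, A, -A)
    elif name == "contract":
        c = p["contract_factor"]
        shrink = (1.0 - c) / span
        # instantaneous period T*(1 - shrink*t); integrated phase
        phi = (2.0 * np.pi / T) * (-np.log1p(-shrink * t) / shrink)
        v = A * np.cos(phi - 2.0 * np.pi * spec.phase / T)
    elif name == "flat":
        v = np.zeros_like(t)
    elif name == "line":
        v = spec.amplitude * (t / span - 0.5)
    elif name == "exp_decay":
        tau = p["exp_decay_timescale_fraction"] * span
        v = spec.amplitude * np.exp(-t / tau)
    elif name == "sigmoid":
        s = p["sigmoid_steepness"]
        v = spec.amplitude * (1.0 / (1.0 + np.exp(-s * (t - span / 2.0) / span)) - 0.5)
    else:  # pragma: no cover - guarded by ShapeSpec
        raise ValueError(name)
    return TimeSeries(id=name, times=t, values=v)


def apply_noise(series: TimeSeries, spec: NoiseSpec, rng: np.random.Generator) -> TimeSeries:
    """Corrupt a series with zero-mean noise.

    Additive models add eta to each value; multiplicative models scale each
    value by (1 + eta).  Level 0 returns the series unchanged.
    """
    if spec.level == 0:
        return series
    n = len(series)
    if spec.model.startswith("gaussian"):
        eta = rng.normal(0.0, spec.level, size=n)
    else:
        eta = rng.laplace(0.0, spec.level, size=n)
    if spec.model.endswith("additive"):
        v = series.values + eta
    else:
        v = series.values * (1.0 + eta)
    return TimeSeries(id=series.id, times=series.times, values=v)


def match_laplace_spread(sd: float) -> float:
    """Laplace spread b with the same variance as a Gaussian SD (SD = sqrt(2) b).

    Rounded to 2 decimals for reporting, mirroring the printed level grids.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return round(sd / math.sqrt(2.0), 2)


def sample_times(n_samples: int, span: float = DEFAULT_SPAN) -> np.ndarray:
    """n evenly spaced sampling times including both endpoints 0 and span."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    return np.linspace(0.0, span, n_samples)


@dataclass(frozen=True)
class SignalRecord:
    """One labeled benchmark signal."""

    series: TimeSeries
    shape: str
    periodic: bool
    noise_model: str
    noise_level: float
    n_samples: int
    phase: float


@dataclass(frozen=True)
class BenchmarkDataset:
    """All signals of a benchmark run plus the generating configuration."""

    records: tuple
    config: dict
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def cells(self):
        """Distinct (noise_model, noise_level, n_samples) keys, in order."""
        seen = []
        for r in self.records:
            key = (r.noise_model, r.noise_level, r.n_samples)
            if key not in seen:
                seen.append(key)
        return seen


def build_benchmark(
    shapes=ALL_SHAPES,
    noise_specs=(NoiseSpec("gaussian_additive", 0.0),),
    samplings=(50, 25, 17),
    signals_per_shape: int = 1000,
    seed: int = 0,
    period: float = DEFAULT_PERIOD,
    amplitude: float = DEFAULT_AMPLITUDE,
    span: float = DEFAULT_SPAN,
) -> BenchmarkDataset:
    """Generate the labeled synthetic dataset.

    For every (noise spec, sampling) cell and every shape,
    ``signals_per_shape`` signals are drawn with phases uniform on
    [0, period).  Each signal gets its own child random stream derived from
    (seed, running counter), so the dataset is bit-reproducible and safe to
    generate in parallel.
    """
    shapes = tuple(shapes)
    noise_specs = tuple(noise_specs)
    samplings = tuple(int(s) for s in samplings)
    if not shapes or not noise_specs or not samplings:
        raise ValueError("shapes, noise_specs and samplings must be nonempty")
    if signals_per_shape < 1:
        raise ValueError("signals_per_shape must be >= 1")
    unknown = [s for s in shapes if s not in ALL_SHAPES]
    if unknown:
        raise ValueError(f"unknown shapes: {unknown}; admissible: {', '.join(ALL_SHAPES)}")

    records = []
    counter = 0
    for nspec in noise_specs:
        for n_samples in samplings:
            times = sample_times(n_samples, span)
            for shape in shapes:
                for _ in range(signals_per_shape):
                    rng = np.random.default_rng(
                        np.random.SeedSequence(entropy=seed, spawn_key=(counter,))
                    )
                    phase = float(rng.uniform(0.0, period))
                    sspec = ShapeSpec(
                        name=shape,
                        period=period,
                        amplitude=amplitude,
                        phase=phase if shape in PERIODIC_SHAPES else 0.0,
                        shape_params={"span": span},
                    )
                    clean = generate_shape(sspec, times)
                    noisy = apply_noise(clean, nspec, rng)
                    records.append(
                        SignalRecord(
                            series=TimeSeries(
                                id=f"{shape}_{counter:06d}",
                                times=noisy.times,
                                values=noisy.values,
                            ),
                            shape=shape,
                            periodic=shape in PERIODIC_SHAPES,
                            noise_model=nspec.model,
                            noise_level=nspec.level,
                            n_samples=n_samples,
                            phase=phase,
                        )
                    )
                    counter += 1
    config = {
        "shapes": list(shapes),
        "noise_specs": [{"model": n.model, "level": n.level} for n in noise_specs],
        "samplings": list(samplings),
        "signals_per_shape": signals_per_shape,
        "period": period,
        "amplitude": amplitude,
        "span": span,
    }
    return BenchmarkDataset(records=tuple(records), config=config, seed=seed)
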