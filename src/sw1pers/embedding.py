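"""Sliding-window (time-delay) embedding of expression time series.

A scalar signal g sampled at arbitrary strictly increasing times is mapped
linearly onto [0, 2*pi], interpolated with a cubic spline, and expanded into
the point cloud of window vectors

    SW(t) = [g(t), g(t + tau), ..., g(t + M*tau)],    tau = w / M,

for window starts t on an even grid of [0, 2*pi - w].  A signal with L
periods in the record traces this cloud around a closed loop when the window
size w is near its natural value 2*pi*M / (L*(M+1)).  Pointwise
mean-centering and unit normalization of every vector then removes
amplitude, offset, damping and trending effects, placing the cloud on the
unit sphere in R^{M+1}.

Two optional denoisers: a simple moving average on the series (local mean
with shrinking half-width at the record ends) and a mean-shift pass on the
sphere (each point replaced by the average of its angular neighbourhood,
then re-normalized).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline

from .signals import TimeSeries

__all__ = [
    "WindowParams",
    "PointCloud",
    "default_window",
    "default_embedding_dim",
    "fit_spline",
    "sliding_window_cloud",
    "center_normalize",
    "moving_average",
    "mean_shift",
]

#: Relative tolerance below which a centered window vector counts as
#: degenerate (a flat window has no direction on the sphere).
_DEGENERATE_RTOL = 1e-9
_DEGENERATE_ATOL = 1e-12


def default_window(M: int, L: float) -> float:
    """Natural window size 2*pi*M / (L*(M+1)) for L expected periods."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if L < 1:
        raise ValueError("L must be >= 1")
    return 2.0 * math.pi * M / (L * (M + 1))


def default_embedding_dim(n_samples: int) -> int:
    """Default M: 2*n_samples + 1 (odd), with a floor of 23."""
    return max(2 * int(n_samples) + 1, 23)


@dataclass(frozen=True)
class WindowParams:
    """Embedding dimension, window size and window-start grid."""

    M: int
    w: float
    L: float
    grid_size: int = 200

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not 0 < self.w < 2 * math.pi:
            raise ValueError("window size must lie in (0, 2*pi)")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")

    @property
    def tau(self) -> float:
        return self.w / self.M

    @classmethod
    def for_signal(cls, n_samples: int, L: float, M: int | None = None,
                   grid_size: int = 200) -> "WindowParams":
        """Defaults for a record of ``n_samples`` points and L periods."""
        if M is None:
            M = default_embedding_dim(n_samples)
        return cls(M=M, w=default_window(M, L), L=L, grid_size=grid_size)


@dataclass(frozen=True)
class PointCloud:
    """Ordered window vectors; rows are points in R^{M+1}."""

    points: np.ndarray
    normalized: bool = False
    n_degenerate: int = 0
    n_raw: int | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2:
            raise ValueError("points must be a 2-d array")
        object.__setattr__(self, "points", pts)
        if self.n_raw is None:
            object.__setattr__(self, "n_raw", pts.shape[0])
        if self.normalized and pts.shape[0]:
            norms = np.linalg.norm(pts, axis=1)
            means = pts.mean(axis=1)
            if not (np.allclose(norms, 1.0, atol=1e-9) and np.allclose(means, 0.0, atol=1e-9)):
                raise ValueError("normalized cloud must have unit-norm, zero-mean points")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def degenerate_fraction(self) -> float:
        return self.n_degenerate / self.n_raw if self.n_raw else 0.0


def fit_spline(series: TimeSeries):
    """Cubic spline of a series over [0, 2*pi].

    Times are mapped linearly so the first sample lands at 0 and the last at
    2*pi; the spline interpolates every sample (natural boundary conditions:
    zero second derivative at the ends).  Records with fewer than 4 points
    get a spline of correspondingly lower degree.
    """
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    x = (t - t[0]) * (2.0 * math.pi / (t[-1] - t[0]))
    x[-1] = 2.0 * math.pi  # exact endpoint despite rounding
    if t.size >= 4:
        return CubicSpline(x, v, bc_type="natural")
    return make_interp_spline(x, v, k=t.size - 1)


def sliding_window_cloud(g, params: WindowParams) -> PointCloud:
    """Evaluate the sliding-window vectors on the window-start grid.

    Point j (j = 0..grid_size) starts at t_j = j*(2*pi - w)/grid_size, so
    the final window ends exactly at 2*pi; the default grid gives 201
    points.
    """
    N = params.grid_size
    starts = np.arange(N + 1) * ((2.0 * math.pi - params.w) / N)
    offsets = np.arange(params.M + 1) * params.tau
    grid = starts[:, None] + offsets[None, :]
    # window ends can overshoot 2*pi by rounding; clamp inside the domain
    np.clip(grid, 0.0, 2.0 * math.pi, out=grid)
    pts = np.asarray(g(grid.ravel()), dtype=float).reshape(grid.shape)
    return PointCloud(points=pts, normalized=False)


def center_normalize(cloud: PointCloud) -> PointCloud:
    """Pointwise mean-center and unit-normalize every window vector.

    This is the step that makes the score blind to amplitude, offset,
    damping and trending: x and a*x + c*(1,..,1) map to the same point for
    any a > 0.  Vectors with (numerically) all-equal coordinates have no
    direction and are excluded; their count is carried on the cloud.
    """
    if len(cloud) == 0:
        raise ValueError("cannot normalize an empty cloud")
    pts = cloud.points
    centered = pts - pts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    scale = np.linalg.norm(pts, axis=1)
    ok = norms > (_DEGENERATE_RTOL * np.maximum(scale, 1.0) + _DEGENERATE_ATOL)
    out = centered[ok] / norms[ok, None]
    return PointCloud(
        points=out,
        normalized=True,
        n_degenerate=int((~ok).sum()),
        n_raw=pts.shape[0],
    )


def moving_average(
    series: TimeSeries, k: int, params: WindowParams | None = None
) -> TimeSeries:
    """Simple moving average with half-width k and shrinking ends.

    Sample s is replaced by the mean of samples s-l .. s+l with
    l = min(s, S-s, k), so the first and last samples are left unchanged.
    When window parameters are supplied, k is checked against the rule that
    2k+1 consecutive samples must not span more than a third of the window
    size (measured after the linear map of the record onto [0, 2*pi]); the
    error message reports the largest admissible k.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    S = len(series) - 1
    if 2 * k + 1 > len(series):
        raise ValueError("2k+1 must not exceed the series length")
    if params is not None and k > 0:
        x = (series.times - series.times[0]) * (
            2.0 * math.pi / (series.times[-1] - series.times[0])
        )
        limit = params.w / 3.0

        def span_ok(kk: int) -> bool:
            if kk == 0:
                return True
            spans = x[2 * kk :] - x[: -2 * kk] if 2 * kk < x.size else [np.inf]
            return float(np.max(spans)) <= limit

        if not span_ok(k):
            kmax = 0
            while kmax + 1 <= S // 2 and span_ok(kmax + 1):
                kmax += 1
            raise ValueError(
                f"k={k} spans more than w/3 of the window; "
                f"largest admissible k is {kmax}"
            )
    if k == 0:
        return series
    v = series.values
    out = np.empty_like(v)
    for s in range(S + 1):
        l = min(s, S - s, k)
        out[s] = v[s - l : s + l + 1].mean()
    return TimeSeries(id=series.id, times=series.times, values=out)


def mean_shift(
    cloud: PointCloud, angle_threshold: float = math.pi / 16, rounds: int = 1
) -> PointCloud:
    """Tighten a spherical cloud by averaging angular neighbourhoods.

    Each point is replaced by the mean of all points (itself included) whose
    angle to it is below the threshold, then re-normalized to the sphere
    (no re-centering).  The threshold default pi/16 was tuned on the
    synthetic benchmark.  The pass is a contraction: the maximum pairwise
    angle never increases.
    """
    if len(cloud) == 0:
        raise ValueError("cannot mean-shift an empty cloud")
    if not cloud.normalized:
        raise ValueError("mean_shift expects a normalized cloud")
    pts = cloud.points
    for _ in range(rounds):
        cosines = np.clip(pts @ pts.T, -1.0, 1.0)
        near = np.arccos(cosines) < angle_threshold
        sums = near.astype(float) @ pts
        norms = np.linalg.norm(sums, axis=1, keepdims=True)
        norms[norms == 0] = 1.0  # isolated antipodal degeneracies: keep point
        pts = sums / norms
    return PointCloud(
        points=pts,
        normalized=True,
        n_degenerate=cloud.n_degenerate,
        n_raw=cloud.n_raw,
    )
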