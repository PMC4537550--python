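# Methods

## Model and pipeline

The scorer treats periodicity as a geometric property: a signal that repeats
L times over its record traces a closed loop when embedded by sliding
windows. The pipeline is

1. **Time normalization and splining.** Sample times are mapped linearly onto
   [0, 2π] (t₀ → 0, t_S → 2π; original units are never rescaled on input)
   and interpolated with a natural cubic spline (zero second derivative at
   the ends — the boundary condition is a package choice; records with fewer
   than 4 points get a correspondingly lower spline degree). Missing cells in
   an input table are handled by fitting the spline through the observed
   samples only, which is exactly spline imputation of the gaps; rows with
   fewer than 4 observed values are skipped and logged.
2. **Sliding-window cloud.** SW g(t) = [g(t), g(t+τ), …, g(t+Mτ)] with
   τ = w/M, evaluated at window starts t_j = j(2π−w)/grid_size,
   j = 0…grid_size. The last window ends exactly at 2π.
3. **Pointwise center/normalize.** Each vector loses its own coordinate mean
   and is scaled to unit norm. This makes the score exactly invariant under
   g ↦ a·g + c (a > 0) and is what absorbs damping and trending. Windows
   with numerically zero variance (relative tolerance 1e−9) have no
   direction; they are excluded and counted.
4. **Optional denoisers** (both off by default): a simple moving average on
   the series (half-width k, shrinking to ℓ = min{s, S−s, k} at the ends, so
   endpoints are untouched; k is rejected if 2k+1 samples span more than w/3)
   and a single mean-shift pass on the sphere (each point replaced by the
   mean of all points within angle π/16 — a constant tuned on the synthetic
   benchmark — then re-normalized; re-centering is deliberately not repeated).
   Whether the original evaluation ran these during the synthetic benchmark
   is unknown, so opt-in is the safe default.
5. **Persistence.** Euclidean distances; Vietoris–Rips H1 over ℤ/2 up to the
   filtration cap √3 + 1e−6; coverage radius b; d = max(b, maximal death).
6. **Score.** s(n,m) = 1 − (dⁿ − bᵐ)/3^{n/2} with n = m = 2, clipped to
   [0, 1] (clipping flagged; it can occur only when d exceeds √3 numerically).

### Degenerate inputs

If more than half the windows are degenerate, or fewer than 4 points remain,
the cloud has no circular structure to measure: the pipeline short-circuits
to score 1.0 with a `degenerate` flag. Constant signals take this path. This
avoids 0/0 in the normalization and matches the semantics "no repetition
detected".

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| L | required | expected periods in the record; the method scores at this period length and never estimates period or phase |
| M | 2·(samples)+1, floor 23 | embedding dimension − 1; "larger than twice the number of time points" with an odd default and a floor so very short records still embed richly |
| w | 2πM/(L(M+1)) | the theoretically motivated window size; at this w a pure cos(Lθ) embeds as a planar circle |
| grid_size | 200 | 201 window starts; the printed grid convention t_j = j(2π−w)/200 |
| n, m | 2, 2 | score exponents; the pair reported to perform best on the benchmark |
| field | ℤ/2 | coefficient field; odd primes available (theory occasionally needs p ≠ 2), and ℤ/2 vs ℤ/3 agreement is asserted on test clouds |
| max_scale | √3 + 1e−6 | deaths beyond √3 carry no extra information for the score; capping bounds the filtration size. Cycles alive at the cap are censored there, flagged, and scored with death = cap (conservative) |
| SMA k / mean-shift | off | opt-in denoisers, see above |

## Persistence engine

Simplices are ordered by (filtration value, dimension, lexicographic vertex
tuple); edge-length ties use the same rule, so the diagram is a pure function
of the distance matrix. Two independent routes:

- **ℤ/2 (default).** Column reduction of the anti-transposed boundary matrix:
  coboundary columns of edges, processed in decreasing filtration order,
  against triangle rows. Clearing skips the columns of negative edges
  (identified by a union-find sweep; they provably reduce to zero). Cofacets
  are enumerated on the fly from the distance matrix — no triangle list is
  materialized, although the filtration of a 201-point cloud holds on the
  order of 10⁶ triangles. Pivot collisions are rare, so freshly assembled
  columns are stored lazily (just the edge id) and materialized only when a
  chase needs them; long chases switch from sorted-array merging to a lazy
  binary-heap column so each addition costs only the added column's length.
  A circle-like 201-point cloud reduces in ~0.1 s; adversarial (uniformly
  random) clouds take ~1 s.
- **Odd primes.** Plain sparse column reduction of the triangle boundary in
  the homology direction. Quadratic-ish and Python-level: intended for small
  clouds and cross-checks, not the 201-point hot path.

Both routes are tested against a deliberately naive oracle (full simplex
enumeration + dense Gaussian elimination over GF(p)) on hundreds of random
clouds, including censored/essential classes, and against closed-form
geometry: unit square → (1, √2); regular hexagon → (1, √3); regular n-gons
with 6 | n → (2 sin(π/n), √3).

## Synthetic benchmark

The generator's defaults are the study conditions: period 100, span 200
(two cycles), peak-to-trough amplitude 100 around baseline 0, phases uniform
on [0, period), 1000 signals/shape in a full run, samplings {50, 25, 17},
and the four noise models with level grids
SD ∈ {0, 12, 25, 37, 50} (Gaussian additive), b ∈ {0, 8.49, 17.68, 26.16,
35.36} (Laplace additive, variance-matched via SD = √2·b), and the
multiplicative analogues {0, 0.12, 0.25, 0.37, 0.5} / {0, 0.08, 0.18, 0.26,
0.35}. Multiplicative noise is value·(1+η) — chosen over value·e^η for
symmetry at small levels. Each signal draws its own child random stream from
(master seed, counter), so datasets are bit-reproducible and parallel-safe.

The exact closed forms of the original benchmark waveforms are not publicly
documented, so this package fixes its own (listed in `signals.py`): shapes
requiring normalization (cos2, peak, peak2) are affinely rescaled to the
target peak-to-trough; the square wave uses the 50% duty-cycle convention
(+A on the first half-period); the contracting cosine integrates an
instantaneous period shrinking linearly to 0.7·T across the span; phase is
applied only to periodic shapes (a time-shifted ramp would change its range
over the fixed record rather than model a phase). These reproduce the
intended qualitative regimes — e.g. the zero-noise medians order the damped
cosine among the most periodic shapes — but not any particular published
coefficients.

**What passing synthetic tests does and does not show.** The generator
emulates shape diversity, damping/trending/contraction, heavy- vs
light-tailed noise, and sparse sampling. It does not emulate real expression
data's correlated (non-i.i.d.) noise, synchrony loss across a culture,
platform-specific intensity distributions, or uneven/missing sampling
beyond what the user supplies, so benchmark AUCs bound idealized, not
biological, performance.

## Permutation significance

p = #{shuffled copies scoring ≤ original}/N, ties counted, no +1 correction
(p = 0 is attainable); the conventional (hits+1)/(N+1) estimate is reported
alongside. Shuffles permute values only (times fixed). Permutation i of
repetition r uses the stream seeded by (master, r, i), so results are
reproducible and parallelizable; R repetitions (default 5) yield a mean and
a sample standard deviation whose size is governed by the binomial bound
√(p(1−p)/N).

## Problem sizes used in the checked runs

The shipped verification runs are scaled to a single CPU: the zero-noise
benchmark uses 50 signals/shape at 25 samples with the full 201-point cloud
grid (pooled AUC and per-shape medians are stable at this size; the full
1000/shape run is a flag away), and the permutation checks use N = 1000 with
a 101-point window-start grid (grid_size=100) — the p-value definition and
scorer are unchanged, only the cloud density is halved, which leaves the
qualitative p-values (sigmoid at 1, cosine near 0) untouched while keeping
the ~2000 pipeline runs to about a minute. Larger N (10⁴–10⁵) and the
default grid reproduce the same conclusions at proportionally larger cost.

## Numerical choices

- Degenerate-window threshold: centered norm ≤ 1e−9·max(1, ‖x‖) + 1e−12.
- Mean-shift dot products are clamped to [−1, 1] before arccos.
- d is clamped below by b (clamp flagged) to honor 0 ≤ b ≤ d.
- ROC: thresholds sweep distinct scores; ties move the operating point
  diagonally, so the trapezoidal AUC equals the tie-averaged Mann–Whitney
  statistic (asserted against scipy in tests).
- Scores are serialized to 6 decimals; ranks average ties.

## Known limitations

- No period or phase estimation: L is the user's statement of the expected
  number of cycles, and scanning multiple candidate periods means multiple
  runs.
- The score is blind to the *number* of repetitions beyond what the window
  captures; it cannot distinguish 2 from 20 cycles at matched w.
- Very short records (< ~10 points) embed coarsely; b grows and even clean
  periodic signals drift away from 0.
- The odd-prime reduction is not performance-tuned.
- Multiplicative noise on the zero-baseline flat shape leaves it exactly
  constant (degenerate path, score 1) — faithful to the noise semantics, but
  it means that cell's negatives are trivial.
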