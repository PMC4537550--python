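"""Permutation significance of periodicity scores.

The score has no known analytic null distribution, so significance is
assessed empirically: the values of a signal are shuffled N times (times
kept fixed), every shuffle is scored with the same settings as the
original, and the p-value is the proportion of shuffles scoring at least as
periodic (score less than or equal) as the original.  The proportion is
reported verbatim, so p = 0 is attainable; the conventional
(count+1)/(N+1) estimate is carried alongside.  Repetitions use disjoint
random streams so a run is reproducible and parallelizable: permutation i
of repetition r draws its stream from (master seed, r, i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import score_signal
from .signals import TimeSeries

__all__ = ["PermutationResult", "permutation_pvalue", "repeated_permutation"]


@dataclass(frozen=True)
class PermutationResult:
    """Empirical p-values of one signal across R repetitions."""

    id: str
    original_score: float
    N: int
    R: int
    p_values: tuple
    p_values_corrected: tuple
    seed: int
    flags: tuple = ()

    @property
    def mean_p(self) -> float:
        return float(np.mean(self.p_values))

    @property
    def std_p(self) -> float:
        """Sample standard deviation across repetitions (0 when R = 1)."""
        if self.R < 2:
            return 0.0
        return float(np.std(self.p_values, ddof=1))


def _perm_rng(seed: int, r: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r, i)))


def permutation_pvalue(
    series: TimeSeries,
    L: float,
    N: int,
    seed: int = 0,
    repetition: int = 0,
    **scorer_options,
):
    """One-sample permutation p-value.

    Returns (p, p_corrected, original_score).  Lower score means more
    periodic, so a shuffle "beats" the original when its score is <= the
    original's; ties count toward the numerator.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    original = score_signal(series, L, **scorer_options)
    hits = 0
    for i in range(N):
        rng = _perm_rng(seed, repetition, i)
        shuffled = TimeSeries(
            id=f"{series.id}~perm{repetition}.{i}",
            times=series.times,
            values=rng.permutation(series.values),
        )
        res = score_signal(shuffled, L, **scorer_options)
        if res.score <= original.score:
            hits += 1
    return hits / N, (hits + 1) / (N + 1), original.score


def repeated_permutation(
    series: TimeSeries,
    L: float,
    N: int,
    R: int = 5,
    seed: int = 0,
    **scorer_options,
) -> PermutationResult:
    """R independent permutation p-values with mean and spread.

    The standard deviation across repetitions measures Monte-Carlo
    convergence; by the binomial bound it shrinks like sqrt(p(1-p)/N).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    ps = []
    ps_corr = []
    orig = None
    for r in range(R):
        p, pc, orig = permutation_pvalue(
            series, L, N, seed=seed, repetition=r, **scorer_options
        )
        ps.append(p)
        ps_corr.append(pc)
    flags = ("single_repetition",) if R == 1 else ()
    return PermutationResult(
        id=series.id,
        original_score=orig,
        N=N,
        R=R,
        p_values=tuple(ps),
        p_values_corrected=tuple(ps_corr),
        seed=seed,
        flags=flags,
    )
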