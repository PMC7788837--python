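"""Distributions of the panel summary statistics K and X.

K is the number of heterozygous loci of one individual; under mutual
independence it is Poisson-binomial with the per-locus heterozygosities
h_1..h_m, built here by the forward recurrence

    P(K = r | m loci) = P(K = r | m-1) (1 - h_m) + P(K = r-1 | m-1) h_m.

X is the number of IBS-shared alleles of one pair of individuals summed
over loci; under independence it is the trinomial convolution

    P(X = r | m) = P(r | m-1) p0_m + P(r-1 | m-1) p1_m + P(r-2 | m-1) p2_m,

with (p0, p1, p2) the per-locus sharing probabilities. Both recurrences are
exact; no large-m approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basics import HeteroMatrix, HeterozygosityVector
from .sharing import AlleleShareMatrix, ShareProbTable

__all__ = [
    "DiscreteDistribution",
    "observed_K_distribution",
    "expected_K_distribution",
    "observed_X_distribution",
    "expected_X_distribution",
    "compare_distributions",
]


@dataclass
class DiscreteDistribution:
    """Probability (expected) or frequency (observed) vector on 0..max.

    ``probs[r]`` is P(statistic = r); for observed distributions ``counts``
    holds the raw tally and ``n`` its total, and ``n_excluded`` reports how
    many individuals/pairs were dropped by the complete-case policy.
    """

    statistic: str  # "K" | "X"
    probs: np.ndarray
    counts: np.ndarray | None = None
    n: int | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.statistic not in {"K", "X"}:
            raise ValueError("statistic must be 'K' or 'X'")
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {self.probs.sum()}, expected 1")

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.probs))

    def mean(self) -> float:
        return float((self.support * self.probs).sum())

    def variance(self) -> float:
        mu = self.mean()
        return float(((self.support - mu) ** 2 * self.probs).sum())


# ----------------------------------------------------------------------

def observed_K_distribution(h_matrix: HeteroMatrix) -> DiscreteDistribution:
    """Observed distribution of K over complete-case individuals."""
    complete = ~h_matrix.mask.any(axis=1)
    if not complete.any():
        raise ValueError("no individual with complete genotypes across all markers")
    m = len(h_matrix.marker_ids)
    k_values = h_matrix.values[complete].sum(axis=1)
    counts = np.bincount(k_values, minlength=m + 1).astype(float)
    n = int(counts.sum())
    return DiscreteDistribution(
        "K", counts / n, counts, n, n_excluded=int((~complete).sum())
    )


def expected_K_distribution(
    h: HeterozygosityVector | np.ndarray,
) -> DiscreteDistribution:
    """Poisson-binomial pmf of K from per-locus heterozygosities."""
    values = h.values if isinstance(h, HeterozygosityVector) else np.asarray(h, float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("heterozygosity must lie in [0, 1]")
    pmf = np.array([1.0])
    for hm in values:
        pmf = np.convolve(pmf, [1.0 - hm, hm])
    return DiscreteDistribution("K", pmf / pmf.sum())


def observed_X_distribution(shares: AlleleShareMatrix) -> DiscreteDistribution:
    """Observed distribution of X over complete-case pairs."""
    complete = ~shares.mask.any(axis=1)
    if not complete.any():
        raise ValueError("no pair with complete genotypes across all markers")
    m = len(shares.marker_ids)
    x_values = shares.values[complete].sum(axis=1)
    counts = np.bincount(x_values, minlength=2 * m + 1).astype(float)
    n = int(counts.sum())
    return DiscreteDistribution(
        "X", counts / n, counts, n, n_excluded=int((~complete).sum())
    )


def expected_X_distribution(probs: ShareProbTable) -> DiscreteDistribution:
    """Trinomial-convolution pmf of X from per-locus sharing probabilities."""
    pmf = np.array([1.0])
    for p0, p1, p2 in probs.probs:
        pmf = np.convolve(pmf, [p0, p1, p2])
    return DiscreteDistribution("X", pmf / pmf.sum())


# ----------------------------------------------------------------------

def compare_distributions(
    observed: DiscreteDistribution,
    expected: DiscreteDistribution,
    transpose: bool = False,
    seed=None,
) -> pd.DataFrame:
    """Tabulate an observed against an expected distribution.

    ``transpose=False`` returns a long table (value, frequency, origin)
    ready for plotting. ``transpose=True`` returns one row per observed
    unit (individual for K, pair for X), pairing each observed value with a
    seeded draw from the expected distribution.
    """
    if observed.statistic != expected.statistic:
        raise ValueError("cannot compare distributions of different statistics")
    if len(observed.probs) != len(expected.probs):
        raise ValueError("distribution supports differ")
    stat = observed.statistic
    if not transpose:
        support = observed.support
        return pd.DataFrame(
            {
                "value": np.concatenate([support, support]),
                "frequency": np.concatenate([observed.probs, expected.probs]),
                "origin": ["observed"] * len(support) + ["expected"] * len(support),
            }
        )
    if observed.counts is None or observed.n is None:
        raise ValueError("transpose=True needs an observed distribution with counts")
    rng = np.random.default_rng(seed)
    obs_units = np.repeat(observed.support, observed.counts.astype(int))
    exp_units = rng.choice(expected.support, size=observed.n, p=expected.probs)
    return pd.DataFrame({f"{stat}_io": obs_units, f"{stat}_ie": exp_units})
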