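"""Mutual independence test via simulated chi-square nulls.

The null hypothesis is that all markers of the panel are mutually
independent. The observed distribution of a summary statistic (K or X) is
compared to its exact expected distribution under independence with a
Pearson goodness-of-fit statistic; because the expected distribution has
locus-specific probabilities the asymptotic chi-square reference does not
apply, so the null distribution of the statistic is simulated (B panels
drawn from the expected distribution) and the critical value and p-value
are read off the empirical CDF.

Binning contract: the support is partitioned into contiguous bins, merged
from both tails inward toward the mode until every bin has expected count
>= 5; the same partition is applied to the observed counts and to every
null replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .basics import allele_freq, heterozygosity_matrix, locus_heterozygosity
from .distributions import (
    DiscreteDistribution,
    expected_K_distribution,
    expected_X_distribution,
    observed_K_distribution,
    observed_X_distribution,
)
from .sharing import allele_share_matrix, expected_share_props, observed_share_props
from .table import GenotypeTable

__all__ = [
    "Binning",
    "ChiSquareNull",
    "IndependenceResult",
    "bin_support",
    "chisq_statistic",
    "simulate_null_K",
    "simulate_null_X",
    "null_chisq_set",
    "critical_value",
    "p_value",
    "test_independence",
]


@dataclass
class Binning:
    """Contiguous partition of a discrete support with expected counts >= 5."""

    edges: np.ndarray  # start index of each bin; edges[0] == 0
    probs: np.ndarray  # expected probability mass per bin
    n: int  # sample size the binning was built for
    min_expected: float = 5.0

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    def bin_counts(self, counts: np.ndarray) -> np.ndarray:
        """Aggregate per-value counts (last axis = support) into bins."""
        counts = np.asarray(counts, dtype=float)
        return np.add.reduceat(counts, self.edges, axis=-1)

    def labels(self, support_size: int) -> list[str]:
        ends = list(self.edges[1:] - 1) + [support_size - 1]
        return [
            f"{s}" if s == e else f"{s}-{e}" for s, e in zip(self.edges, ends)
        ]


@dataclass
class ChiSquareNull:
    """Simulated null chi-square values with their empirical CDF."""

    statistic: str
    values: np.ndarray
    binning: Binning
    _sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("chi-square values must be non-negative")
        self._sorted = np.sort(self.values)

    @property
    def B(self) -> int:
        return len(self.values)

    def ecdf(self, x) -> np.ndarray | float:
        """Right-continuous ECDF: fraction of null values <= x."""
        out = np.searchsorted(self._sorted, np.asarray(x, dtype=float), side="right")
        return out / self.B


@dataclass
class IndependenceResult:
    """Outcome of the mutual independence test for one statistic."""

    statistic: str
    chisq: float
    critical: float
    p: float
    alpha: float
    B: int
    n: int
    binning: Binning
    null: ChiSquareNull
    share_mode: str | None = None
    seed: int | None = None

    @property
    def reject(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "chisq": self.chisq,
            "critical_value": self.critical,
            "p_value": self.p,
            "alpha": self.alpha,
            "reject": self.reject,
            "B": self.B,
            "n": self.n,
            "n_bins": self.binning.n_bins,
            "share_mode": self.share_mode,
            "seed": self.seed,
        }


# ----------------------------------------------------------------------

def bin_support(
    expected: DiscreteDistribution, n: int, min_expected: float = 5.0
) -> Binning:
    """Partition the support so every bin's expected count is >= min_expected.

    Bins are built greedily from both tails inward toward the mode; any
    still-deficient bin is then merged with its neighbour on the mode side.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = expected.probs
    if p.max() > 1.0 - 1e-12:
        raise ValueError("no variation under null: distribution is degenerate")
    if n * p.sum() < 2 * min_expected:
        raise ValueError(
            f"total expected count {n * p.sum():.3g} cannot support two bins "
            f"of >= {min_expected}"
        )
    exp = n * p
    mode = int(np.argmax(p))

    bins: list[tuple[int, int]] = []  # inclusive (start, end)
    # left tail -> mode
    start, cum = 0, 0.0
    for i in range(mode + 1):
        cum += exp[i]
        if cum >= min_expected:
            bins.append((start, i))
            start, cum = i + 1, 0.0
    if start <= mode:  # leftover under-filled stretch next to the mode
        if bins:
            s, _ = bins.pop()
            bins.append((s, mode))
        else:
            bins.append((0, mode))
    # right tail -> mode
    right: list[tuple[int, int]] = []
    end, cum = len(p) - 1, 0.0
    for i in range(len(p) - 1, mode, -1):
        cum += exp[i]
        if cum >= min_expected:
            right.append((i, end))
            end, cum = i - 1, 0.0
    if end > mode:
        if right:
            _, e = right.pop()
            right.append((mode + 1, e))
        else:
            right.append((mode + 1, end))
    bins.extend(reversed(right))

    # mop up any bin still under the threshold by merging toward the mode
    def bin_mass(b: tuple[int, int]) -> float:
        return float(exp[b[0] : b[1] + 1].sum())

    changed = True
    while changed and len(bins) > 1:
        changed = False
        for idx, b in enumerate(bins):
            if bin_mass(b) < min_expected:
                if b[1] < mode:
                    other = idx + 1
                elif b[0] > mode:
                    other = idx - 1
                else:
                    other = idx + 1 if idx + 1 < len(bins) else idx - 1
                lo = min(bins[idx][0], bins[other][0])
                hi = max(bins[idx][1], bins[other][1])
                bins[min(idx, other)] = (lo, hi)
                del bins[max(idx, other)]
                changed = True
                break
    if len(bins) < 2:
        raise ValueError("binning collapsed to a single bin; null has no variation")

    edges = np.array([b[0] for b in bins], dtype=np.int64)
    probs = np.add.reduceat(p, edges)
    return Binning(edges, probs, int(n), float(min_expected))


def chisq_statistic(
    observed_counts: np.ndarray,
    expected: DiscreteDistribution,
    binning: Binning,
) -> float:
    """Pearson X^2 = sum over bins of (O - n p)^2 / (n p)."""
    observed_counts = np.asarray(observed_counts, dtype=float)
    if len(observed_counts) != len(expected.probs):
        raise ValueError("observed counts do not match the expected support")
    total = observed_counts.sum()
    if abs(total - binning.n) > 1e-9:
        raise ValueError(
            f"observed counts sum to {total}, but the binning was built for n={binning.n}"
        )
    o = binning.bin_counts(observed_counts)
    e = binning.n * binning.bin_counts(expected.probs)
    return float((((o - e) ** 2) / e).sum())


# ----------------------------------------------------------------------

def simulate_null_K(h, n: int, B: int, seed=None) -> np.ndarray:
    """B simulated K count vectors for n independent individuals.

    Each replicate is a draw of n individuals whose K follows the exact
    Poisson-binomial pmf of the heterozygosities, recorded as a count
    vector over 0..m (equivalently one multinomial(n, pmf) draw).
    """
    if n < 1 or B < 1:
        raise ValueError("n and B must be >= 1")
    rng = np.random.default_rng(seed)
    pmf = expected_K_distribution(h).probs
    return rng.multinomial(n, pmf / pmf.sum(), size=B)


def simulate_null_X(probs, n_pairs: int, B: int, seed=None) -> np.ndarray:
    """B simulated X count vectors for n_pairs independent pairs."""
    if n_pairs < 1 or B < 1:
        raise ValueError("n_pairs and B must be >= 1")
    rng = np.random.default_rng(seed)
    pmf = expected_X_distribution(probs).probs
    return rng.multinomial(n_pairs, pmf / pmf.sum(), size=B)


def null_chisq_set(
    simulated: np.ndarray,
    expected: DiscreteDistribution,
    binning: Binning,
    statistic: str = "K",
) -> ChiSquareNull:
    """One chi-square value per simulated replicate, with its ECDF."""
    simulated = np.asarray(simulated, dtype=float)
    if simulated.shape[1] != len(expected.probs):
        raise ValueError("simulated replicates do not match the expected support")
    o = binning.bin_counts(simulated)
    e = binning.n * binning.bin_counts(expected.probs)
    values = (((o - e) ** 2) / e).sum(axis=1)
    return ChiSquareNull(statistic, values, binning)


def critical_value(null: ChiSquareNull | np.ndarray, alpha: float = 0.05) -> float:
    """Empirical (1 - alpha) critical value of the simulated null.

    Returns the largest null value whose exceedance probability is still
    >= alpha, so that "observed > critical" agrees with "p < alpha" for
    observed values drawn from the null's support.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    values = null.values if isinstance(null, ChiSquareNull) else np.asarray(null, float)
    vs = np.sort(values)
    B = len(vs)
    t = ceil(alpha * B)
    if t <= 1:  # alpha below the ECDF's resolution: nothing short of the
        return float(vs[-1])  # largest simulated value can ever be rejected
    return float(vs[max(0, B - t - 1)])


def p_value(
    null: ChiSquareNull | np.ndarray, observed: float, add_one: bool = False
) -> float:
    """ECDF p-value 1 - F(observed); add_one uses (1 + #{null >= obs})/(B + 1)."""
    values = null.values if isinstance(null, ChiSquareNull) else np.asarray(null, float)
    if add_one:
        return (1 + int((values >= observed).sum())) / (len(values) + 1)
    return float((values > observed).sum()) / len(values)


# ----------------------------------------------------------------------

def test_independence(
    table: GenotypeTable,
    statistic: str = "K",
    B: int = 500,
    alpha: float = 0.05,
    share_mode: str = "expected",
    hwe: bool = True,
    min_expected: float = 5.0,
    add_one: bool = False,
    seed=None,
    pairs: np.ndarray | None = None,
) -> IndependenceResult:
    """End-to-end mutual independence test on a genotype panel.

    Parameters
    ----------
    statistic :
        ``"K"`` (heterozygous loci per individual) or ``"X"`` (shared
        alleles per random disjoint pair).
    B :
        Number of simulated null panels (>= 100 recommended).
    share_mode :
        For X: ``"expected"`` uses the Weir sharing probabilities from the
        allele frequencies; ``"observed"`` uses the sample proportions.
    hwe :
        For K: use HWE-expected heterozygosities (True) or the observed
        per-marker heterozygosity (False).
    seed :
        Drives the random pairing (X) and the null simulation; the result
        is bit-reproducible given the seed.
    pairs :
        Optional explicit (P, 2) index array fixing the X pairing (the
        pairing is part of the analysis and may be held fixed while the
        null simulation is reseeded); ignored for K.
    """
    if statistic not in {"K", "X"}:
        raise ValueError("statistic must be 'K' or 'X'")
    rng = np.random.default_rng(seed)

    if statistic == "K":
        hm = heterozygosity_matrix(table)
        freqs = allele_freq(table)
        h = locus_heterozygosity(hm, freqs, hwe=hwe)
        expected = expected_K_distribution(h)
        observed = observed_K_distribution(hm)
        simulate = lambda n, B: simulate_null_K(h, n, B, seed=rng)
        mode = None
    else:
        freqs = allele_freq(table)
        shares = allele_share_matrix(table, replacement=False, seed=rng, pairs=pairs)
        if share_mode == "expected":
            probs = expected_share_props(freqs)
        elif share_mode == "observed":
            probs = observed_share_props(shares)
        else:
            raise ValueError("share_mode must be 'expected' or 'observed'")
        expected = expected_X_distribution(probs)
        observed = observed_X_distribution(shares)
        simulate = lambda n, B: simulate_null_X(probs, n, B, seed=rng)
        mode = share_mode

    n = observed.n
    binning = bin_support(expected, n, min_expected=min_expected)
    chisq = chisq_statistic(observed.counts, expected, binning)
    null = null_chisq_set(simulate(n, B), expected, binning, statistic=statistic)
    crit = critical_value(null, alpha=alpha)
    p = p_value(null, chisq, add_one=add_one)
    return IndependenceResult(
        statistic=statistic,
        chisq=chisq,
        critical=crit,
        p=p,
        alpha=alpha,
        B=B,
        n=n,
        binning=binning,
        null=null,
        share_mode=mode,
        seed=seed if isinstance(seed, int) else None,
    )
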