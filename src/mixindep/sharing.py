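"""Allele sharing between pairs of individuals.

Sharing is identity by state: the number of alleles two diploid genotypes
share is the size of the multiset intersection of their allele pairs, so
{A,B} vs {B,B} share one allele and {A,A} vs {A,A} share two. Expected
sharing probabilities for unrelated individuals follow Weir's genotype-pair
enumeration under HWE.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .basics import AlleleFreqTable
from .table import GenotypeTable

__all__ = [
    "AlleleShareMatrix",
    "ShareProbTable",
    "shared_alleles",
    "pair_individuals",
    "all_pairs",
    "allele_share_matrix",
    "observed_share_props",
    "expected_share_props",
]


@dataclass
class AlleleShareMatrix:
    """Pairs x markers matrix of shared-allele counts (0, 1 or 2)."""

    marker_ids: list[str]
    pairs: np.ndarray  # (P, 2) individual indices
    values: np.ndarray  # (P, m) int8; content under mask is 0
    mask: np.ndarray  # (P, m) bool, True = either member missing
    replacement: bool

    def to_frame(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        if sample_ids is None:
            names = [f"{a}-{b}" for a, b in self.pairs]
        else:
            names = [f"{sample_ids[a]}-{sample_ids[b]}" for a, b in self.pairs]
        out = pd.DataFrame(self.values.astype(float), index=names, columns=self.marker_ids)
        out[pd.DataFrame(self.mask, index=names, columns=self.marker_ids)] = np.nan
        return out


@dataclass
class ShareProbTable:
    """Per-marker probabilities (p0, p1, p2) of sharing 0/1/2 alleles."""

    marker_ids: list[str]
    probs: np.ndarray  # (m, 3)
    mode: str  # "observed" | "expected"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.marker_ids), 3):
            raise ValueError("share probability table must be markers x 3")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("share probabilities must lie in [0, 1]")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("share probabilities must sum to 1 per marker")


# ----------------------------------------------------------------------

def shared_alleles(genotype_a: tuple[str, str], genotype_b: tuple[str, str]) -> int:
    """Number of IBS-shared alleles between two diploid genotypes (0..2)."""
    ca, cb = Counter(genotype_a), Counter(genotype_b)
    return sum(min(ca[k], cb[k]) for k in ca)


def _shared_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized multiset-intersection size for stacks of allele pairs.

    ``a`` and ``b`` have shape (..., 2). For size-2 multisets the
    intersection size is min(#A-elements found in B, #B-elements found in A).
    """
    m11 = a[..., 0] == b[..., 0]
    m12 = a[..., 0] == b[..., 1]
    m21 = a[..., 1] == b[..., 0]
    m22 = a[..., 1] == b[..., 1]
    x = (m11 | m12).astype(np.int8) + (m21 | m22).astype(np.int8)
    y = (m11 | m21).astype(np.int8) + (m12 | m22).astype(np.int8)
    return np.minimum(x, y)


def pair_individuals(n: int, replacement: bool = False, seed=None) -> np.ndarray:
    """Random pairing of ``n`` individuals (index pairs, shape (P, 2)).

    Without replacement: a uniform random permutation cut into floor(n/2)
    disjoint consecutive pairs (for odd n one individual is left out). With
    replacement: n pairs drawn uniformly from all unordered pairs of
    distinct individuals.
    """
    if n < 2:
        raise ValueError("pairing requires at least two individuals")
    rng = np.random.default_rng(seed)
    if not replacement:
        perm = rng.permutation(n)
        n_pairs = n // 2
        return perm[: 2 * n_pairs].reshape(n_pairs, 2)
    out = np.empty((n, 2), dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.integers(0, n, size=(n - filled, 2))
        draw = draw[draw[:, 0] != draw[:, 1]]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    out.sort(axis=1)
    return out


def all_pairs(n: int) -> np.ndarray:
    """Exhaustive list of the C(n, 2) unordered pairs of distinct individuals."""
    if n < 2:
        raise ValueError("pairing requires at least two individuals")
    return np.array(list(combinations(range(n), 2)), dtype=np.int64)


def allele_share_matrix(
    table: GenotypeTable,
    replacement: bool = False,
    seed=None,
    pairs: np.ndarray | None = None,
) -> AlleleShareMatrix:
    """Shared-allele counts for random pairs of individuals at every marker.

    Pairs are drawn once for the whole table (a pair shares a row across
    markers). A pair is masked at a marker where either member is missing.
    ``pairs`` overrides the random pairing with an explicit (P, 2) index
    array.
    """
    if pairs is None:
        pairs = pair_individuals(table.n_samples, replacement=replacement, seed=seed)
    else:
        pairs = np.asarray(pairs, dtype=np.int64)
    a = table.alleles[pairs[:, 0]]
    b = table.alleles[pairs[:, 1]]
    values = _shared_counts(a, b)
    mask = table.missing[pairs[:, 0]] | table.missing[pairs[:, 1]]
    values = values.copy()
    values[mask] = 0
    return AlleleShareMatrix(list(table.marker_ids), pairs, values, mask, replacement)


def observed_share_props(shares: AlleleShareMatrix) -> ShareProbTable:
    """Per-marker relative frequencies of sharing 0, 1 or 2 alleles."""
    m = len(shares.marker_ids)
    probs = np.empty((m, 3))
    for j, marker in enumerate(shares.marker_ids):
        ok = ~shares.mask[:, j]
        if not ok.any():
            raise ValueError(f"marker {marker}: no pair with complete genotypes")
        counts = np.bincount(shares.values[ok, j], minlength=3)[:3]
        probs[j] = counts / counts.sum()
    return ShareProbTable(list(shares.marker_ids), probs, "observed")


def expected_share_props(freqs: AlleleFreqTable) -> ShareProbTable:
    """Weir probabilities of sharing 0/1/2 alleles for unrelated pairs.

    For each marker, all unordered genotypes are enumerated with their HWE
    probabilities (p_i^2, 2 p_i p_j); two genotypes are drawn independently
    and p_k sums the probability of genotype pairs sharing exactly k alleles.
    """
    m = len(freqs.marker_ids)
    probs = np.empty((m, 3))
    for j, marker in enumerate(freqs.marker_ids):
        p = np.array(list(freqs.freqs[marker].values()))
        k = len(p)
        ii, jj = np.triu_indices(k)
        gprob = np.where(ii == jj, p[ii] * p[jj], 2 * p[ii] * p[jj])
        geno = np.stack([ii, jj], axis=-1)  # (G, 2) allele codes
        s = _shared_counts(geno[:, None, :], geno[None, :, :])
        w = gprob[:, None] * gprob[None, :]
        probs[j] = [w[s == c].sum() for c in range(3)]
        probs[j] /= probs[j].sum()  # guard fp drift; sums to 1 analytically
    return ShareProbTable(list(freqs.marker_ids), probs, "expected")
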