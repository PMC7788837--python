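"""Per-marker genetics: allele/genotype frequencies, heterozygosity, HWE.

All quantities are computed marker by marker. An individual missing at
marker *j* is excluded from marker *j*'s counts only; panel-wide statistics
(distributions of K and X) apply their own complete-case policy downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .table import GenotypeTable

__all__ = [
    "AlleleFreqTable",
    "GenotypeFreqTable",
    "HeteroMatrix",
    "HeterozygosityVector",
    "allele_freq",
    "genotype_freq",
    "heterozygosity_matrix",
    "locus_heterozygosity",
    "hwe_test",
]

Genotype = tuple[str, str]  # sorted allele pair


@dataclass
class AlleleFreqTable:
    """Per-marker map allele label -> relative frequency (p_i)."""

    marker_ids: list[str]
    freqs: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for marker in self.marker_ids:
            f = self.freqs[marker]
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"marker {marker}: allele frequencies sum to {total}")
            if any(v <= 0 or v > 1 for v in f.values()):
                raise ValueError(f"marker {marker}: frequencies must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Alleles x markers frequency table (absent allele -> 0)."""
        return pd.DataFrame(self.freqs).reindex(columns=self.marker_ids).fillna(0.0)


@dataclass
class GenotypeFreqTable:
    """Per-marker unordered-genotype counts (observed) or probabilities (expected)."""

    marker_ids: list[str]
    values: dict[str, dict[Genotype, float]]
    mode: str  # "observed" | "expected"
    n: dict[str, int]  # non-missing individuals per marker

    def __post_init__(self) -> None:
        if self.mode not in {"observed", "expected"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        for marker in self.marker_ids:
            total = sum(self.values[marker].values())
            if self.mode == "expected" and abs(total - 1.0) > 1e-9:
                raise ValueError(f"marker {marker}: expected probabilities sum to {total}")
            if self.mode == "observed" and abs(total - self.n[marker]) > 1e-9:
                raise ValueError(
                    f"marker {marker}: observed counts sum to {total}, "
                    f"expected {self.n[marker]}"
                )


@dataclass
class HeteroMatrix:
    """Individuals x markers heterozygosity indicators (1 = heterozygous)."""

    sample_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray  # (n, m) int8; content under mask is 0
    mask: np.ndarray  # (n, m) bool, True = missing

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            self.values.astype(float), index=self.sample_ids, columns=self.marker_ids
        )
        out[pd.DataFrame(self.mask, index=self.sample_ids, columns=self.marker_ids)] = np.nan
        return out


@dataclass
class HeterozygosityVector:
    """Per-marker heterozygosity h_m with its provenance mode."""

    marker_ids: list[str]
    values: np.ndarray
    mode: str  # "observed" | "hwe"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("heterozygosity must lie in [0, 1]")


# ----------------------------------------------------------------------

def allele_freq(table: GenotypeTable) -> AlleleFreqTable:
    """Relative allele frequencies per marker (homozygotes count twice)."""
    freqs: dict[str, dict[str, float]] = {}
    for j, marker in enumerate(table.marker_ids):
        ok = ~table.missing[:, j]
        if not ok.any():
            raise ValueError(f"marker {marker}: all genotypes missing")
        labels = table.alleles[ok, j, :].ravel()
        uniq, counts = np.unique(labels.astype(str), return_counts=True)
        total = counts.sum()
        freqs[marker] = {a: c / total for a, c in zip(uniq, counts)}
    return AlleleFreqTable(list(table.marker_ids), freqs)


def genotype_freq(table: GenotypeTable, expected: bool = False) -> GenotypeFreqTable:
    """Observed genotype counts, or HWE-expected genotype probabilities.

    Genotypes are unordered: ``A|T`` and ``T|A`` are one category. Expected
    mode enumerates every allele pair with non-zero frequency and assigns
    p_i^2 to homozygotes and 2 p_i p_j to heterozygotes.
    """
    n_per_marker = {
        marker: int((~table.missing[:, j]).sum())
        for j, marker in enumerate(table.marker_ids)
    }
    if expected:
        af = allele_freq(table)
        values: dict[str, dict[Genotype, float]] = {}
        for marker in table.marker_ids:
            p = af.freqs[marker]
            alleles = sorted(p)
            probs: dict[Genotype, float] = {}
            for i, a in enumerate(alleles):
                for b in alleles[i:]:
                    probs[(a, b)] = p[a] ** 2 if a == b else 2 * p[a] * p[b]
            values[marker] = probs
        return GenotypeFreqTable(list(table.marker_ids), values, "expected", n_per_marker)

    values = {}
    for j, marker in enumerate(table.marker_ids):
        counts: dict[Genotype, float] = {}
        for i in range(table.n_samples):
            pair = table.cell(i, j)
            if pair is not None:
                counts[pair] = counts.get(pair, 0.0) + 1.0
        values[marker] = counts
    return GenotypeFreqTable(list(table.marker_ids), values, "observed", n_per_marker)


def heterozygosity_matrix(table: GenotypeTable) -> HeteroMatrix:
    """Indicator matrix: 1 where the two allele labels of a cell differ."""
    values = (table.alleles[:, :, 0] != table.alleles[:, :, 1]).astype(np.int8)
    values[table.missing] = 0
    return HeteroMatrix(
        list(table.sample_ids), list(table.marker_ids), values, table.missing.copy()
    )


def locus_heterozygosity(
    h_matrix: HeteroMatrix,
    freqs: AlleleFreqTable | None = None,
    hwe: bool = False,
) -> HeterozygosityVector:
    """Per-marker heterozygosity.

    ``hwe=True`` returns the HWE expectation 1 - sum(p_i^2) from ``freqs``;
    ``hwe=False`` returns the observed column mean of the indicator matrix.
    """
    if hwe:
        if freqs is None:
            raise ValueError("hwe=True requires an allele frequency table")
        if freqs.marker_ids != h_matrix.marker_ids:
            raise ValueError("marker sets of heterozygosity matrix and frequencies differ")
        values = np.array(
            [1.0 - sum(p * p for p in freqs.freqs[m].values()) for m in freqs.marker_ids]
        )
        return HeterozygosityVector(list(h_matrix.marker_ids), values, "hwe")
    ok = ~h_matrix.mask
    counts = ok.sum(axis=0)
    if np.any(counts == 0):
        bad = [m for m, c in zip(h_matrix.marker_ids, counts) if c == 0]
        raise ValueError(f"markers with no observed genotypes: {bad}")
    values = (h_matrix.values * ok).sum(axis=0) / counts
    return HeterozygosityVector(list(h_matrix.marker_ids), values, "observed")


# ----------------------------------------------------------------------

def hwe_test(
    observed: GenotypeFreqTable,
    expected: GenotypeFreqTable,
    rescale: bool = True,
    simulate_p: bool = True,
    B: int = 2000,
    seed=None,
) -> pd.Series:
    """Pearson chi-square test of HWE per marker.

    The observed genotype counts are compared to ``n * p_expected`` over the
    union of the two genotype supports. With ``simulate_p`` the null
    distribution of X^2 is simulated by drawing B multinomial tables from
    the expected probabilities and the p-value uses the add-one estimator
    ``(1 + #{X^2_sim >= X^2_obs}) / (B + 1)``; otherwise the asymptotic
    chi-square tail with df = #categories - 1 is used.
    """
    if observed.mode != "observed" or expected.mode != "expected":
        raise ValueError("hwe_test needs an observed and an expected genotype table")
    if observed.marker_ids != expected.marker_ids:
        raise ValueError("marker sets differ between observed and expected tables")
    if simulate_p and B < 1:
        raise ValueError("B must be >= 1 when simulate_p is set")
    rng = np.random.default_rng(seed)

    pvalues = {}
    for marker in observed.marker_ids:
        obs, exp = observed.values[marker], expected.values[marker]
        support = sorted(set(obs) | set(exp))
        o = np.array([obs.get(g, 0.0) for g in support])
        p = np.array([exp.get(g, 0.0) for g in support])
        if np.any((p == 0) & (o > 0)) and not rescale:
            raise ValueError(
                f"marker {marker}: observed genotype with zero expected probability "
                "(set rescale=True to renormalize)"
            )
        keep = p > 0
        o, p = o[keep], p[keep]
        if rescale:
            p = p / p.sum()
        n = o.sum()
        e = n * p
        x2 = float((((o - e) ** 2) / e).sum())
        if simulate_p:
            sims = rng.multinomial(int(n), p, size=B)
            x2_sim = (((sims - e) ** 2) / e).sum(axis=1)
            pvalues[marker] = (1 + int((x2_sim >= x2).sum())) / (B + 1)
        else:
            df = len(p) - 1
            pvalues[marker] = float(stats.chi2.sf(x2, df)) if df > 0 else 1.0
    return pd.Series(pvalues, name="hwe_p")
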