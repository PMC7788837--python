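"""Synthetic mixed SNP/STR panels and the power study.

Panels hold an even number of markers, half SNPs and half STRs. Unlinked
loci draw genotypes independently under HWE. Linked loci live in a single
block driven by a latent haplotype-class pair: each individual draws two
class indices i.i.d. from Dirichlet class frequencies, and every locus in
the block maps classes to alleles through a fixed random map, so all block
loci are functions of the same latent pair (strong LD) while each locus
taken alone still satisfies HWE.

The design grid follows the published rules: linkage levels Unlinked,
OnePair, HalfQuarter (12.5%), Quarter, Half, ThreeQuarter, Almost (all but
one pair) and Fully, each biased toward SNPs, STRs, or balanced ("Both").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .independence import test_independence
from .table import GenotypeTable

__all__ = [
    "MarkerModel",
    "PanelDesign",
    "LINKAGE_LEVELS",
    "sample_marker_model",
    "simulate_unlinked",
    "simulate_linked_block",
    "build_panel",
    "power_study",
]

NUCLEOTIDES = np.array(["A", "C", "G", "T"], dtype=object)

#: linkage label -> fraction (or fixed count rule) of linked markers
LINKAGE_LEVELS = (
    "Unlinked",
    "OnePair",
    "HalfQuarter",
    "Quarter",
    "Half",
    "ThreeQuarter",
    "Almost",
    "Fully",
)


@dataclass
class MarkerModel:
    """Allele labels and population frequencies of one simulated marker."""

    marker_type: str  # "SNP" | "STR"
    labels: list[str]
    freqs: np.ndarray
    block: int | None = None  # linked-block membership

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("marker model frequencies must sum to 1")
        if self.marker_type == "SNP" and len(self.labels) != 2:
            raise ValueError("a SNP model must have exactly two alleles")

    @property
    def heterozygosity(self) -> float:
        return float(1.0 - (self.freqs**2).sum())


@dataclass
class PanelDesign:
    """One row of the power-study design grid."""

    panel_size: int  # even; half SNPs, half STRs
    n_linked: int
    n_linked_snps: int
    n_linked_strs: int
    linkage: str
    bias: str  # "SNP" | "STR" | "Both"

    def __post_init__(self) -> None:
        x = self.panel_size
        if x < 2 or x % 2:
            raise ValueError("panel_size must be an even number >= 2")
        if self.linkage not in LINKAGE_LEVELS:
            raise ValueError(f"unknown linkage level {self.linkage!r}")
        if self.bias not in {"SNP", "STR", "Both"}:
            raise ValueError(f"unknown bias {self.bias!r}")
        if self.n_linked_snps + self.n_linked_strs != self.n_linked:
            raise ValueError("linked SNPs + linked STRs must equal n_linked")
        if self.n_linked_snps > x // 2 or self.n_linked_strs > x // 2:
            raise ValueError("linked markers of one type exceed the panel's half")
        if self.n_linked == 1 or self.n_linked > x:
            raise ValueError("n_linked must be 0 or in 2..panel_size")
        if self.bias == "Both" and self.n_linked_snps != self.n_linked_strs:
            raise ValueError("bias 'Both' requires equally many linked SNPs and STRs")
        expected_n = _linked_count(self.linkage, x)
        if self.n_linked != expected_n:
            raise ValueError(
                f"linkage {self.linkage!r} at panel size {x} requires "
                f"{expected_n} linked markers, got {self.n_linked}"
            )

    @classmethod
    def from_rules(cls, panel_size: int, linkage: str, bias: str) -> "PanelDesign":
        """Apply the design-grid rules for one (size, linkage, bias) cell."""
        x = panel_size
        n_linked = _linked_count(linkage, x)
        half = x // 2
        if linkage == "Unlinked":
            snps, strs = 0, 0
            bias = "Both"  # the grid defines no biased unlinked rows
        elif linkage == "OnePair":
            if bias == "Both":
                raise ValueError("OnePair linkage is only defined for SNP or STR bias")
            snps, strs = (2, 0) if bias == "SNP" else (0, 2)
        elif linkage == "Almost":
            if bias == "Both":
                raise ValueError("Almost linkage is only defined for SNP or STR bias")
            snps, strs = (half, n_linked - half)
            if bias == "STR":
                snps, strs = strs, snps
        elif linkage == "Fully":
            snps = strs = half
            bias = "Both"
        else:  # fractional levels: HalfQuarter, Quarter, Half, ThreeQuarter
            if bias == "Both":
                if n_linked % 2:
                    raise ValueError(
                        f"{linkage} at size {x} cannot be split evenly between types"
                    )
                snps = strs = n_linked // 2
            else:
                # all linked markers on the biased type, overflowing onto the
                # other type once the biased half is exhausted
                on_bias = min(n_linked, half)
                snps, strs = (on_bias, n_linked - on_bias)
                if bias == "STR":
                    snps, strs = strs, snps
        return cls(x, n_linked, snps, strs, linkage, bias)


def _linked_count(linkage: str, x: int) -> int:
    frac = {"HalfQuarter": 0.125, "Quarter": 0.25, "Half": 0.5, "ThreeQuarter": 0.75}
    if linkage == "Unlinked":
        return 0
    if linkage == "OnePair":
        return 2
    if linkage == "Almost":
        return x - 2
    if linkage == "Fully":
        return x
    n = frac[linkage] * x
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"linkage {linkage!r} is not an integer count at size {x}")
    return int(round(n))


# ----------------------------------------------------------------------

def sample_marker_model(marker_type: str, rng=None) -> MarkerModel:
    """Draw one marker model.

    SNP: two distinct nucleotides with minor-allele frequency ~ U(0.1, 0.5).
    STR: 5..10 alleles with flat-Dirichlet frequencies, re-drawn until the
    heterozygosity is at least 0.5 (microsatellites are highly polymorphic).
    """
    rng = np.random.default_rng(rng)
    if marker_type == "SNP":
        labels = list(rng.choice(NUCLEOTIDES, size=2, replace=False))
        maf = rng.uniform(0.1, 0.5)
        return MarkerModel("SNP", labels, np.array([1.0 - maf, maf]))
    if marker_type == "STR":
        k = int(rng.integers(5, 11))
        start = int(rng.integers(5, 16))
        labels = [str(start + i) for i in range(k)]
        while True:
            freqs = rng.dirichlet(np.ones(k))
            if 1.0 - (freqs**2).sum() >= 0.5:
                return MarkerModel("STR", labels, freqs)
    raise ValueError(f"unknown marker type {marker_type!r}")


def simulate_unlinked(models: list[MarkerModel], n: int, seed=None) -> GenotypeTable:
    """HWE genotypes at mutually independent loci."""
    if any(m.block is not None for m in models):
        raise ValueError("simulate_unlinked requires models without block membership")
    rng = np.random.default_rng(seed)
    alleles = np.empty((n, len(models), 2), dtype=object)
    for j, model in enumerate(models):
        alleles[:, j, :] = _draw_hwe_column(model, n, rng)
    return _as_table(models, alleles)


def _draw_hwe_column(model: MarkerModel, n: int, rng) -> np.ndarray:
    codes = rng.choice(len(model.labels), size=(n, 2), p=model.freqs)
    return np.array(model.labels, dtype=object)[codes]


def simulate_linked_block(
    models: list[MarkerModel], n: int, n_hap_classes: int = 6, rng=None
) -> np.ndarray:
    """Genotype columns for one block of markers in strong LD.

    Haplotype-class frequencies are Dirichlet(1); each individual draws two
    class indices i.i.d.; each locus carries a fixed random map class ->
    allele (SNP: balanced 2-partition of the classes; STR: map onto
    min(n_alleles, n_classes) alleles with every allele hit at least once).
    Because the two classes are drawn i.i.d., each locus alone is in HWE.

    Returns an object array of shape (n, len(models), 2).
    """
    if len(models) < 2:
        raise ValueError("a linked block needs at least two loci")
    if n_hap_classes < 2:
        raise ValueError("n_hap_classes must be >= 2")
    rng = np.random.default_rng(rng)
    class_freqs = rng.dirichlet(np.ones(n_hap_classes))
    classes = rng.choice(n_hap_classes, size=(n, 2), p=class_freqs)
    out = np.empty((n, len(models), 2), dtype=object)
    for j, model in enumerate(models):
        k = len(model.labels)
        if model.marker_type == "SNP":
            perm = rng.permutation(n_hap_classes)
            cls_to_allele = np.zeros(n_hap_classes, dtype=np.int64)
            cls_to_allele[perm[n_hap_classes // 2 :]] = 1
        else:
            k_eff = min(k, n_hap_classes)
            perm = rng.permutation(n_hap_classes)
            cls_to_allele = np.empty(n_hap_classes, dtype=np.int64)
            cls_to_allele[perm[:k_eff]] = np.arange(k_eff)  # surjective part
            if n_hap_classes > k_eff:
                cls_to_allele[perm[k_eff:]] = rng.integers(0, k_eff, n_hap_classes - k_eff)
        out[:, j, :] = np.array(model.labels, dtype=object)[cls_to_allele[classes]]
    return out


def build_panel(design: PanelDesign, n: int, seed=None) -> GenotypeTable:
    """Simulate one panel following a design-grid row.

    Linked markers share a single latent block; all other markers are
    mutually independent; column order is randomized. Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    half = design.panel_size // 2
    snp_models = [sample_marker_model("SNP", rng) for _ in range(half)]
    str_models = [sample_marker_model("STR", rng) for _ in range(half)]
    for model in snp_models[: design.n_linked_snps]:
        model.block = 0
    for model in str_models[: design.n_linked_strs]:
        model.block = 0

    models = snp_models + str_models
    alleles = np.empty((n, design.panel_size, 2), dtype=object)
    linked_idx = [j for j, m in enumerate(models) if m.block == 0]
    if linked_idx:
        block = simulate_linked_block([models[j] for j in linked_idx], n, rng=rng)
        for col, j in enumerate(linked_idx):
            alleles[:, j, :] = block[:, col, :]
    for j, model in enumerate(models):
        if model.block is None:
            alleles[:, j, :] = _draw_hwe_column(model, n, rng)

    order = rng.permutation(design.panel_size)
    return _as_table([models[j] for j in order], alleles[:, order, :])


def _as_table(models: list[MarkerModel], alleles: np.ndarray) -> GenotypeTable:
    n = alleles.shape[0]
    counters = {"SNP": 0, "STR": 0}
    marker_ids = []
    for model in models:
        counters[model.marker_type] += 1
        marker_ids.append(f"{model.marker_type}{counters[model.marker_type]}")
    return GenotypeTable(
        [f"ind{i + 1}" for i in range(n)],
        marker_ids,
        alleles,
        np.zeros((n, len(models)), dtype=bool),
        marker_types=[m.marker_type for m in models],
    )


# ----------------------------------------------------------------------

def synthetic_reference_panel(
    n: int = 2504, n_snps: int = 94, n_strs: int = 6, seed=None
) -> GenotypeTable:
    """Synthetic stand-in for a pruned real-world mixed reference panel.

    Emulates the shape of an LD-pruned 1000-Genomes-style panel (2504
    individuals, 94 SNPs + 6 STRs) with mutually independent HWE loci. The
    genotypes are simulated, not real data; the panel is meant for worked
    examples and end-to-end checks of the independence pipeline, where the
    truth (mutual independence) must be known.
    """
    rng = np.random.default_rng(seed)
    models = [sample_marker_model("SNP", rng) for _ in range(n_snps)]
    models += [sample_marker_model("STR", rng) for _ in range(n_strs)]
    order = rng.permutation(len(models))
    return simulate_unlinked([models[j] for j in order], n, seed=rng)


def power_study(
    designs: list[PanelDesign],
    n: int = 500,
    trials: int = 1000,
    B: int = 500,
    alpha: float = 0.05,
    seed=None,
    statistics: tuple[str, ...] = ("K", "X"),
    share_mode: str = "expected",
) -> pd.DataFrame:
    """Rejection rate of the independence test over repeated panels.

    For each design, ``trials`` fresh panels of ``n`` individuals are built
    and tested with each statistic; the reported proportion of p < alpha is
    the type-I error for unlinked designs and the power otherwise.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    for design, design_ss in zip(designs, root.spawn(len(designs))):
        rejections = {s: 0 for s in statistics}
        for trial_ss in design_ss.spawn(trials):
            streams = trial_ss.spawn(1 + len(statistics))
            panel = build_panel(design, n, seed=streams[0])
            for s, stream in zip(statistics, streams[1:]):
                result = test_independence(
                    panel, statistic=s, B=B, alpha=alpha,
                    share_mode=share_mode, seed=np.random.default_rng(stream),
                )
                rejections[s] += result.reject
        row = {
            "panel_size": design.panel_size,
            "n_linked": design.n_linked,
            "linkage": design.linkage,
            "bias": design.bias,
        }
        for s in statistics:
            row[f"power_{s}"] = rejections[s] / trials
        row.update({"n": n, "trials": trials, "B": B, "alpha": alpha})
        rows.append(row)
    return pd.DataFrame(rows)
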