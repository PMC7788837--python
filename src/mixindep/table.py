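"""Diploid genotype matrix container shared by every module.

A :class:`GenotypeTable` is a rectangular individuals x markers matrix whose
cells hold an *unordered* pair of allele labels. Labels are opaque strings:
a SNP allele ("A"), an STR repeat number ("12") and an indel label are all
treated identically, because the independence test only ever compares labels
for equality. Phase is never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeTable"]


@dataclass
class GenotypeTable:
    """Individuals x markers matrix of unordered diploid allele pairs.

    Parameters
    ----------
    sample_ids :
        One opaque identifier per row (individual).
    marker_ids :
        One opaque identifier per column (marker).
    alleles :
        Object array of shape ``(n_samples, n_markers, 2)`` of allele labels.
        The order of the two labels within a cell carries no meaning.
    missing :
        Boolean mask of shape ``(n_samples, n_markers)``; ``True`` marks a
        cell with no usable genotype. The ``alleles`` content under a missing
        cell is ignored.
    marker_types :
        Optional per-marker label (``"SNP"``, ``"STR"``, ``"other"``).
        Informational only; no computation branches on it.
    n_bad_cells :
        Number of input cells that could not be parsed into two alleles and
        were therefore recorded as missing (set by the readers).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    alleles: np.ndarray
    missing: np.ndarray
    marker_types: list[str] | None = None
    n_bad_cells: int = 0

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = len(self.sample_ids), len(self.marker_ids)
        if n == 0 or m == 0:
            raise ValueError("genotype table must have at least one individual and one marker")
        if self.alleles.shape != (n, m, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n} individuals x {m} markers x 2"
            )
        if self.missing.shape != (n, m):
            raise ValueError("missing mask shape does not match the table")
        if self.marker_types is not None and len(self.marker_types) != m:
            raise ValueError("marker_types length does not match the marker count")
        ok = ~self.missing
        for k in range(2):
            lab = self.alleles[:, :, k][ok]
            if lab.size and np.any(lab == ""):
                raise ValueError("non-missing cells must contain two non-empty allele labels")

    # ------------------------------------------------------------------
    @classmethod
    def from_cells(
        cls,
        sample_ids: list[str],
        marker_ids: list[str],
        cells: list[list[tuple[str, str] | None]],
        marker_types: list[str] | None = None,
    ) -> "GenotypeTable":
        """Build a table from nested lists; ``None`` marks a missing cell."""
        n, m = len(sample_ids), len(marker_ids)
        alleles = np.empty((n, m, 2), dtype=object)
        missing = np.zeros((n, m), dtype=bool)
        for i in range(n):
            for j in range(m):
                cell = cells[i][j]
                if cell is None:
                    missing[i, j] = True
                    alleles[i, j] = ("", "")
                else:
                    alleles[i, j] = (str(cell[0]), str(cell[1]))
        return cls(list(sample_ids), list(marker_ids), alleles, missing, marker_types)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def cell(self, i: int, j: int) -> tuple[str, str] | None:
        """Unordered (sorted) allele pair of one cell, or None if missing."""
        if self.missing[i, j]:
            return None
        a, b = self.alleles[i, j]
        return (a, b) if a <= b else (b, a)

    def sorted_alleles(self) -> np.ndarray:
        """Copy of the allele array with each cell's labels sorted."""
        out = self.alleles.copy()
        swap = out[:, :, 0] > out[:, :, 1]
        out[swap] = out[swap][:, ::-1]
        return out

    def equals(self, other: "GenotypeTable") -> bool:
        """Equality on ids, missingness and *unordered* allele pairs."""
        if self.sample_ids != other.sample_ids or self.marker_ids != other.marker_ids:
            return False
        if not np.array_equal(self.missing, other.missing):
            return False
        a, b = self.sorted_alleles(), other.sorted_alleles()
        ok = ~self.missing
        return bool(np.all((a == b)[ok]))
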