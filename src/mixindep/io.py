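"""Readers and writers for genotype matrices (tabular files and VCF).

Tabular layout: first row = marker names, first column = sample IDs, each
cell an allele pair joined by a separator, e.g. ``12|13`` or ``A/T``. The
separator is matched literally (no regex escaping needed). VCF input uses
the GT field only; allele indices are resolved to REF/ALT strings and phase
is discarded.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .table import GenotypeTable

__all__ = [
    "read_genotypes_table",
    "write_genotypes_table",
    "read_vcf_gt",
    "write_vcf",
]


def _read_frame(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        return pd.read_excel(path, index_col=0, dtype=str)
    sep = "\t" if suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, index_col=0, dtype=str, sep=sep)


def read_genotypes_table(path: str | Path, allele_sep: str = "|") -> GenotypeTable:
    """Read a CSV/TSV/XLSX genotype matrix into a :class:`GenotypeTable`.

    Cells that do not split on ``allele_sep`` into exactly two non-empty
    labels (including empty/NaN cells) are recorded as missing; a single
    warning reports how many.
    """
    if not allele_sep:
        raise ValueError("allele_sep must be a non-empty string")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_frame(path)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: genotype table has zero individuals or zero markers")

    n, m = df.shape
    alleles = np.empty((n, m, 2), dtype=object)
    alleles[:] = ""
    missing = np.zeros((n, m), dtype=bool)
    n_bad = 0
    values = df.to_numpy(dtype=object)
    for i in range(n):
        for j in range(m):
            raw = values[i, j]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                missing[i, j] = True
                continue
            parts = str(raw).strip().split(allele_sep)
            if len(parts) != 2 or not parts[0] or not parts[1]:
                missing[i, j] = True
                n_bad += 1
                continue
            alleles[i, j] = (parts[0], parts[1])
    if n_bad:
        warnings.warn(
            f"{path}: {n_bad} cell(s) did not split into two alleles on "
            f"{allele_sep!r} and were recorded as missing",
            stacklevel=2,
        )
    return GenotypeTable(
        [str(s) for s in df.index],
        [str(c) for c in df.columns],
        alleles,
        missing,
        n_bad_cells=n_bad,
    )


def write_genotypes_table(
    table: GenotypeTable, path: str | Path, allele_sep: str = "|"
) -> None:
    """Write a table as CSV/TSV in the tabular layout; missing cells -> ""."""
    if not allele_sep:
        raise ValueError("allele_sep must be a non-empty string")
    path = Path(path)
    cells = np.empty((table.n_samples, table.n_markers), dtype=object)
    for i in range(table.n_samples):
        for j in range(table.n_markers):
            pair = table.cell(i, j)
            cells[i, j] = "" if pair is None else allele_sep.join(pair)
    df = pd.DataFrame(cells, index=table.sample_ids, columns=table.marker_ids)
    df.index.name = "Sample ID"
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df.to_csv(path, sep=sep)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def read_vcf_gt(path: str | Path) -> GenotypeTable:
    """Read the GT field of a VCF into a :class:`GenotypeTable`.

    One marker per record; phased and unphased genotypes are both accepted
    and phase is discarded; ``./.`` becomes a missing cell. Marker id is the
    ID field when present, else ``CHROM:POS``. Haploid or polyploid GTs
    raise a validation error naming the record.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")

    marker_ids: list[str] = []
    marker_types: list[str] = []
    columns: list[list[tuple[str, str] | None]] = []
    for variant in vcf:
        if "GT" not in (variant.FORMAT or []):
            raise ValueError(
                f"{path}: record {variant.CHROM}:{variant.POS} has no GT field"
            )
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ref, alts = variant.REF, list(variant.ALT)
        labels = [ref] + alts
        is_snp = len(ref) == 1 and all(len(a) == 1 for a in alts)
        col: list[tuple[str, str] | None] = []
        for sample, gt in zip(samples, variant.genotypes):
            calls = list(gt[:-1])  # last element is the phased flag
            if len(calls) != 2:
                raise ValueError(
                    f"{path}: record {name}, sample {sample}: ploidy "
                    f"{len(calls)} genotype (only diploid GT is supported)"
                )
            if any(c < 0 for c in calls):
                col.append(None)
            else:
                col.append((labels[calls[0]], labels[calls[1]]))
        marker_ids.append(name)
        marker_types.append("SNP" if is_snp else "other")
        columns.append(col)
    vcf.close()
    if not marker_ids:
        raise ValueError(f"{path}: VCF contains no variant records")
    cells = [[columns[j][i] for j in range(len(marker_ids))] for i in range(len(samples))]
    alleles, missing = _cells_to_arrays(cells)
    return GenotypeTable(samples, marker_ids, alleles, missing, marker_types)


def _cells_to_arrays(cells):
    n, m = len(cells), len(cells[0])
    alleles = np.empty((n, m, 2), dtype=object)
    alleles[:] = ""
    missing = np.zeros((n, m), dtype=bool)
    for i in range(n):
        for j in range(m):
            if cells[i][j] is None:
                missing[i, j] = True
            else:
                alleles[i, j] = cells[i][j]
    return alleles, missing


def write_vcf(table: GenotypeTable, path: str | Path, chrom: str = "1") -> None:
    """Write a minimal single-chromosome VCF 4.2 (GT only) for a table.

    Each marker becomes one record at POS = column index + 1; REF is the
    lexicographically first allele observed at the marker. Intended for
    fixtures and format conversion, not for annotated variant data.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={chrom}>",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += table.sample_ids
    lines.append("\t".join(header))
    for j, marker in enumerate(table.marker_ids):
        observed: set[str] = set()
        for i in range(table.n_samples):
            pair = table.cell(i, j)
            if pair is not None:
                observed.update(pair)
        if not observed:
            raise ValueError(f"marker {marker}: all cells missing, cannot write VCF record")
        labels = sorted(observed)
        code = {a: k for k, a in enumerate(labels)}
        ref, alts = labels[0], labels[1:]
        alt_field = ",".join(alts) if alts else "."
        row = [chrom, str(j + 1), marker, ref, alt_field, ".", "PASS", ".", "GT"]
        for i in range(table.n_samples):
            pair = table.cell(i, j)
            if pair is None:
                row.append("./.")
            else:
                a, b = sorted(code[x] for x in pair)
                row.append(f"{a}/{b}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
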