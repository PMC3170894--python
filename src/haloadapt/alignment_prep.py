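"""Column masks and catalytic-site conservation checks.

Conserved-block selection itself (GBLOCKS-style) is consumed as input: a mask
is an explicit, strictly increasing list of 1-based amino-acid column indices.
``codon_mask`` applies the same mask to the matching in-frame nucleotide
alignment, keeping nt columns {3i-2, 3i-1, 3i} for each kept aa column i.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seqio import Alignment


@dataclass(frozen=True)
class ColumnMask:
    """Ordered 1-based aa column indices to keep."""

    keep: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.keep:
            raise ValueError("empty mask")
        if any(k < 1 for k in self.keep):
            raise ValueError("mask indices are 1-based and must be >= 1")
        if any(b <= a for a, b in zip(self.keep, self.keep[1:])):
            raise ValueError("mask indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.keep)


@dataclass(frozen=True)
class SiteSpec:
    """An expected catalytic residue at a 1-based masked-alignment column,
    e.g. Arg at the column homologous to AprA position alpha-265."""

    name: str
    expected_residue: str
    column: int

    def __post_init__(self) -> None:
        if len(self.expected_residue) != 1:
            raise ValueError("expected_residue must be a single letter")
        if self.column < 1:
            raise ValueError("site columns are 1-based")


def read_mask(path: str | Path) -> ColumnMask:
    """Mask file: one 1-based index per line (blank lines ignored)."""
    with open(path) as fh:
        idx = [int(line) for line in fh if line.strip()]
    return ColumnMask(tuple(idx))


def read_site_specs(path: str | Path) -> list[SiteSpec]:
    """Site spec TSV with columns name, residue, column."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "residue": str, "column": int})
    return [
        SiteSpec(row["name"], row["residue"], int(row["column"]))
        for _, row in df.iterrows()
    ]


def apply_mask(aa_alignment: Alignment, mask: ColumnMask) -> Alignment:
    """Keep only the masked aa columns (mask indices 1-based)."""
    if mask.keep[-1] > aa_alignment.length:
        raise ValueError(
            f"mask index {mask.keep[-1]} exceeds alignment length {aa_alignment.length}"
        )
    cols = [k - 1 for k in mask.keep]
    records = [
        replace(r, seq="".join(r.seq[c] for c in cols)) for r in aa_alignment.records
    ]
    return Alignment(records, codon_aligned=False)


def codon_mask(nt_alignment: Alignment, mask: ColumnMask) -> Alignment:
    """Keep the nt codon triplets matching the masked aa columns."""
    if not nt_alignment.codon_aligned:
        raise ValueError("codon_mask requires a codon-aligned nucleotide alignment")
    n_codons = nt_alignment.length // 3
    if mask.keep[-1] > n_codons:
        raise ValueError(f"mask index {mask.keep[-1]} exceeds codon count {n_codons}")
    cols: list[int] = []
    for k in mask.keep:
        cols.extend((3 * k - 3, 3 * k - 2, 3 * k - 1))
    records = [
        replace(r, seq="".join(r.seq[c] for c in cols)) for r in nt_alignment.records
    ]
    return Alignment(records, codon_aligned=True)


def site_conservation(
    masked_alignment: Alignment, sitespecs: Sequence[SiteSpec]
) -> pd.DataFrame:
    """Per-site fraction of sequences carrying the expected residue.

    Gaps (and any other residue) count as non-conserved. Returns a DataFrame
    with columns name, expected, column, fraction, nonmatching_ids.
    """
    rows = []
    for spec in sitespecs:
        if spec.column > masked_alignment.length:
            raise ValueError(
                f"site {spec.name}: column {spec.column} exceeds alignment length"
            )
        c = spec.column - 1
        nonmatch = [
            r.id
            for r in masked_alignment.records
            if r.seq[c].upper() != spec.expected_residue.upper()
        ]
        frac = 1 - len(nonmatch) / len(masked_alignment)
        rows.append(
            {
                "name": spec.name,
                "expected": spec.expected_residue,
                "column": spec.column,
                "fraction": frac,
                "nonmatching_ids": ",".join(nonmatch),
            }
        )
    return pd.DataFrame(rows)
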