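"""GC content, relative synonymous codon usage (RSCU), and correspondence
analysis of RSCU across sequence groups.

GC% = (G + C) / (G + C + A + T) * 100, with gaps and N excluded; positional
GC is reported per codon position for in-frame alignments. RSCU_i is the
observed count of codon i divided by the mean count over its synonymous
family, so every codon of an unbiased family scores 1.00 and family totals
sum to the family size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.stats.ordination import ca as _skbio_ca

from .seqio import CODON_TO_AA, SequenceRecord

BASES = set("ACGT")
GC = set("GC")

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
STOP_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa == "*")

# Synonymous families: amino acid -> codons (stops kept separate).
FAMILIES: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    FAMILIES.setdefault(CODON_TO_AA[_c], []).append(_c)


@dataclass
class GCProfile:
    """Total and per-codon-position GC percentages with counted-base totals."""

    gc_total: float
    counted_total: int
    gc1: float | None = None
    gc2: float | None = None
    gc3: float | None = None
    counted_by_position: tuple[int, int, int] | None = None


def _gc_fraction(counts_gc: int, counts_all: int) -> float:
    if counts_all == 0:
        raise ValueError("no countable (unambiguous, ungapped) bases")
    return 100.0 * counts_gc / counts_all


def gc_content(
    nt_seqs: Sequence[SequenceRecord] | Sequence[str], codon_aligned: bool = False
) -> GCProfile:
    """Pooled GC% of a set of nucleotide sequences, optionally by codon
    position (requires in-frame sequences of length divisible by 3)."""
    seqs = [s.seq if isinstance(s, SequenceRecord) else s for s in nt_seqs]
    total_gc = total = 0
    pos_gc = [0, 0, 0]
    pos_n = [0, 0, 0]
    for seq in seqs:
        seq = seq.upper().replace("U", "T")
        if codon_aligned and len(seq) % 3 != 0:
            raise ValueError("positional GC requires length divisible by 3")
        for i, ch in enumerate(seq):
            if ch not in BASES:
                continue
            total += 1
            is_gc = ch in GC
            total_gc += is_gc
            if codon_aligned:
                p = i % 3
                pos_n[p] += 1
                pos_gc[p] += is_gc
    profile = GCProfile(gc_total=_gc_fraction(total_gc, total), counted_total=total)
    if codon_aligned:
        profile.gc1 = _gc_fraction(pos_gc[0], pos_n[0])
        profile.gc2 = _gc_fraction(pos_gc[1], pos_n[1])
        profile.gc3 = _gc_fraction(pos_gc[2], pos_n[2])
        profile.counted_by_position = (pos_n[0], pos_n[1], pos_n[2])
    return profile


def codon_counts(
    nt_seqs: Sequence[SequenceRecord] | Sequence[str], include_stops: bool = False
) -> dict[str, int]:
    """Pooled in-frame codon counts; codons containing N or gaps are skipped."""
    seqs = [s.seq if isinstance(s, SequenceRecord) else s for s in nt_seqs]
    codons = SENSE_CODONS + STOP_CODONS if include_stops else SENSE_CODONS
    counts = {c: 0 for c in codons}
    saw_codon = False
    for seq in seqs:
        seq = seq.upper().replace("U", "T")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if set(codon) <= BASES:
                saw_codon = True
                if codon in counts:
                    counts[codon] += 1
    if not saw_codon:
        raise ValueError("no complete unambiguous codons")
    return counts


def rscu(
    nt_seqs: Sequence[SequenceRecord] | Sequence[str], include_stops: bool = False
) -> pd.DataFrame:
    """RSCU per codon: observed count / mean count over the synonymous family.

    Families with zero total count are reported missing (NaN), not zero.
    Met and Trp (single-codon families) score 1.0 whenever observed. With
    ``include_stops`` the three stop codons form an additional family
    (display parity with codon-usage plots that show them).
    """
    counts = codon_counts(nt_seqs, include_stops=include_stops)
    families = dict(FAMILIES)
    if include_stops:
        families["*"] = list(STOP_CODONS)
    rows = []
    for aa, codons in sorted(families.items()):
        fam_total = sum(counts[c] for c in codons)
        n = len(codons)
        for c in codons:
            if fam_total == 0:
                value = np.nan
            else:
                value = counts[c] / (fam_total / n)
            rows.append(
                {"codon": c, "amino_acid": aa, "count": counts[c],
                 "family_size": n, "rscu": value}
            )
    return pd.DataFrame(rows).sort_values("codon", ignore_index=True)


def rscu_by_group(
    records: Sequence[SequenceRecord],
    labels: Sequence[str] | None = None,
    include_stops: bool = False,
) -> pd.DataFrame:
    """Groups x codons RSCU matrix, pooling codon counts within each group."""
    if labels is None:
        labels = [r.group or "ungrouped" for r in records]
    if len(labels) != len(records):
        raise ValueError("labels and records differ in length")
    groups = list(dict.fromkeys(labels))
    tables = {}
    for g in groups:
        members = [r for r, lab in zip(records, labels) if lab == g]
        t = rscu(members, include_stops=include_stops)
        tables[g] = t.set_index("codon")["rscu"]
    return pd.DataFrame(tables).T.loc[groups]


@dataclass
class CorrespondenceResult:
    """CA of a nonnegative table: principal-axis coordinates and inertias."""

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    inertia: np.ndarray  # per-axis
    total_inertia: float

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.inertia / self.total_inertia


def rscu_correspondence(matrix: pd.DataFrame) -> CorrespondenceResult:
    """Correspondence analysis of a groups x codons RSCU matrix.

    Columns with any missing value (zero-count families in some group) are
    dropped; the decomposition is the standard SVD of standardized residuals
    of the row/column-profile matrix, so total inertia equals the table's
    chi-square statistic divided by its grand total.
    """
    m = matrix.dropna(axis=1, how="any")
    m = m.loc[(m != 0).any(axis=1), (m != 0).any(axis=0)]
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("correspondence analysis needs at least a 2x2 table")
    if (m.values < 0).any():
        raise ValueError("negative entries in CA input")
    res = _skbio_ca(m, scaling=1)
    inertia = res.eigvals.values
    if inertia.sum() <= 0:
        # rank-0 (independent) table: coordinates are all zero
        total = 0.0
    else:
        total = float(inertia.sum())
    return CorrespondenceResult(
        row_coords=res.samples,
        col_coords=res.features,
        inertia=inertia,
        total_inertia=total,
    )


def table_inertia(matrix: pd.DataFrame | np.ndarray) -> float:
    """Total inertia of a contingency-style table: chi-square / grand total."""
    x = np.asarray(matrix, dtype=float)
    n = x.sum()
    r = x.sum(axis=1, keepdims=True) / n
    c = x.sum(axis=0, keepdims=True) / n
    e = r * c * n
    return float(((x - e) ** 2 / e).sum() / n)


def plot_rscu(
    matrix: pd.DataFrame, path: str | None = None
):  # pragma: no cover - optional plotting
    """Bar-plus-dot chart of codon frequency and RSCU per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(max(8, matrix.shape[1] * 0.25), 4))
    codons = matrix.columns
    x = np.arange(len(codons))
    width = 0.8 / matrix.shape[0]
    for k, (g, row) in enumerate(matrix.iterrows()):
        ax1.bar(x + k * width, row.values, width=width, label=str(g))
    ax1.set_xticks(x + 0.4)
    ax1.set_xticklabels(codons, rotation=90, fontsize=6)
    ax1.set_ylabel("RSCU")
    ax1.axhline(1.0, color="grey", lw=0.5, ls="--")
    ax1.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
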