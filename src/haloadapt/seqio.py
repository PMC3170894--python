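"""Sequence and tree input/output, translation, and identity clustering.

Covers reading/writing FASTA with optional group metadata, six-frame
translation under the standard genetic code, best-frame selection by minimum
internal stop count, greedy identity clustering of phylotypes (a desk-scale
analogue of CD-HIT's redundancy filtering), and Newick serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import Align, SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

NT_CHARS = set("ACGTUN-")
AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYX*-")

_STANDARD_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class SequenceRecord:
    """A labeled nucleotide or amino-acid sequence.

    ``group`` carries the adaptation class (``tirez`` / ``halophile`` /
    ``nonhalophile``), ``clade`` a taxonomic label, ``season`` a sampling
    season (``winter`` / ``summer``).
    """

    id: str
    seq: str
    alphabet: str = "nt"  # "nt" or "aa"
    group: str | None = None
    clade: str | None = None
    season: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        chars = set(self.seq.upper())
        allowed = NT_CHARS if self.alphabet == "nt" else AA_CHARS
        bad = chars - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """Equal-length SequenceRecords; ``codon_aligned`` marks an in-frame
    nucleotide alignment (length divisible by 3, codon i spanning nt columns
    3i-2..3i, 1-based)."""

    records: list[SequenceRecord]
    codon_aligned: bool = False

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment with no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.codon_aligned:
            if self.records[0].alphabet != "nt":
                raise ValueError("codon_aligned requires nucleotide records")
            if self.length % 3 != 0:
                raise ValueError("codon_aligned alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def infer_alphabet(seq: str) -> str:
    """Infer nt vs aa: any residue outside the nucleotide alphabet means aa."""
    return "nt" if set(seq.upper()) <= NT_CHARS else "aa"


def read_fasta(
    path: str | Path,
    alphabet: str | None = None,
    group_table: str | Path | None = None,
) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords, preserving input order.

    The alphabet is inferred per file (aa if any record needs it) unless given.
    ``group_table`` is an optional TSV sidecar keyed by id with columns
    ``id, group, clade, season``.
    """
    raw = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not raw:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    for rid, _ in raw:
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
    if alphabet is None:
        alphabet = "aa" if any(infer_alphabet(s) == "aa" for _, s in raw) else "nt"
    records = [SequenceRecord(rid, s, alphabet) for rid, s in raw]
    if group_table is not None:
        records = attach_groups(records, read_group_table(group_table))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_group_table(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated group-label table (id, group, clade, season)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise ValueError(f"group table {path} lacks an 'id' column")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in group table: {dups}")
    return df.set_index("id")


def attach_groups(
    records: Sequence[SequenceRecord], table: pd.DataFrame
) -> list[SequenceRecord]:
    out = []
    for r in records:
        if r.id in table.index:
            row = table.loc[r.id]
            out.append(
                replace(
                    r,
                    group=row.get("group") or None,
                    clade=row.get("clade") or None,
                    season=row.get("season") or None,
                )
            )
        else:
            out.append(r)
    return out


def reverse_complement(nt_seq: str) -> str:
    return nt_seq.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str, frame: int = 1) -> str:
    """Translate under the standard genetic code in one of the six frames.

    Codons containing N or a gap translate to X; stops render as '*'; an
    incomplete trailing codon is dropped.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    seq = nt_seq.upper().replace("U", "T")
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    seq = seq[offset:]
    if len(seq) < 3:
        raise ValueError("fewer than 3 nucleotides after frame offset")
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon == "---":  # aligned gap codon
            aa.append("-")
        else:
            aa.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aa)


def best_frame(nt_seq: str) -> tuple[int, str, int]:
    """Pick the reading frame with the fewest internal stop codons.

    Returns ``(frame, aa_sequence, internal_stop_count)``. Ties resolve in
    frame order +1, +2, +3, -1, -2, -3. A nonzero minimum stop count flags an
    interrupted reading frame (homology-search confirmation is out of scope).
    """
    best: tuple[int, str, int] | None = None
    for frame in FRAMES:
        aa = translate(nt_seq, frame)
        stops = aa[:-1].count("*")  # a trailing stop is not internal
        if best is None or stops < best[2]:
            best = (frame, aa, stops)
    assert best is not None
    return best


@dataclass
class Cluster:
    """A greedy identity cluster with its representative member."""

    representative: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)


_aligner_cache: dict[str, Align.PairwiseAligner] = {}


def _aligner(alphabet: str) -> Align.PairwiseAligner:
    if alphabet not in _aligner_cache:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = 1
        al.mismatch_score = 0
        al.open_gap_score = -1
        al.extend_gap_score = -1
        _aligner_cache[alphabet] = al
    return _aligner_cache[alphabet]


def pairwise_identity(a: str, b: str, alphabet: str = "nt") -> float:
    """Fraction of identical columns in a global pairwise alignment
    (match +1 / mismatch 0 / linear gap -1)."""
    if a == b:
        return 1.0
    aln = _aligner(alphabet).align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return matches / len(s1)


def greedy_identity_cluster(
    records: Sequence[SequenceRecord], threshold: float
) -> list[Cluster]:
    """Greedy longest-first identity clustering (CD-HIT-style, exact pairwise).

    Records are sorted by descending length (input order breaks ties); each
    joins the first cluster whose representative matches at >= threshold
    identity, else founds a new cluster. At threshold 1.0 equal-length
    clustering degenerates to exact deduplication.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"identity threshold must be in (0, 1], got {threshold}")
    alphabets = {r.alphabet for r in records}
    if len(alphabets) > 1:
        raise ValueError("records mix alphabets")
    order = sorted(range(len(records)), key=lambda i: (-len(records[i]), i))
    clusters: list[Cluster] = []
    for i in order:
        rec = records[i]
        for cl in clusters:
            if pairwise_identity(rec.seq, cl.representative.seq, rec.alphabet) >= threshold:
                cl.members.append(rec)
                break
        else:
            clusters.append(Cluster(representative=rec, members=[rec]))
    return clusters


def representatives(clusters: Sequence[Cluster]) -> list[SequenceRecord]:
    return [c.representative for c in clusters]


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with bootstrap supports as internal node labels."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
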