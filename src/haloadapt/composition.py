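"""Amino-acid composition and the PAB / AB "salt-in" haloadaptation indicators.

Salt-in halophiles keep cytoplasmic proteins functional at multimolar KCl by
acidifying them: an excess of Asp/Glu and a dearth of Lys/Arg. Two scalar
indicators quantify this on percentage composition:

    PAB = (Asx + Glx) - (Arg + Lys)        [percentage points]
    AB  = (Asp + Glu) : (His + Arg + Lys)  [ratio]

where Asx = Asn + Asp and Glx = Gln + Glu (sequence residues are unambiguous,
so the ambiguity codes are simple sums).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CATEGORIES: dict[str, str] = {
    "hydrophobic": "GLVIFMAWP",
    "polar": "STCYQN",
    "basic": "HRK",
    "acidic": "ED",
}

# Bulk-proteome reference rows (percent Asx+Glx, PAB, Lys, Arg, GC%) shipped
# for report context only; not recomputed from proteomes.
REFERENCE_STRAINS: dict[str, dict[str, float]] = {
    "Halobacterium salinarum": {"asx_glx": 31.80, "pab": 25.36, "lys": 2.34, "arg": 4.10, "gc": 65.7},
    "Halomonas elongata": {"asx_glx": 25.98, "pab": 17.56, "lys": 3.7, "arg": 5.25},
    "Escherichia coli": {"asx_glx": 26.04, "pab": 15.85, "lys": 6.03, "arg": 4.16, "gc": 50.6},
}


@dataclass
class CompositionProfile:
    """Percent composition of one amino-acid sequence (gaps, X and '*'
    excluded from both numerator and denominator), with category sums and
    haloadaptation indicators."""

    percent: dict[str, float]
    counted: int
    hydrophobic: float = field(init=False)
    polar: float = field(init=False)
    basic: float = field(init=False)
    acidic: float = field(init=False)

    def __post_init__(self) -> None:
        for cat, members in CATEGORIES.items():
            setattr(self, cat, sum(self.percent[a] for a in members))

    @property
    def pab(self) -> float:
        return pab(self)

    @property
    def ab(self) -> float | None:
        return ab_ratio(self)

    @property
    def asp_to_lys(self) -> float | None:
        if self.percent["K"] == 0:
            return None
        return self.percent["D"] / self.percent["K"]


def composition_profile(aa_seq: str) -> CompositionProfile:
    """Percent amino-acid composition of ``aa_seq`` on the 0-100 scale."""
    counts = {a: 0 for a in AMINO_ACIDS}
    for ch in aa_seq.upper():
        if ch in counts:
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no countable residues")
    return CompositionProfile(
        percent={a: 100.0 * c / total for a, c in counts.items()}, counted=total
    )


def pab(profile: CompositionProfile) -> float:
    """PAB = (Asx + Glx) - (Arg + Lys), in percentage points."""
    p = profile.percent
    return pab_from_percentages(p["N"] + p["D"] + p["Q"] + p["E"], p["K"], p["R"])


def pab_from_percentages(asx_glx: float, lys: float, arg: float) -> float:
    """PAB from tabulated percentages (e.g. published bulk-protein rows)."""
    return asx_glx - (arg + lys)


def ab_ratio(profile: CompositionProfile) -> float | None:
    """AB = (Asp + Glu) : (His + Arg + Lys); None when no basic residues."""
    p = profile.percent
    basic = p["H"] + p["R"] + p["K"]
    if basic == 0:
        return None
    return (p["D"] + p["E"]) / basic


_METRICS = [
    "asx_glx", "pab", "ab", "lys", "asp_to_lys", "arg",
    "hydrophobic", "polar", "basic", "acidic",
]


def _metric_row(profile: CompositionProfile) -> dict[str, float | None]:
    p = profile.percent
    return {
        "asx_glx": p["N"] + p["D"] + p["Q"] + p["E"],
        "pab": profile.pab,
        "ab": profile.ab,
        "lys": p["K"],
        "asp_to_lys": profile.asp_to_lys,
        "arg": p["R"],
        "hydrophobic": profile.hydrophobic,
        "polar": profile.polar,
        "basic": profile.basic,
        "acidic": profile.acidic,
    }


def group_summary(
    profiles: Sequence[CompositionProfile],
    labels: Sequence[str],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean and sample SD (n-1) of each composition metric per group.

    ``groups`` fixes the row order and validates the labels; by default groups
    appear in first-occurrence order. SD is reported as 0 for n = 1.
    """
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels differ in length")
    if groups is None:
        groups = list(dict.fromkeys(labels))
    unknown = set(labels) - set(groups)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    df = pd.DataFrame([_metric_row(p) for p in profiles])
    df["group"] = list(labels)
    rows = []
    for g in groups:
        sub = df[df["group"] == g]
        if sub.empty:
            continue
        row: dict[str, object] = {"group": g, "n": len(sub)}
        for m in _METRICS:
            vals = sub[m].dropna()
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) else math.nan
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def composition_report(
    summary: pd.DataFrame, gc_by_group: Mapping[str, Mapping[str, float]] | None = None
) -> pd.DataFrame:
    """Assemble the group-summary report table (composition indicators plus,
    when available, total and third-position GC% from codon statistics)."""
    out = summary.copy()
    if gc_by_group:
        out["gc_total"] = [gc_by_group.get(g, {}).get("gc_total") for g in out["group"]]
        out["gc3"] = [gc_by_group.get(g, {}).get("gc3") for g in out["group"]]
    return out
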