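"""Tajima's D neutrality test for nucleotide alignments.

D contrasts mean pairwise nucleotide diversity (pi) with Watterson's
estimator S/a1; under the standard neutral model its expectation is near
zero, with positive values suggesting balancing/positive selection or
population contraction and negative values purifying selection or expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .seqio import Alignment

_VALID = set("ACGT")


@dataclass
class TajimaResult:
    n: int
    sites_used: int
    S: int
    pi_hat: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float | None


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1, a2, b1, b2, c1, c2, e1, e2 for sample size n."""
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(
    nt_alignment: Alignment, complete_deletion: bool = True
) -> TajimaResult:
    """Tajima's D with its intermediate quantities.

    Columns containing any gap or ambiguous base are removed first (complete
    deletion; per-site pairwise deletion behind the flag). Multi-allelic
    sites count once toward S; pairwise differences count any mismatch.
    D is None (undefined) when S = 0.
    """
    n = len(nt_alignment)
    if n < 4:
        raise ValueError(f"Tajima's D needs >= 4 sequences, got {n}")
    mat = np.array(
        [list(r.seq.upper().replace("U", "T")) for r in nt_alignment.records]
    )
    valid = np.isin(mat, sorted(_VALID))
    if complete_deletion:
        keep = valid.all(axis=0)
        mat, valid = mat[:, keep], valid[:, keep]
    n_cols = mat.shape[1]

    S = 0
    for j in range(n_cols):
        if len(set(mat[valid[:, j], j])) > 1:
            S += 1

    pairs = list(combinations(range(n), 2))
    total_diff = 0
    for i, k in pairs:
        comparable = valid[i] & valid[k]
        total_diff += int(((mat[i] != mat[k]) & comparable).sum())
    pi_hat = total_diff / len(pairs)

    const = tajima_constants(n)
    if S == 0:
        D = None
    else:
        var = const["e1"] * S + const["e2"] * S * (S - 1)
        D = (pi_hat - S / const["a1"]) / np.sqrt(var)
    return TajimaResult(n=n, sites_used=n_cols, S=S, pi_hat=pi_hat, D=D, **const)
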