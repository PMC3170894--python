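"""Synthetic inputs for every pipeline stage.

Generators emulate the study's data shapes without any downloads: coding
sequence sets with controlled positional GC and acidic/basic balance
(mimicking Tirez / halophile / nonhalophile marker-gene groups), amino-acid
alignments evolved on trees under the JTT model (an oracle for distance and
tree estimation), neutral Kingman-coalescent nucleotide alignments with
infinite-sites mutations (the null model for Tajima's D), and binary DGGE
band tables with tunable within-season noise and between-season shift.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import root

from .phylo import DistanceModel
from .dgge import BandMatrix
from .neutrality import tajima_constants
from .seqio import Alignment, SequenceRecord, CODON_TO_AA
from .codonstats import SENSE_CODONS

_GC = set("GC")
_PAB_PLUS = set("NDQE")  # Asx + Glx members
_PAB_MINUS = set("RK")   # Arg + Lys


@dataclass
class CompositionTarget:
    """Targets for an i.i.d.-codon coding-sequence generator.

    ``gc1``/``gc2``/``gc3`` are positional GC fractions in (0, 1).
    Exactly one of ``pab_target`` (expected PAB of the translations, in
    percentage points) or ``acidic_excess`` (PAB shift over the same
    construction without the shift) may be set.
    """

    gc1: float = 0.5
    gc2: float = 0.5
    gc3: float = 0.5
    pab_target: float | None = None
    acidic_excess: float | None = None
    n_sequences: int = 20
    n_codons: int = 125
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc1", "gc2", "gc3"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_sequences < 1 or self.n_codons < 1:
            raise ValueError("counts must be >= 1")
        if self.pab_target is not None and self.acidic_excess is not None:
            raise ValueError("set at most one of pab_target / acidic_excess")


_CODON_ARR = np.array([list(c) for c in SENSE_CODONS])
_IS_GC = np.isin(_CODON_ARR, list(_GC))  # 61 x 3
_CODON_AA = np.array([CODON_TO_AA[c] for c in SENSE_CODONS])
_PLUS = np.isin(_CODON_AA, list(_PAB_PLUS))
_MINUS = np.isin(_CODON_AA, list(_PAB_MINUS))


def _codon_probs(log_f: float, logit_g: np.ndarray) -> np.ndarray:
    g = 1.0 / (1.0 + np.exp(-logit_g))  # per-position GC weight
    w = np.where(_IS_GC, g[np.newaxis, :], 1.0 - g[np.newaxis, :]).prod(axis=1)
    f = np.exp(log_f)
    w = w * np.where(_PLUS, f, 1.0) * np.where(_MINUS, 1.0 / f, 1.0)
    return w / w.sum()


def _expected(p: np.ndarray) -> np.ndarray:
    """(E[GC1], E[GC2], E[GC3], E[PAB]) under codon distribution p."""
    gc = (p[:, np.newaxis] * _IS_GC).sum(axis=0)
    pab = 100.0 * (p[_PLUS].sum() - p[_MINUS].sum())
    return np.append(gc, pab)


def solve_codon_distribution(target: CompositionTarget) -> np.ndarray:
    """Codon probabilities (over the 61 sense codons) matching the target
    positional GC fractions and, if requested, the expected PAB."""
    gc_targets = np.array([target.gc1, target.gc2, target.gc3])
    logit0 = np.log(gc_targets / (1 - gc_targets))

    def gc_resid(x: np.ndarray) -> np.ndarray:
        return _expected(_codon_probs(0.0, x))[:3] - gc_targets

    sol = root(gc_resid, logit0, method="hybr")
    if not sol.success or np.abs(sol.fun).max() > 1e-9:
        raise ValueError(
            f"infeasible positional GC targets {gc_targets.tolist()}"
        )
    if target.pab_target is None and target.acidic_excess is None:
        return _codon_probs(0.0, sol.x)

    if target.pab_target is not None:
        pab_goal = target.pab_target
    else:
        baseline = _expected(_codon_probs(0.0, sol.x))[3]
        pab_goal = baseline + target.acidic_excess
    goal = np.append(gc_targets, pab_goal)

    def resid(x: np.ndarray) -> np.ndarray:
        return _expected(_codon_probs(x[0], x[1:])) - goal

    sol2 = root(resid, np.concatenate([[0.0], sol.x]), method="hybr")
    if not sol2.success or np.abs(sol2.fun).max() > 1e-7:
        raise ValueError(
            f"infeasible composition target: positional GC {gc_targets.tolist()} "
            f"conflicts with expected PAB {pab_goal}"
        )
    return _codon_probs(sol2.x[0], sol2.x[1:])


def generate_coding_set(
    target: CompositionTarget,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Draw i.i.d. codons from the solved distribution (stop codons excluded).

    Returns (nucleotide records, amino-acid translations), both in-frame and
    equal-length; deterministic given ``target.seed``.
    """
    p = solve_codon_distribution(target)
    rng = np.random.default_rng(target.seed)
    nt_records, aa_records = [], []
    for i in range(target.n_sequences):
        idx = rng.choice(len(SENSE_CODONS), size=target.n_codons, p=p)
        nt = "".join(SENSE_CODONS[k] for k in idx)
        aa = "".join(_CODON_AA[k] for k in idx)
        nt_records.append(SequenceRecord(f"syn{i+1}", nt, "nt"))
        aa_records.append(SequenceRecord(f"syn{i+1}", aa, "aa"))
    return nt_records, aa_records


def evolve_on_tree(
    tree: dendropy.Tree,
    model: DistanceModel,
    sites: int,
    seed: int | None = None,
) -> Alignment:
    """Evolve an amino-acid alignment along a tree under the JTT model.

    The root sequence is drawn from the equilibrium frequencies; each site
    evolves independently down branches with P(t) transition sampling. With
    ``model.gamma_shape`` set, per-site rate multipliers are drawn from
    Gamma(alpha, 1/alpha).
    """
    rng = np.random.default_rng(seed)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    if model.gamma_shape is not None:
        rates = rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=sites)
    else:
        rates = None
    pi = model.freqs
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(20, size=sites, p=pi / pi.sum())
    uniform_model = DistanceModel(gamma_shape=None, freqs=model.freqs)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent = states[id(node.parent_node)]
        if t == 0:
            child = parent.copy()
        elif rates is None:
            p_mat = uniform_model.transition_matrix(t)
            p_mat = p_mat / p_mat.sum(axis=1, keepdims=True)
            child = np.empty(sites, dtype=int)
            for a in np.unique(parent):
                mask = parent == a
                child[mask] = rng.choice(20, size=int(mask.sum()), p=p_mat[a])
        else:
            child = np.empty(sites, dtype=int)
            for s in range(sites):
                p_mat = uniform_model.transition_matrix(t * rates[s])
                row = p_mat[parent[s]]
                child[s] = rng.choice(20, p=row / row.sum())
        states[id(node)] = child
    from ._jtt import AA_ORDER

    records = []
    for leaf in tree.leaf_node_iter():
        seq = "".join(AA_ORDER[k] for k in states[id(leaf)])
        records.append(SequenceRecord(leaf.taxon.label, seq, "aa"))
    return Alignment(records)


def coalescent_alignment(
    n: int,
    theta: float,
    sites: int,
    seed: int | None = None,
    on_overflow: str = "resample",
) -> Alignment:
    """Neutral Kingman-coalescent alignment under the infinite-sites model.

    Coalescence times are exponential with rate k(k-1)/2 while k lineages
    remain; mutations fall as Poisson(theta/2 * total branch length), each on
    its own column, encoded as ancestral A / derived G. When more mutations
    arise than ``sites``, the replicate is redrawn (``on_overflow="resample"``)
    or an error raised.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if on_overflow not in ("resample", "error"):
        raise ValueError("on_overflow must be 'resample' or 'error'")
    rng = np.random.default_rng(seed)
    while True:
        branches: list[tuple[frozenset[int], float]] = []
        active: list[tuple[set[int], float]] = [({i}, 0.0) for i in range(n)]
        while len(active) > 1:
            k = len(active)
            dt = rng.exponential(2.0 / (k * (k - 1)))
            active = [(m, ln + dt) for m, ln in active]
            i, j = sorted(rng.choice(k, size=2, replace=False))
            mi, li = active[i]
            mj, lj = active[j]
            branches.append((frozenset(mi), li))
            branches.append((frozenset(mj), lj))
            merged = (mi | mj, 0.0)
            active = [x for p, x in enumerate(active) if p not in (i, j)] + [merged]
        total_len = sum(ln for _, ln in branches)
        n_mut = rng.poisson(theta / 2.0 * total_len)
        if n_mut > sites:
            if on_overflow == "error":
                raise ValueError(
                    f"{n_mut} mutations exceed {sites} sites; increase sites"
                )
            continue
        cols = rng.choice(sites, size=n_mut, replace=False)
        lens = np.array([ln for _, ln in branches])
        probs = lens / lens.sum() if lens.sum() > 0 else None
        matrix = np.full((n, sites), "A", dtype="U1")
        if n_mut:
            which = rng.choice(len(branches), size=n_mut, p=probs)
            for col, b in zip(cols, which):
                for sample in branches[b][0]:
                    matrix[sample, col] = "G"
        records = [
            SequenceRecord(f"s{i+1}", "".join(matrix[i]), "nt") for i in range(n)
        ]
        return Alignment(records)


def generate_band_table(
    lanes_per_group: int,
    bands: int,
    within_noise: float,
    between_shift: float,
    seed: int | None = None,
    groups: tuple[str, str] = ("winter", "summer"),
) -> BandMatrix:
    """Two-season binary band table.

    The first season's archetype pattern is Bernoulli(1/2) per band; the
    second season's archetype flips each band with probability
    ``between_shift``; each lane then flips each band of its season archetype
    with probability ``within_noise``. Noise 0 / shift 1 gives perfectly
    separated seasons; shift 0 carries no group signal. Lanes that would come
    out empty get one random band switched on.
    """
    for name, p in (("within_noise", within_noise), ("between_shift", between_shift)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arch_a = rng.random(bands) < 0.5
    arch_b = np.where(rng.random(bands) < between_shift, ~arch_a, arch_a)
    lanes, seasons, depths, rows = [], [], [], []
    depth_labels = ["0-5", "5-10", "10-15", "15-20"]
    for g, arch in zip(groups, (arch_a, arch_b)):
        for i in range(lanes_per_group):
            lane = np.where(rng.random(bands) < within_noise, ~arch, arch)
            if not lane.any():
                lane[rng.integers(bands)] = True
            lanes.append(f"{g}_{i+1}")
            seasons.append(g)
            depths.append(depth_labels[i % len(depth_labels)])
            rows.append(lane.astype(int))
    return BandMatrix(
        lanes=lanes, values=np.array(rows), seasons=seasons, depths=depths
    )


def expected_segregating_sites(n: int, theta: float) -> float:
    """Closed-form neutral expectation E[S] = theta * a1(n)."""
    return theta * tajima_constants(n)["a1"]
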