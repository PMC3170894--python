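"""JTT(+Gamma) maximum-likelihood protein distances, neighbor-joining,
bootstrap and majority-rule consensus with support-threshold collapsing.

The pairwise distance between two aligned amino-acid sequences is the time t
maximizing sum over comparable sites of log(pi_a * P_ab(t)) under the JTT
model normalized to one expected substitution per site per unit time, so
distances are in substitutions per site. Rate variation among sites uses the
continuous-gamma transform of the eigenvalues:
P(t) = U diag((1 - lambda_k t/alpha)^(-alpha)) U^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from ._jtt import AA_ORDER, JTT_FREQS, rate_matrix
from .seqio import Alignment

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

MAX_DISTANCE = 10.0


@dataclass
class DistanceModel:
    """JTT substitution model, optionally with gamma rate variation.

    ``gamma_shape`` is the shape parameter alpha (> 0); None means uniform
    rates. The rate matrix is normalized so branch lengths/distances are in
    expected substitutions per site.
    """

    gamma_shape: float | None = None
    freqs: np.ndarray = field(default_factory=lambda: JTT_FREQS.copy(), repr=False)
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be > 0")
        q = rate_matrix()
        pi = self.freqs
        # symmetrize with diag(sqrt(pi)) for a stable eigendecomposition
        d = np.sqrt(pi)
        b = (q * d[:, np.newaxis]) / d[np.newaxis, :]
        lam, v = np.linalg.eigh((b + b.T) / 2)
        u = v / d[:, np.newaxis]
        uinv = v.T * d[np.newaxis, :]
        self._eig = (lam, u, uinv)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t); with gamma rates, the expectation over the rate distribution."""
        if t < 0:
            raise ValueError("negative time")
        lam, u, uinv = self._eig
        if self.gamma_shape is None:
            g = np.exp(lam * t)
        else:
            a = self.gamma_shape
            g = (1.0 - lam * t / a) ** (-a)
        p = (u * g[np.newaxis, :]) @ uinv
        return np.clip(p, 0.0, None)


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix (zero diagonal)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = (v + v.T) / 2

    def __len__(self) -> int:
        return len(self.labels)


def _pair_counts(a: str, b: str) -> np.ndarray:
    """20x20 substitution count matrix over pairwise-deleted columns."""
    n = np.zeros((20, 20))
    for x, y in zip(a.upper(), b.upper()):
        i = _AA_INDEX.get(x)
        j = _AA_INDEX.get(y)
        if i is not None and j is not None:
            n[i, j] += 1
    return n


def jtt_distance(aa_seq_a: str, aa_seq_b: str, model: DistanceModel) -> float:
    """ML distance between two equal-length aligned aa sequences.

    Columns with a gap, X or other non-standard symbol in either sequence are
    dropped (pairwise deletion). The likelihood is optimized on
    t in [0, 10] by bounded scalar search to 1e-6.
    """
    if len(aa_seq_a) != len(aa_seq_b):
        raise ValueError("sequences differ in length")
    counts = _pair_counts(aa_seq_a, aa_seq_b)
    total = counts.sum()
    if total == 0:
        raise ValueError("no comparable (pairwise ungapped) columns")
    if np.trace(counts) == total:
        return 0.0
    log_pi = np.log(model.freqs)[:, np.newaxis]

    def neg_ll(t: float) -> float:
        p = np.clip(model.transition_matrix(t), 1e-300, None)
        return -float((counts * (log_pi + np.log(p))).sum())

    res = minimize_scalar(
        neg_ll, bounds=(1e-9, MAX_DISTANCE), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def distance_matrix(aa_alignment: Alignment, model: DistanceModel) -> DistanceMatrix:
    """All-pairs JTT(+Gamma) ML distances for an aa alignment."""
    n = len(aa_alignment)
    seqs = [r.seq for r in aa_alignment.records]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_distance(seqs[i], seqs[j], model)
    return DistanceMatrix(aa_alignment.ids, d)


def write_phylip_distances(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"    {len(dm)}\n")
        for label, row in zip(dm.labels, dm.values):
            name = label[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def read_phylip_distances(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        tokens = fh.read().split()
    n = int(tokens[0])
    labels, rows = [], []
    k = 1
    for _ in range(n):
        labels.append(tokens[k])
        rows.append([float(x) for x in tokens[k + 1 : k + 1 + n]])
        k += 1 + n
    return DistanceMatrix(labels, np.array(rows))


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Q-criterion agglomeration; ties break on the smallest (i, j) pair in the
    current node order; negative branch-length estimates are clamped to 0.
    Returns an unrooted dendropy tree (trifurcating at the seed node for
    more than 3 taxa).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    tns = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in dm.labels]
    d = dm.values.astype(float).copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int, li: float, lj: float) -> None:
        """Replace active[i_pos], active[j_pos] by their new parent."""
        i, j = active[i_pos], active[j_pos]
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, li)
        nodes[j].edge.length = max(0.0, lj)
        nodes.append(parent)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        dab = sub[a, b]
        li = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lj = dab - li
        join(a, b, li, lj)
        new = len(nodes) - 1
        # distances from the new node to the remaining actives
        i, j = active[a], active[b]
        d = np.pad(d, ((0, 1), (0, 1)))
        for pos, k in enumerate(active):
            if pos in (a, b):
                continue
            d[new, k] = d[k, new] = (d[i, k] + d[j, k] - dab) / 2
        active = [k for pos, k in enumerate(active) if pos not in (a, b)] + [new]

    # three-point formulas for the final trifurcation
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    root = dendropy.Node()
    for node, ln in (
        (nodes[i], (dij + dik - djk) / 2),
        (nodes[j], (dij + djk - dik) / 2),
        (nodes[k], (dik + djk - dij) / 2),
    ):
        root.add_child(node)
        node.edge.length = max(0.0, ln)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def _label_supports(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        support = getattr(nd, "support", None)
        if support is not None:
            nd.label = str(int(round(support)))


def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Collapse internal branches whose bootstrap support (percent) is below
    ``threshold``, producing polytomies."""
    to_collapse = [
        nd.edge
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf()
        and nd.parent_node is not None
        and getattr(nd, "support", 100.0) is not None
        and getattr(nd, "support", 100.0) < threshold
    ]
    for edge in to_collapse:
        edge.collapse()
    _label_supports(tree)
    return tree


def bootstrap_consensus(
    aa_alignment: Alignment,
    model: DistanceModel,
    replicates: int = 100,
    support_collapse_threshold: float = 60.0,
    seed: int | None = None,
) -> dendropy.Tree:
    """Majority-rule (>50%) consensus of NJ trees over column-bootstrap
    replicates, with branches under ``support_collapse_threshold`` percent
    support collapsed. Supports are percentages on internal node labels;
    consensus branch lengths are means over replicates containing the branch.
    """
    if len(aa_alignment) < 4:
        raise ValueError("bootstrap needs >= 4 sequences")
    if replicates < 1:
        raise ValueError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    length = aa_alignment.length
    seqs = [r.seq for r in aa_alignment.records]
    tns = dendropy.TaxonNamespace(aa_alignment.ids)
    trees = dendropy.TreeList(taxon_namespace=tns)
    from dataclasses import replace as _replace

    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        records = [
            _replace(r, seq="".join(s[c] for c in cols))
            for r, s in zip(aa_alignment.records, seqs)
        ]
        rep_aln = Alignment(records)
        t = neighbor_joining(distance_matrix(rep_aln, model))
        t.taxon_namespace = tns
        t.migrate_taxon_namespace(tns)
        trees.append(t)
    consensus = trees.consensus(
        min_freq=0.5, support_as_percentages=True, set_edge_lengths="mean-length"
    )
    return collapse_low_support(consensus, support_collapse_threshold)


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as frozensets of leaf labels (smaller side,
    ties by lexicographic order), for topology comparison."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        a, b = sorted([side, other], key=lambda s: (len(s), sorted(s)))
        out.add(frozenset(a))
    return out
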