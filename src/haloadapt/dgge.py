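"""DGGE fingerprint analysis: presence/absence band matrices, Jaccard
distances, lane dendrograms, and a seasonal-partition permutation test.

A DGGE gel yields lanes (samples labeled by season and depth interval) and
bands scored qualitatively as present/absent. Lanes are clustered on Jaccard
distance with neighbor joining (or UPGMA); this binary-distance clustering is
a documented stand-in for restriction-site ML clustering of band patterns.
The seasonal-partition comparison is a label-permutation test on the mean
between-group minus mean within-group Jaccard distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .phylo import DistanceMatrix, neighbor_joining


@dataclass
class BandMatrix:
    """Lanes x bands binary matrix with per-lane season/depth metadata."""

    lanes: list[str]
    values: np.ndarray
    seasons: list[str] | None = None
    depths: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != len(self.lanes):
            raise ValueError("band matrix shape does not match lane labels")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("band matrix entries must be 0/1")
        if (v.sum(axis=1) == 0).any():
            empty = [self.lanes[i] for i in np.where(v.sum(axis=1) == 0)[0]]
            raise ValueError(f"empty lanes (no bands): {empty}")
        self.values = v.astype(int)

    def __len__(self) -> int:
        return len(self.lanes)


def read_band_table(path: str | Path) -> BandMatrix:
    """Band table TSV: columns lane, season, depth, then one 0/1 column per band."""
    df = pd.read_csv(path, sep="\t")
    meta = [c for c in ("lane", "season", "depth") if c in df.columns]
    if "lane" not in meta:
        raise ValueError("band table needs a 'lane' column")
    bands = [c for c in df.columns if c not in meta]
    return BandMatrix(
        lanes=df["lane"].astype(str).tolist(),
        values=df[bands].to_numpy(),
        seasons=df["season"].astype(str).tolist() if "season" in meta else None,
        depths=df["depth"].astype(str).tolist() if "depth" in meta else None,
    )


def write_band_table(bm: BandMatrix, path: str | Path) -> None:
    df = pd.DataFrame(bm.values, columns=[f"band{i+1}" for i in range(bm.values.shape[1])])
    df.insert(0, "lane", bm.lanes)
    if bm.seasons is not None:
        df.insert(1, "season", bm.seasons)
    if bm.depths is not None:
        df.insert(2, "depth", bm.depths)
    df.to_csv(path, sep="\t", index=False)


def band_distance(bm: BandMatrix) -> DistanceMatrix:
    """Jaccard distance 1 - |A&B| / |A|B| per lane pair.

    Two all-zero lanes would be distance 0 by convention, but BandMatrix
    forbids empty lanes upstream.
    """
    v = bm.values
    inter = v @ v.T
    sizes = v.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(bm.lanes), d)


def band_dendrogram(dm: DistanceMatrix, method: str = "nj") -> dendropy.Tree:
    """Lane dendrogram from a distance matrix: ``nj`` (default) or ``upgma``."""
    if method == "nj":
        return neighbor_joining(dm)
    if method == "upgma":
        return _upgma(dm)
    raise ValueError(f"unknown method {method!r}")


def _upgma(dm: DistanceMatrix) -> dendropy.Tree:
    z = average(squareform(dm.values, checks=False))
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in dm.labels]
    heights = [0.0] * len(dm.labels)
    for row in z:
        a, b, h = int(row[0]), int(row[1]), float(row[2])
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = h / 2 - heights[a]
        nodes[b].edge.length = h / 2 - heights[b]
        nodes.append(parent)
        heights.append(h / 2)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[-1]
    tree.update_taxon_namespace()
    return tree


@dataclass
class PermutationTestResult:
    statistic: float  # mean between-group minus mean within-group distance
    p_value: float
    permutations: int


def seasonal_permutation_test(
    dm: DistanceMatrix,
    labels: Sequence[str],
    permutations: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Label-permutation test of group separation on a distance matrix.

    The statistic is mean between-group minus mean within-group distance;
    the p-value is the (add-one smoothed) fraction of label permutations with
    a statistic at least as large as observed.
    """
    labels = np.asarray(labels)
    if len(labels) != len(dm):
        raise ValueError("labels do not match distance matrix")
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two groups")
    d = dm.values
    iu = np.triu_indices(len(dm), k=1)

    def stat(lab: np.ndarray) -> float:
        same = lab[iu[0]] == lab[iu[1]]
        return float(d[iu][~same].mean() - d[iu][same].mean())

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        if stat(perm) >= observed - 1e-12:
            exceed += 1
    return PermutationTestResult(
        statistic=observed,
        p_value=(exceed + 1) / (permutations + 1),
        permutations=permutations,
    )
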