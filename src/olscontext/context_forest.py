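"""Context forests: clustering of context trees, grove detection, and
chromosomal co-distribution geometry.

A context forest is a dendrogram whose leaves are themselves context trees
(one per seed family / query). Trees whose leaf partitions agree at every
granularity are at dissimilarity 0; trees sharing fewer than three species
cannot be meaningfully compared and get the maximal dissimilarity 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix

from .context_trees import (
    ContextTree,
    CTNode,
    Partition,
    cut_k,
    fowlkes_mallows,
    restrict_tree,
    vg_ahc,
)
from .genome_io import Gene

DEFAULT_STEM_PERCENTILE = 90.0
DEFAULT_MIN_GROVE_LEAVES = 3
DEFAULT_MIN_CLUSTERICITY = 0.5


@dataclass
class ContextForest:
    tree: ContextTree

    def leaf_ids(self) -> list[str]:
        return self.tree.leaf_ids()


@dataclass
class Grove:
    """A forest subtree separated from the rest by a long stem branch."""

    members: list[str]
    stem_length: float
    height: float


def _species_cut(t: ContextTree, k: int) -> Partition:
    p = cut_k(t, k)
    species_of = t.species_of_leaf()
    merged: dict[str, set] = {}
    labels: dict[str, str] = {}
    # merge blocks sharing a species (duplicate species tags merge, never error)
    parent: dict[frozenset, frozenset] = {}
    blocks = [set(species_of[l] for l in b) for b in p.blocks]
    out: list[set] = []
    for b in blocks:
        hit = [o for o in out if o & b]
        for o in hit:
            out.remove(o)
            b = b | o
        out.append(b)
    return Partition(blocks=[frozenset(b) for b in out])


def tree_dissim(t1: ContextTree, t2: ContextTree) -> float:
    """1 − mean Fowlkes–Mallows agreement over all cut granularities.

    Both trees are restricted to their shared species S; for every
    k = 2..|S|−1 the two k-cluster cuts (removing the k−1 highest merges)
    are compared. Fewer than three shared species → 1.0 by convention.
    """
    s1, s2 = t1.species(), t2.species()
    shared = s1 & s2
    if len(shared) < 3:
        return 1.0
    r1, r2 = restrict_tree(t1, shared), restrict_tree(t2, shared)
    scores = []
    for k in range(2, len(shared)):
        p1 = _species_cut(r1, k)
        p2 = _species_cut(r2, k)
        scores.append(fowlkes_mallows(p1, p2))
    return 1.0 - float(np.mean(scores))


def forest_dissimilarity_matrix(
    trees: Mapping[str, ContextTree]
) -> DistanceMatrix:
    ids = sorted(trees)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree_dissim(trees[ids[i]], trees[ids[j]])
    return DistanceMatrix(d, ids=ids)


def build_forest(
    trees: Mapping[str, ContextTree],
    linkage: str = "unweighted_average",
) -> ContextForest:
    """Cluster context trees into a context forest (leaves = tree ids)."""
    if len(trees) < 2:
        raise ValueError("a context forest needs at least two trees")
    dm = forest_dissimilarity_matrix(trees)
    return ContextForest(tree=vg_ahc(dm, linkage=linkage))


def detect_groves(
    forest: ContextForest,
    stem_percentile: float = DEFAULT_STEM_PERCENTILE,
    min_leaves: int = DEFAULT_MIN_GROVE_LEAVES,
) -> list[Grove]:
    """Quantitative grove detection.

    A grove is a maximal forest subtree with at least ``min_leaves``
    members whose stem length (parent merge height minus subtree height)
    reaches the given percentile of all stem lengths in the forest — the
    quantitative analogue of a "visibly long" separating branch.
    """
    root = forest.tree.root
    stems: list[tuple[CTNode, float]] = []

    def walk(node: CTNode) -> None:
        for c in node.children:
            stems.append((c, node.height - c.height))
            walk(c)

    walk(root)
    if not stems:
        return []
    lengths = np.array([s for _, s in stems])
    cutoff = float(np.percentile(lengths, stem_percentile))
    if cutoff <= 0:
        return []
    qualifying = {
        id(nd)
        for nd, s in stems
        if s >= cutoff and len(nd.leaves()) >= min_leaves
    }
    groves: list[Grove] = []

    def collect(node: CTNode, parent_height: float, under: bool) -> None:
        is_grove = id(node) in qualifying and not under
        if is_grove:
            groves.append(
                Grove(
                    members=sorted(node.leaf_ids()),
                    stem_length=parent_height - node.height,
                    height=node.height,
                )
            )
        for c in node.children:
            collect(c, node.height, under or is_grove)

    for c in root.children:
        collect(c, root.height, False)
    return groves


def groves_to_tsv(groves: Sequence[Grove]) -> str:
    lines = ["grove_id\tstem_length\tn_members\tmembers"]
    for i, g in enumerate(groves):
        lines.append(
            f"grove{i:03d}\t{g.stem_length:.6g}\t{len(g.members)}\t"
            + ",".join(g.members)
        )
    return "\n".join(lines) + "\n"


def bisect_distance(
    gene1: Gene, gene2: Gene, length: int, circular: bool = True
) -> float:
    """Chromosomal separation as a fraction of half the chromosome.

    The gene-pair midpoint distance (around the shorter arc when circular)
    divided by half the replicon length: 0 for coincident genes, 1 for
    genes diametrically opposite on a circular chromosome.
    """
    if gene1.replicon_id != gene2.replicon_id:
        raise ValueError("bisect distance requires genes on one replicon")
    d = abs(gene1.midpoint - gene2.midpoint)
    if circular:
        d = min(d, length - d)
    return d / (length / 2.0)


def pairwise_distance_profile(
    genes: Sequence[Gene],
    length: int,
    bins: int = 20,
    circular: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of bisect distances over all unordered gene pairs.

    Returns (counts, bin edges) over [0, 1]; the pair count is C(n, 2).
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes for a distance profile")
    dists = [
        bisect_distance(genes[i], genes[j], length, circular=circular)
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
    ]
    counts, edges = np.histogram(dists, bins=bins, range=(0.0, 1.0))
    return counts, edges


def profile_to_tsv(counts: np.ndarray, edges: np.ndarray) -> str:
    lines = ["bin_lo\tbin_hi\tcount"]
    for i, c in enumerate(counts):
        lines.append(f"{edges[i]:.4f}\t{edges[i + 1]:.4f}\t{int(c)}")
    return "\n".join(lines) + "\n"
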