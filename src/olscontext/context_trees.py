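"""Context trees: variable-group agglomerative hierarchical clustering and
Fowlkes–Mallows correlation of trees with external data groupings.

Variable-group AHC differs from textbook sequential AHC only in how ties
are handled: at each step *all* clusters connected by an inter-cluster
dissimilarity within ``TIE_EPS`` of the global minimum are merged at once,
producing one multifurcating node per connected tie component. Without
ties, the output is node-for-node identical to sequential clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from skbio import DistanceMatrix

TIE_EPS = 1e-9
LINKAGES = ("unweighted_average", "complete")
DEFAULT_SEGMENTATION_THRESHOLD = 0.05


@dataclass
class CTNode:
    """Node of a context tree; leaves carry an id and optional species tag."""

    height: float = 0.0
    children: list["CTNode"] = field(default_factory=list)
    leaf_id: str | None = None
    species_id: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["CTNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_ids(self) -> list[str]:
        return [l.leaf_id for l in self.leaves()]

    def internal_nodes(self) -> list["CTNode"]:
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out


@dataclass
class ContextTree:
    root: CTNode
    linkage: str = "unweighted_average"

    def leaves(self) -> list[CTNode]:
        return self.root.leaves()

    def leaf_ids(self) -> list[str]:
        return self.root.leaf_ids()

    def species(self) -> set[str]:
        return {l.species_id for l in self.leaves() if l.species_id is not None}

    def species_of_leaf(self) -> dict[str, str]:
        return {
            l.leaf_id: (l.species_id if l.species_id is not None else l.leaf_id)
            for l in self.leaves()
        }

    @property
    def height(self) -> float:
        return self.root.height

    def to_newick(self) -> str:
        def fmt(node: CTNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.leaf_id}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        if self.root.is_leaf:
            return f"{self.root.leaf_id}:0;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def to_dict(self) -> dict:
        def conv(node: CTNode) -> dict:
            if node.is_leaf:
                return {"leaf": node.leaf_id, "species": node.species_id}
            return {
                "height": node.height,
                "children": [conv(c) for c in node.children],
            }

        return conv(self.root)


@dataclass
class Partition:
    """Disjoint nonempty blocks covering a universe of labels."""

    blocks: list[frozenset]

    def __post_init__(self) -> None:
        self.blocks = [frozenset(b) for b in self.blocks]
        if any(not b for b in self.blocks):
            raise ValueError("empty partition block")
        total = sum(len(b) for b in self.blocks)
        if total != len(self.universe):
            raise ValueError("partition blocks overlap")

    @property
    def universe(self) -> frozenset:
        return frozenset().union(*self.blocks) if self.blocks else frozenset()

    def __len__(self) -> int:
        return len(self.blocks)

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and set(self.blocks) == set(other.blocks)

    def block_of(self) -> dict:
        return {x: i for i, b in enumerate(self.blocks) for x in b}


def vg_ahc(
    dm: DistanceMatrix,
    linkage: str = "unweighted_average",
    species_of: Mapping[str, str] | None = None,
) -> ContextTree:
    """Variable-group agglomerative hierarchical clustering.

    At every step the global minimum inter-cluster dissimilarity ``m`` is
    found, and all clusters connected by dissimilarities within ``TIE_EPS``
    of ``m`` merge simultaneously into one node per connected component at
    height ``m``. Inter-cluster dissimilarities are computed from the
    original leaf-level matrix: the mean over all cross leaf pairs
    (``unweighted_average``) or their maximum (``complete``).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    ids = list(dm.ids)
    n = len(ids)
    if n == 0:
        raise ValueError("cannot cluster an empty matrix")
    base = np.asarray(dm.data, dtype=float)

    def make_leaf(i: int) -> CTNode:
        sp = species_of.get(ids[i]) if species_of else None
        return CTNode(height=0.0, leaf_id=ids[i], species_id=sp)

    if n == 1:
        return ContextTree(root=make_leaf(0), linkage=linkage)

    clusters: list[tuple[CTNode, list[int]]] = [
        (make_leaf(i), [i]) for i in range(n)
    ]

    def cdist(a: list[int], b: list[int]) -> float:
        block = base[np.ix_(a, b)]
        return float(block.mean()) if linkage == "unweighted_average" else float(block.max())

    prev_height = 0.0
    while len(clusters) > 1:
        k = len(clusters)
        dists = {}
        m = math.inf
        for i in range(k):
            for j in range(i + 1, k):
                d = cdist(clusters[i][1], clusters[j][1])
                dists[(i, j)] = d
                m = min(m, d)
        assert m >= prev_height - TIE_EPS, "merge-height inversion"
        # connected components over edges within TIE_EPS of the minimum
        parent = list(range(k))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (i, j), d in dists.items():
            if d <= m + TIE_EPS:
                parent[find(i)] = find(j)
        comps: dict[int, list[int]] = {}
        for i in range(k):
            comps.setdefault(find(i), []).append(i)
        new_clusters = []
        for members in comps.values():
            if len(members) == 1:
                new_clusters.append(clusters[members[0]])
            else:
                node = CTNode(
                    height=max(m, prev_height),
                    children=[clusters[i][0] for i in members],
                )
                idxs = [x for i in members for x in clusters[i][1]]
                new_clusters.append((node, idxs))
        clusters = new_clusters
        prev_height = max(m, prev_height)
    return ContextTree(root=clusters[0][0], linkage=linkage)


def cut_tree(t: ContextTree, height: float) -> Partition:
    """Cut at ``height``: blocks are maximal subtrees whose internal merge
    heights all lie at or below the cut."""
    if height < 0:
        raise ValueError("cut height must be ≥ 0")
    blocks: list[frozenset] = []

    def walk(node: CTNode) -> None:
        if node.is_leaf or node.height <= height:
            blocks.append(frozenset(node.leaf_ids()))
        else:
            for c in node.children:
                walk(c)

    walk(t.root)
    return Partition(blocks=blocks)


def cut_k(t: ContextTree, k: int) -> Partition:
    """Partition obtained by removing the ``k−1`` highest merges.

    With multifurcations the result may have more than ``k`` blocks (a
    removed multifurcating merge releases all its children at once).
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    frontier: list[CTNode] = [t.root]
    removed = 0
    while removed < k - 1:
        internal = [nd for nd in frontier if not nd.is_leaf]
        if not internal:
            break
        top = max(internal, key=lambda nd: nd.height)
        frontier.remove(top)
        frontier.extend(top.children)
        removed += 1
    return Partition(blocks=[frozenset(nd.leaf_ids()) for nd in frontier])


def fowlkes_mallows(p1: Partition, p2: Partition) -> float:
    """Fowlkes–Mallows index B between two flat partitions.

    B = T/√(P·Q) with T = Σ mᵢⱼ² − n, P = Σ mᵢ·² − n, Q = Σ m·ⱼ² − n over
    the block contingency table; B = 1 iff the partitions are identical.
    When either partition is all-singletons (P·Q = 0) the convention B = 0
    applies.
    """
    if p1.universe != p2.universe:
        raise ValueError("partitions cover different universes")
    n = len(p1.universe)
    b2 = p2.block_of()
    m = np.zeros((len(p1), len(p2)))
    for i, block in enumerate(p1.blocks):
        for x in block:
            m[i, b2[x]] += 1
    T = float((m**2).sum() - n)
    P = float((m.sum(axis=1) ** 2).sum() - n)
    Q = float((m.sum(axis=0) ** 2).sum() - n)
    if P * Q == 0:
        return 0.0
    return T / math.sqrt(P * Q)


def leaf_to_species_partition(
    p: Partition, species_of: Mapping[str, str]
) -> Partition:
    """Map a leaf-level partition to species labels.

    Leaves of the same species must fall in one block (error on conflict);
    the resulting blocks contain species ids.
    """
    block_of_species: dict[str, int] = {}
    for i, block in enumerate(p.blocks):
        for leaf in block:
            sp = species_of[leaf]
            if sp in block_of_species and block_of_species[sp] != i:
                raise ValueError(
                    f"species {sp} split across partition blocks"
                )
            block_of_species[sp] = i
    blocks: dict[int, set] = {}
    for sp, i in block_of_species.items():
        blocks.setdefault(i, set()).add(sp)
    return Partition(blocks=[frozenset(b) for b in blocks.values()])


def single_group_partition(labels: Iterable[str]) -> Partition:
    """The trivial data grouping: all labels in one unified group."""
    return Partition(blocks=[frozenset(labels)])


def data_grouping_correlation(
    t: ContextTree,
    grouping: Partition,
    segmentation_threshold: float = DEFAULT_SEGMENTATION_THRESHOLD,
    mode: str = "height",
) -> tuple[float, bool]:
    """Correlate a context tree with an external species grouping.

    The tree is segmented into a flat partition — by a dendrogram cut at
    ``segmentation_threshold`` (default) or, with ``mode="k"``, by removing
    the ``threshold−1`` highest merges — mapped to species labels, and
    scored against ``grouping`` with the Fowlkes–Mallows index. ``agrees``
    is exact partition equality.
    """
    species_of = t.species_of_leaf()
    missing = set(species_of.values()) - set().union(*grouping.blocks)
    if missing:
        raise ValueError(f"species {sorted(missing)} absent from data grouping")
    if mode == "height":
        p = cut_tree(t, segmentation_threshold)
    elif mode == "k":
        p = cut_k(t, int(segmentation_threshold))
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")
    ps = leaf_to_species_partition(p, species_of)
    score = fowlkes_mallows(ps, grouping)
    return score, ps == grouping


def restrict_tree(t: ContextTree, keep_species: set[str]) -> ContextTree:
    """Prune a context tree to leaves whose species tag is in ``keep_species``.

    Unary internal nodes collapse to their child; merge heights are kept.
    """

    def prune(node: CTNode) -> CTNode | None:
        if node.is_leaf:
            sp = node.species_id if node.species_id is not None else node.leaf_id
            return node if sp in keep_species else None
        kids = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return CTNode(height=node.height, children=kids)

    root = prune(t.root)
    if root is None:
        raise ValueError("restriction removed every leaf")
    return ContextTree(root=root, linkage=t.linkage)
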