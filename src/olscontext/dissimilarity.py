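"""Pairwise dissimilarity metrics between genomic groupings.

The metrics mirror the comparison options used for cross-species context
analysis: gene content (multiset Jaccard), linear gene order (normalized
Kendall-tau with orientation equivalence), presence/absence of common
promoter motifs (optionally restricted to OLS heads or internal start
sites), and changes in intergenic gap size (0.01-scaled absolute difference
or a 30 nt threshold). Several metrics may be combined by linear
amalgamation with nonnegative weights.

A metric can be *undefined* for a pair (too few shared families, no shared
adjacent pair); such pairs return ``None`` and are dropped from downstream
trees rather than imputed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skbio import DistanceMatrix

from .ols_core import GenomicGrouping

DEFAULT_GAP_SCALE = 0.01
DEFAULT_GAP_THRESHOLD = 30


def _content(g: GenomicGrouping) -> Counter:
    return Counter(f for f in g.families if f is not None)


def gene_content_dissim(g1: GenomicGrouping, g2: GenomicGrouping) -> float:
    """1 − multiset Jaccard similarity of family contents."""
    c1, c2 = _content(g1), _content(g2)
    inter = sum((c1 & c2).values())
    union = sum((c1 | c2).values())
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def _single_copy_order(g: GenomicGrouping) -> list[str]:
    """Families occurring exactly once, in transcription order."""
    c = _content(g)
    return [f for f in g.families if f is not None and c[f] == 1]


def _kendall_distance(a: Sequence[str], b: Sequence[str]) -> float:
    """Normalized Kendall-tau distance between two orderings of one set."""
    pos = {f: i for i, f in enumerate(b)}
    ranks = [pos[f] for f in a]
    n = len(ranks)
    discordant = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if ranks[i] > ranks[j]
    )
    return discordant / (n * (n - 1) / 2)


def gene_order_dissim(
    g1: GenomicGrouping, g2: GenomicGrouping
) -> float | None:
    """Normalized Kendall-tau distance over shared single-copy families.

    The minimum over the second ordering and its reversal is taken, so a
    grouping and its exact reverse are orientation-equivalent (distance 0).
    Undefined (None) with fewer than two shared families.
    """
    s1, s2 = _single_copy_order(g1), _single_copy_order(g2)
    shared = set(s1) & set(s2)
    a = [f for f in s1 if f in shared]
    b = [f for f in s2 if f in shared]
    if len(a) < 2:
        return None
    return min(_kendall_distance(a, b), _kendall_distance(a, b[::-1]))


def _scoped_flags(g: GenomicGrouping, scope: str) -> dict[str, bool]:
    """Per-family promoter flag restricted to a positional scope.

    A family occurring at several in-scope positions is flagged if any of
    its genes is.
    """
    flags: dict[str, bool] = {}
    for i, gene in enumerate(g.genes):
        if gene.family_id is None:
            continue
        if scope == "head_only" and i != 0:
            continue
        if scope == "internal_only" and i == 0:
            continue
        flags[gene.family_id] = flags.get(gene.family_id, False) or g.promoter_flags[i]
    return flags


def motif_dissim(
    g1: GenomicGrouping, g2: GenomicGrouping, scope: str = "all"
) -> float:
    """Fraction of shared in-scope families whose promoter flags differ.

    ``scope`` is one of ``all``, ``head_only`` (motifs at the OLS head) or
    ``internal_only`` (motifs at internal gene start sites). 0 when no
    shared family falls in scope.
    """
    if scope not in ("all", "head_only", "internal_only"):
        raise ValueError(f"unknown motif scope {scope!r}")
    f1, f2 = _scoped_flags(g1, scope), _scoped_flags(g2, scope)
    shared = sorted(set(f1) & set(f2))
    if not shared:
        return 0.0
    return sum(f1[f] != f2[f] for f in shared) / len(shared)


def _adjacent_gaps(g: GenomicGrouping) -> dict[frozenset, int]:
    """Gap per unordered adjacent family pair (first occurrence wins)."""
    out: dict[frozenset, int] = {}
    for i in range(len(g) - 1):
        a, b = g.genes[i].family_id, g.genes[i + 1].family_id
        if a is None or b is None or a == b:
            continue
        key = frozenset((a, b))
        out.setdefault(key, g.gaps[i])
    return out


def gap_dissim_scaled(
    g1: GenomicGrouping,
    g2: GenomicGrouping,
    scale: float = DEFAULT_GAP_SCALE,
) -> float | None:
    """``scale`` × |Δ intergenic gap| over shared adjacent family pairs.

    Multiple shared pairs average; undefined (None) when the groupings
    share no adjacent family pair.
    """
    a1, a2 = _adjacent_gaps(g1), _adjacent_gaps(g2)
    shared = set(a1) & set(a2)
    if not shared:
        return None
    return scale * float(np.mean([abs(a1[k] - a2[k]) for k in shared]))


def gap_dissim_threshold(
    g1: GenomicGrouping,
    g2: GenomicGrouping,
    threshold: int = DEFAULT_GAP_THRESHOLD,
) -> float | None:
    """1 iff any shared adjacent pair's gap changed by ≥ ``threshold`` nt.

    The 30 nt default flags gap widenings large enough to admit a basal
    promoter element between two genes that remain within one OLS.
    """
    a1, a2 = _adjacent_gaps(g1), _adjacent_gaps(g2)
    shared = set(a1) & set(a2)
    if not shared:
        return None
    return 1.0 if any(abs(a1[k] - a2[k]) >= threshold for k in shared) else 0.0


METRICS: dict[str, Callable] = {
    "gene_content": gene_content_dissim,
    "gene_order": gene_order_dissim,
    "common_motifs": motif_dissim,
    "gap_scaled": gap_dissim_scaled,
    "gap_threshold": gap_dissim_threshold,
}


@dataclass
class MetricConfig:
    """A weighted linear amalgamation of named component metrics.

    ``components`` is a list of (metric name, weight, params) triples; the
    amalgamated dissimilarity is the weighted sum of component values.
    """

    components: list[tuple[str, float, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("metric config needs at least one component")
        for name, w, _ in self.components:
            if name not in METRICS:
                raise ValueError(f"unknown metric {name!r}")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"bad weight {w} for metric {name}")

    @classmethod
    def single(cls, name: str, weight: float = 1.0, **params) -> "MetricConfig":
        return cls(components=[(name, weight, params)])


#: The four named analysis presets: gene order, promoter content (three
#: scopes collapse to one preset with a scope parameter), scaled gaps, and
#: thresholded gaps.
PRESETS: dict[str, MetricConfig] = {
    "gene-order": MetricConfig.single("gene_order"),
    "promoter-content": MetricConfig.single("common_motifs", scope="all"),
    "promoter-head": MetricConfig.single("common_motifs", scope="head_only"),
    "promoter-internal": MetricConfig.single("common_motifs", scope="internal_only"),
    "gap-scaled": MetricConfig.single("gap_scaled"),
    "gap-threshold": MetricConfig.single("gap_threshold"),
    "gene-content": MetricConfig.single("gene_content"),
}


def amalgamate(
    config: MetricConfig, g1: GenomicGrouping, g2: GenomicGrouping
) -> float | None:
    """Weighted sum of component metrics; None if any component is undefined."""
    total = 0.0
    for name, weight, params in config.components:
        value = METRICS[name](g1, g2, **params)
        if value is None:
            return None
        total += weight * value
    return total


def dissimilarity_matrix(
    groupings: Sequence[GenomicGrouping],
    config: MetricConfig,
    ids: Sequence[str] | None = None,
) -> DistanceMatrix | None:
    """All-versus-all amalgamated dissimilarities as a DistanceMatrix.

    Returns None when any pair is undefined (the corresponding query yields
    no context tree).
    """
    n = len(groupings)
    if ids is None:
        ids = [g.ols_id or f"g{i}" for i, g in enumerate(groupings)]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = amalgamate(config, groupings[i], groupings[j])
            if v is None:
                return None
            d[i, j] = d[j, i] = v
    return DistanceMatrix(d, ids=list(ids))


def matrix_to_tsv(dm: DistanceMatrix) -> str:
    lines = ["\t" + "\t".join(dm.ids)]
    for i, a in enumerate(dm.ids):
        lines.append(a + "\t" + "\t".join(f"{dm.data[i, j]:.6g}" for j in range(len(dm.ids))))
    return "\n".join(lines) + "\n"
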