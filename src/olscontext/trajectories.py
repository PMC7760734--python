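"""OLS trajectories: per-species homologous groupings seeded by one family,
with the evolutionary summary metrics and modification-event classification.

A trajectory collects, for every species, the union of predicted OLSs that
contain a member of a chosen seed protein family. Homologous copies within
one species are merged into a single grouping (paralogs are not split), so
each species contributes exactly one grouping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from skbio import DistanceMatrix

from .ols_core import GenomicGrouping

DEFAULT_MIN_SPECIES = 10
DEFAULT_MAX_INSTANCES = 100
DEFAULT_DISAGREEMENT_MARGIN = 0.10


@dataclass
class TrajectoryGrouping:
    """One species' merged grouping within a trajectory.

    ``content`` is the multiset of family labels over all member genes that
    carry one; ``ordered`` holds the underlying OLS when the species had a
    single OLS (so transcription order is defined), and is None for merged
    multi-OLS groupings, which have no single linear order.
    """

    species_id: str
    content: Counter
    n_genes: int
    ordered: GenomicGrouping | None = None

    @property
    def singleton(self) -> bool:
        return self.n_genes == 1

    @property
    def multigene(self) -> bool:
        return self.n_genes >= 2

    def content_key(self) -> frozenset:
        return frozenset(self.content.items())


@dataclass
class Trajectory:
    seed_family: str
    groupings: dict[str, TrajectoryGrouping]

    def __post_init__(self) -> None:
        if not self.groupings:
            raise ValueError(f"trajectory for {self.seed_family} has no species")

    @property
    def species(self) -> list[str]:
        return sorted(self.groupings)

    def __len__(self) -> int:
        return len(self.groupings)


@dataclass
class GeneContentCollection:
    """Equivalence class of groupings with identical family content."""

    content: Counter
    species: set[str]
    representative: TrajectoryGrouping

    @property
    def n_genes(self) -> int:
        return sum(self.content.values())


@dataclass
class ModificationEvent:
    kind: str  # prepend | append | insertion
    unique_family: str
    smaller: GeneContentCollection
    larger: GeneContentCollection
    ambiguous: bool = False


def select_seed_families(
    homology: Mapping[str, str],
    ols_by_species: Mapping[str, Sequence[GenomicGrouping]],
    min_species: int = DEFAULT_MIN_SPECIES,
    max_instances: int = DEFAULT_MAX_INSTANCES,
) -> list[str]:
    """Families represented in ≥ ``min_species`` species with ≤
    ``max_instances`` gene copies overall, having at least one multigene OLS.

    The species/instance filters keep families that are well represented but
    not so paralog-rich that orthology becomes ambiguous; the multigene-OLS
    requirement discards families that only ever occur as gene singletons.
    """
    species_of: dict[str, set[str]] = {}
    count_of: Counter = Counter()
    has_multigene: set[str] = set()
    for sp, groupings in ols_by_species.items():
        for grp in groupings:
            for g in grp.genes:
                fam = g.family_id
                if fam is None:
                    continue
                species_of.setdefault(fam, set()).add(sp)
                count_of[fam] += 1
                if len(grp) >= 2:
                    has_multigene.add(fam)
    return sorted(
        fam
        for fam, sps in species_of.items()
        if len(sps) >= min_species
        and count_of[fam] <= max_instances
        and fam in has_multigene
    )


def build_trajectory(
    seed_family: str,
    ols_by_species: Mapping[str, Sequence[GenomicGrouping]],
) -> Trajectory:
    """Build the trajectory seeded by ``seed_family``.

    Per species, every OLS containing a seed-family gene contributes; their
    family contents are combined by multiset union into one grouping.
    """
    groupings: dict[str, TrajectoryGrouping] = {}
    for sp in sorted(ols_by_species):
        hits = [
            grp
            for grp in ols_by_species[sp]
            if any(g.family_id == seed_family for g in grp.genes)
        ]
        if not hits:
            continue
        content: Counter = Counter()
        n_genes = 0
        for grp in hits:
            content.update(f for f in grp.families if f is not None)
            n_genes += len(grp)
        groupings[sp] = TrajectoryGrouping(
            species_id=sp,
            content=content,
            n_genes=n_genes,
            ordered=hits[0] if len(hits) == 1 else None,
        )
    if not groupings:
        raise ValueError(f"seed family {seed_family} absent from every species")
    return Trajectory(seed_family=seed_family, groupings=groupings)


def clustericity(t: Trajectory) -> float:
    """Fraction of the trajectory's species whose grouping is multigene.

    Measures how often the seed gene occurs in a multigene OLS relative to
    all of its species-level occurrences (multigene OLSs plus singletons).
    """
    return sum(g.multigene for g in t.groupings.values()) / len(t)


def variety(t: Trajectory) -> float:
    """Distinct companion family types over total companion gene count.

    Companions are the non-seed genes accompanying the seed across all
    groupings; 0 when the seed is always alone.
    """
    types: set[str] = set()
    total = 0
    for g in t.groupings.values():
        for fam, n in g.content.items():
            if fam == t.seed_family:
                continue
            types.add(fam)
            total += n
    return len(types) / total if total else 0.0


def content_collections(
    t: Trajectory, include_singletons: bool = True
) -> list[GeneContentCollection]:
    """Partition groupings into classes of identical family content.

    Content is compared as a multiset: paralog copies matter, so {S,A,A}
    and {S,A} are distinct. The representative grouping of each class comes
    from its lexicographically first species, for determinism.
    """
    by_key: dict[frozenset, list[TrajectoryGrouping]] = {}
    for sp in sorted(t.groupings):
        g = t.groupings[sp]
        if not include_singletons and g.singleton:
            continue
        by_key.setdefault(g.content_key(), []).append(g)
    return [
        GeneContentCollection(
            content=members[0].content.copy(),
            species={m.species_id for m in members},
            representative=members[0],
        )
        for members in by_key.values()
    ]


def topology_divergence_ratio(t: Trajectory, pd: DistanceMatrix) -> float | None:
    """Number of content collections over the largest patristic distance
    among member species; None (undefined) when that distance is zero."""
    species = t.species
    dmax = 0.0
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            dmax = max(dmax, float(pd[a, b]))
    if dmax == 0.0:
        return None
    return len(content_collections(t)) / dmax


def _one_gene_difference(
    small: GeneContentCollection, large: GeneContentCollection
) -> str | None:
    """Family whose single extra instance turns ``small`` into ``large``."""
    extra = large.content - small.content
    missing = small.content - large.content
    if sum(missing.values()) == 0 and sum(extra.values()) == 1:
        return next(iter(extra))
    return None


def classify_modifications(
    t: Trajectory,
) -> tuple[list[ModificationEvent], str]:
    """Classify single-gene content differences between collection pairs.

    For every pair of collections where the larger content equals the
    smaller plus exactly one extra gene instance and both contain at least
    two genes, the extra gene's position in the larger collection's
    representative grouping decides the kind: head → prepend, tail →
    append, otherwise insertion. Pairs whose representative grouping has no
    defined transcription order (same-species OLS merge) are skipped.

    Returns the events and a trajectory label: ``none`` (no events),
    ``single_type`` (exactly one kind observed) or ``multiple_types``.
    """
    cols = content_collections(t)
    events: list[ModificationEvent] = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            small, large = (a, b) if a.n_genes < b.n_genes else (b, a)
            if small.n_genes < 2:
                continue
            fam = _one_gene_difference(small, large)
            if fam is None:
                continue
            rep = large.representative
            if rep.ordered is None:
                continue  # no linear order: head/tail/internal undefined
            genes = rep.ordered.genes
            idx = [k for k, g in enumerate(genes) if g.family_id == fam]
            if not idx:
                continue
            ambiguous = len(idx) > 1
            if ambiguous:
                seed_idx = [
                    k for k, g in enumerate(genes) if g.family_id == t.seed_family
                ]
                pos = min(
                    idx, key=lambda k: min(abs(k - s) for s in seed_idx) if seed_idx else k
                )
            else:
                pos = idx[0]
            if pos == 0:
                kind = "prepend"
            elif pos == len(genes) - 1:
                kind = "append"
            else:
                kind = "insertion"
            events.append(
                ModificationEvent(
                    kind=kind,
                    unique_family=fam,
                    smaller=small,
                    larger=large,
                    ambiguous=ambiguous,
                )
            )
    kinds = {e.kind for e in events}
    if not events:
        label = "none"
    elif len(kinds) == 1:
        label = "single_type"
    else:
        label = "multiple_types"
    return events, label


def phylogeny_disagreement(
    t: Trajectory,
    pd: DistanceMatrix,
    margin: float = DEFAULT_DISAGREEMENT_MARGIN,
    include_singletons: bool = True,
    compare: str = "max_inter",
) -> bool:
    """Does any content collection straddle the species phylogeny?

    True iff some collection with ≥2 species has a maximum intra-collection
    patristic distance exceeding the maximum distance from any member to any
    trajectory species outside the collection by more than ``margin``.
    ``compare="min_inter"`` substitutes the minimum inter distance (the
    conventional, stricter comparison). With ``include_singletons=False``,
    singleton groupings are removed before partitioning.
    """
    if compare not in ("max_inter", "min_inter"):
        raise ValueError(f"unknown comparison {compare!r}")
    cols = content_collections(t, include_singletons=include_singletons)
    if len(cols) <= 1:
        return False
    universe = set().union(*(c.species for c in cols))
    for col in cols:
        members = sorted(col.species)
        if len(members) < 2:
            continue
        outside = sorted(universe - col.species)
        if not outside:
            continue
        intra = max(
            float(pd[a, b])
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
        inter_vals = [float(pd[a, o]) for a in members for o in outside]
        inter = max(inter_vals) if compare == "max_inter" else min(inter_vals)
        if intra > inter + margin:
            return True
    return False


def trajectory_report_rows(
    trajectories: Iterable[Trajectory],
    pd: DistanceMatrix | None = None,
) -> list[dict]:
    """Flat per-trajectory summary suitable for a TSV report."""
    rows = []
    for t in trajectories:
        events, label = classify_modifications(t)
        row = {
            "seed_family": t.seed_family,
            "n_species": len(t),
            "clustericity": round(clustericity(t), 4),
            "variety": round(variety(t), 4),
            "n_collections": len(content_collections(t)),
            "modification_label": label,
            "n_events": len(events),
        }
        if pd is not None:
            tdr = topology_divergence_ratio(t, pd)
            row["topology_divergence_ratio"] = (
                round(tdr, 4) if tdr is not None else ""
            )
            row["disagreement_with_singletons"] = phylogeny_disagreement(
                t, pd, include_singletons=True
            )
            row["disagreement_without_singletons"] = phylogeny_disagreement(
                t, pd, include_singletons=False
            )
        rows.append(row)
    return rows
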