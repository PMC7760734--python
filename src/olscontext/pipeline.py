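"""Glue between the stages: family labelling, whole-dataset OLS prediction,
and per-trajectory context-tree construction."""

from __future__ import annotations

from typing import Iterable, Mapping

from .context_trees import ContextTree, vg_ahc
from .dissimilarity import MetricConfig, dissimilarity_matrix
from .genome_io import MotifHit, Replicon
from .ols_core import (
    DEFAULT_DOWNSTREAM_WINDOW,
    DEFAULT_MAX_GAP,
    DEFAULT_UPSTREAM_WINDOW,
    GenomicGrouping,
    apply_promoter_flags,
    associate_promoters,
    predict_ols,
)
from .trajectories import Trajectory


def annotate_families(
    replicons: Mapping[str, Mapping[str, Replicon]],
    homology: Mapping[str, str],
) -> dict[str, dict[str, Replicon]]:
    """Attach family labels from a homology map to every gene."""
    out: dict[str, dict[str, Replicon]] = {}
    for sp, reps in replicons.items():
        out[sp] = {}
        for rid, rep in reps.items():
            out[sp][rid] = Replicon(
                replicon_id=rep.replicon_id,
                species_id=rep.species_id,
                length=rep.length,
                circular=rep.circular,
                genes=[g.with_family(homology.get(g.gene_id)) for g in rep.genes],
            )
    return out


def predict_all(
    replicons: Mapping[str, Mapping[str, Replicon]],
    motif_hits: Iterable[MotifHit] = (),
    max_gap: int = DEFAULT_MAX_GAP,
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    downstream_window: int = DEFAULT_DOWNSTREAM_WINDOW,
    allow_origin_spanning: bool = False,
) -> dict[str, list[GenomicGrouping]]:
    """Predict OLSs for every replicon and fill in promoter flags."""
    hits = list(motif_hits)
    out: dict[str, list[GenomicGrouping]] = {}
    for sp in sorted(replicons):
        groupings: list[GenomicGrouping] = []
        for rid in sorted(replicons[sp]):
            rep = replicons[sp][rid]
            ols = predict_ols(
                rep, max_gap=max_gap, allow_origin_spanning=allow_origin_spanning
            )
            flags, _ = associate_promoters(
                rep,
                hits,
                upstream_window=upstream_window,
                downstream_window=downstream_window,
            )
            apply_promoter_flags(ols, flags)
            groupings.extend(ols)
        out[sp] = groupings
    return out


def trajectory_tree(
    t: Trajectory,
    config: MetricConfig,
    linkage: str = "unweighted_average",
) -> ContextTree | None:
    """Context tree over a trajectory's ordered per-species groupings.

    Species whose grouping was merged from several OLSs (no defined
    transcription order) are left out; queries with any undefined pairwise
    dissimilarity, or fewer than two usable groupings, yield no tree.
    """
    ordered = [
        (sp, g.ordered) for sp, g in sorted(t.groupings.items()) if g.ordered is not None
    ]
    if len(ordered) < 2:
        return None
    ids = [sp for sp, _ in ordered]
    dm = dissimilarity_matrix([g for _, g in ordered], config, ids=ids)
    if dm is None:
        return None
    return vg_ahc(dm, linkage=linkage, species_of={sp: sp for sp in ids})


def trajectory_trees(
    trajectories: Iterable[Trajectory],
    config: MetricConfig,
    linkage: str = "unweighted_average",
) -> tuple[dict[str, ContextTree], list[str]]:
    """Trees for all trajectories; returns (trees by seed family, skipped)."""
    trees: dict[str, ContextTree] = {}
    skipped: list[str] = []
    for t in trajectories:
        tree = trajectory_tree(t, config, linkage=linkage)
        if tree is None:
            skipped.append(t.seed_family)
        else:
            trees[t.seed_family] = tree
    return trees, skipped
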