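"""Operon-like structure (OLS) prediction and promoter-motif association.

An OLS is a maximal run of same-strand, coordinate-consecutive genes whose
every internal intergenic gap is at most ``max_gap`` nucleotides (default
50). Overlapping genes have negative gaps and always satisfy the criterion:
overlap is the tightest possible packing and guarantees co-expression.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import Gene, MotifHit, Replicon

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 50
DEFAULT_UPSTREAM_WINDOW = 200
DEFAULT_DOWNSTREAM_WINDOW = 50


def intergenic_gap(upstream: Gene, downstream: Gene) -> int:
    """Nucleotides between two coordinate-adjacent genes (negative = overlap).

    The gap is measured between annotation boundaries:
    ``start(later) − end(earlier) − 1`` with genes ordered by coordinate.
    """
    if upstream.replicon_id != downstream.replicon_id:
        raise ValueError(
            f"genes {upstream.gene_id}/{downstream.gene_id} on different replicons"
        )
    a, b = sorted((upstream, downstream), key=lambda g: (g.start, g.end))
    return b.start - a.end - 1


@dataclass
class GenomicGrouping:
    """An ordered run of genes treated as one unit of genomic context.

    ``genes`` are in transcription order: ascending coordinate on the +
    strand, descending on the −. ``gaps[i]`` is the intergenic gap between
    genes i and i+1 in transcription order; ``promoter_flags[i]`` marks
    whether gene i has an associated promoter motif.
    """

    genes: list[Gene]
    species_id: str
    replicon_id: str
    strand: str
    ols_id: str = ""
    gaps: list[int] = field(default_factory=list)
    promoter_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty grouping")
        if any(g.strand != self.strand for g in self.genes):
            raise ValueError("grouping genes must share one strand")
        if not self.gaps:
            self.gaps = [
                intergenic_gap(self.genes[i], self.genes[i + 1])
                for i in range(len(self.genes) - 1)
            ]
        if not self.promoter_flags:
            self.promoter_flags = [False] * len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def head(self) -> Gene:
        """First gene in transcription order."""
        return self.genes[0]

    @property
    def families(self) -> list[str | None]:
        return [g.family_id for g in self.genes]

    def span(self) -> tuple[int, int]:
        return (
            min(g.start for g in self.genes),
            max(g.end for g in self.genes),
        )


def predict_ols(
    replicon: Replicon,
    max_gap: int = DEFAULT_MAX_GAP,
    allow_origin_spanning: bool = False,
) -> list[GenomicGrouping]:
    """Partition a replicon's genes into OLSs (singletons are 1-gene OLSs).

    Genes are chained while consecutive in coordinate order, on the same
    strand, and separated by at most ``max_gap`` nt. With
    ``allow_origin_spanning`` on a circular replicon, the junction between
    the last and first gene is also tested, allowing an origin-spanning OLS.
    """
    genes = replicon.genes
    if not genes:
        return []
    runs: list[list[Gene]] = [[genes[0]]]
    for prev, cur in zip(genes, genes[1:]):
        gap = cur.start - prev.end - 1
        if cur.strand == prev.strand and gap <= max_gap:
            if cur.start <= prev.end and cur.end <= prev.end:
                logger.info(
                    "gene %s nested within %s; chained with negative gap",
                    cur.gene_id,
                    prev.gene_id,
                )
            runs[-1].append(cur)
        else:
            runs.append([cur])
    if (
        allow_origin_spanning
        and replicon.circular
        and len(runs) > 1
        and runs[0][0].strand == runs[-1][-1].strand
    ):
        first, last = runs[0][0], runs[-1][-1]
        junction_gap = (replicon.length - last.end) + (first.start - 1)
        if junction_gap <= max_gap:
            runs[0] = runs.pop() + runs[0]

    groupings = []
    for i, run in enumerate(runs):
        strand = run[0].strand
        ordered = run if strand == "+" else run[::-1]
        coord_gaps = []
        for j in range(len(run) - 1):
            raw = run[j + 1].start - run[j].end - 1
            if replicon.circular and run[j + 1].start < run[j].start:
                # origin-spanning junction: measure the gap around the origin
                raw += replicon.length
            coord_gaps.append(raw)
        gaps = coord_gaps if strand == "+" else coord_gaps[::-1]
        groupings.append(
            GenomicGrouping(
                genes=ordered,
                species_id=replicon.species_id,
                replicon_id=replicon.replicon_id,
                strand=strand,
                ols_id=f"{replicon.replicon_id}.ols{i:04d}",
                gaps=gaps,
            )
        )
    return groupings


def associate_promoters(
    replicon: Replicon,
    hits: Iterable[MotifHit],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    downstream_window: int = DEFAULT_DOWNSTREAM_WINDOW,
) -> tuple[dict[str, bool], dict[str, int]]:
    """Associate motif hits with genes by proximity to the start site.

    A gene is flagged iff at least one strand-matching hit's center lies no
    further than ``upstream_window`` nt before and ``downstream_window`` nt
    after the gene's predicted start site, measured in the gene's reading
    direction. Returns (per-gene flag, per-gene hit count) keyed by gene id.
    """
    centers = [
        (h.center, h.strand) for h in hits if h.replicon_id == replicon.replicon_id
    ]
    flags: dict[str, bool] = {}
    counts: dict[str, int] = {}
    for g in replicon.genes:
        ss = g.start_site
        if g.strand == "+":
            lo, hi = ss - upstream_window, ss + downstream_window
        else:
            lo, hi = ss - downstream_window, ss + upstream_window
        n = sum(1 for c, s in centers if s == g.strand and lo <= c <= hi)
        flags[g.gene_id] = n > 0
        counts[g.gene_id] = n
    return flags, counts


def apply_promoter_flags(
    groupings: Iterable[GenomicGrouping], flags: dict[str, bool]
) -> None:
    """Fill each grouping's ``promoter_flags`` from a per-gene flag map."""
    for grp in groupings:
        grp.promoter_flags = [flags.get(g.gene_id, False) for g in grp.genes]


def classify_promoter_site(ols: GenomicGrouping, gene_index: int) -> str:
    """Classify position ``gene_index`` (transcription order) as head/internal."""
    if not 0 <= gene_index < len(ols):
        raise IndexError(f"gene index {gene_index} out of range for {len(ols)}-gene OLS")
    return "head" if gene_index == 0 else "internal"


def ols_to_bed_rows(groupings: Sequence[GenomicGrouping]) -> list[str]:
    """BED-like TSV rows: replicon, start, end, strand, ols_id, gene ids."""
    rows = []
    for grp in groupings:
        lo, hi = grp.span()
        rows.append(
            "\t".join(
                [
                    grp.replicon_id,
                    str(lo),
                    str(hi),
                    grp.strand,
                    grp.ols_id,
                    ",".join(g.gene_id for g in grp.genes),
                ]
            )
        )
    return rows


def ols_to_json(groupings: Sequence[GenomicGrouping]) -> str:
    payload = [
        {
            "ols_id": grp.ols_id,
            "species_id": grp.species_id,
            "replicon_id": grp.replicon_id,
            "strand": grp.strand,
            "genes": [g.gene_id for g in grp.genes],
            "families": grp.families,
            "gaps": grp.gaps,
            "promoter_flags": grp.promoter_flags,
        }
        for grp in groupings
    ]
    return json.dumps(payload, indent=1)
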