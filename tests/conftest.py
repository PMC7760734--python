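"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from olscontext.genome_io import Gene, Replicon
from olscontext.ols_core import GenomicGrouping
from olscontext.trajectories import Trajectory, TrajectoryGrouping


def make_grouping(
    families,
    strand="+",
    gaps=None,
    flags=None,
    species_id="sp1",
    replicon_id="chr",
    gene_len=100,
    start=1000,
    tag="",
):
    """Build an ordered grouping with the given transcription-order gaps."""
    n = len(families)
    if gaps is None:
        gaps = [10] * (n - 1)
    coord_gaps = list(gaps) if strand == "+" else list(gaps)[::-1]
    coord_fams = list(families) if strand == "+" else list(families)[::-1]
    genes = []
    cursor = start
    for i, fam in enumerate(coord_fams):
        if i > 0:
            cursor += coord_gaps[i - 1] + 1
        g = Gene(
            gene_id=f"{species_id}{tag}_{fam}_{i}",
            species_id=species_id,
            replicon_id=replicon_id,
            start=cursor,
            end=cursor + gene_len - 1,
            strand=strand,
            family_id=fam,
        )
        cursor = g.end
        genes.append(g)
    ordered = genes if strand == "+" else genes[::-1]
    return GenomicGrouping(
        genes=ordered,
        species_id=species_id,
        replicon_id=replicon_id,
        strand=strand,
        gaps=list(gaps),
        promoter_flags=list(flags) if flags is not None else [],
    )


def make_trajectory(seed_family, per_species):
    """Trajectory from {species: families or (families, strand)} specs.

    Each grouping gets synthetic coordinates; ``ordered`` is always set.
    """
    groupings = {}
    for sp, spec in per_species.items():
        if isinstance(spec, tuple):
            fams, strand = spec
        else:
            fams, strand = spec, "+"
        grp = make_grouping(fams, strand=strand, species_id=sp)
        groupings[sp] = TrajectoryGrouping(
            species_id=sp,
            content=Counter(fams),
            n_genes=len(fams),
            ordered=grp,
        )
    return Trajectory(seed_family=seed_family, groupings=groupings)


def random_replicon(rng, n_genes, max_gap_draw=120, species_id="spX"):
    """A replicon of random-strand genes with gaps spanning the 50 nt rule."""
    genes = []
    cursor = int(rng.integers(1, 200))
    for i in range(n_genes):
        length = int(rng.integers(50, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Gene(
                gene_id=f"{species_id}_g{i}",
                species_id=species_id,
                replicon_id="chr",
                start=cursor,
                end=cursor + length - 1,
                strand=strand,
                family_id=f"F{i}",
            )
        )
        cursor += length + int(rng.integers(0, max_gap_draw))
    return Replicon(
        replicon_id="chr",
        species_id=species_id,
        length=cursor + 500,
        genes=genes,
    )


def brute_force_ols(replicon, max_gap=50):
    """Oracle: every contiguous same-strand run tested against the gap rule;
    maximal valid runs form the partition."""
    genes = replicon.genes
    n = len(genes)

    def valid(i, j):  # run genes[i..j] inclusive
        for k in range(i, j):
            if genes[k + 1].strand != genes[k].strand:
                return False
            if genes[k + 1].start - genes[k].end - 1 > max_gap:
                return False
        return True

    runs = []
    for i in range(n):
        for j in range(i, n):
            if valid(i, j):
                runs.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in runs
        if not any(
            (a <= i and j <= b and (a, b) != (i, j)) for (a, b) in runs
        )
    ]
    return sorted(
        frozenset(genes[k].gene_id for k in range(i, j + 1)) for i, j in sorted(maximal)
    )


def fm_pair_counting(p1_blocks, p2_blocks):
    """Oracle: Fowlkes–Mallows from explicit pair counts."""
    universe = sorted(set().union(*p1_blocks))
    b1 = {x: i for i, b in enumerate(p1_blocks) for x in b}
    b2 = {x: i for i, b in enumerate(p2_blocks) for x in b}
    tp = p1 = p2 = 0
    for i, a in enumerate(universe):
        for b in universe[i + 1 :]:
            s1 = b1[a] == b1[b]
            s2 = b2[a] == b2[b]
            tp += s1 and s2
            p1 += s1
            p2 += s2
    if p1 * p2 == 0:
        return 0.0
    return tp / np.sqrt(p1 * p2)


def random_partition(rng, labels, n_blocks):
    assignment = rng.integers(0, n_blocks, size=len(labels))
    # ensure no empty blocks by reassigning labels if needed
    blocks = {}
    for lab, a in zip(labels, assignment):
        blocks.setdefault(int(a), set()).add(lab)
    return [frozenset(b) for b in blocks.values()]


@pytest.fixture(scope="session")
def sim_dataset():
    """One moderately evolved synthetic dataset shared across tests."""
    from olscontext.synthetic_evolution import SimConfig, simulate_dataset

    cfg = SimConfig(
        seed=11,
        n_species=8,
        n_families=30,
        content_gain=0.15,
        content_loss=0.05,
        gap_resize=0.2,
        promoter_gain=0.4,
        promoter_loss=0.4,
    )
    return simulate_dataset(cfg)
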