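"""Synthetic genome evolution: operon-structured root genomes evolved along
a random species tree under gain/loss/reorder/gap/promoter events.

The simulator emits exactly the formats the readers consume — GFF3
annotations, a 2-column homology TSV, a Newick species tree, and a
FIMO-style motif-hit table — plus a truth log from which every tip genome
can be replayed. Family labels are inherited along the tree, providing
ground-truth orthology; promoters are simulated as motif-hit records placed
a fixed offset upstream of chosen genes, not as sequence.

Event kinds (Poisson processes per unit branch length):

- ``content_gain``: a new single-copy family joins an operon at its head
  (prepend), tail (append) or an internal position (insertion);
- ``content_loss``: one gene is deleted;
- ``reorder``: two transcription-adjacent genes in an operon swap;
- ``gap_resize``: one intra-operon gap grows or shrinks by a drawn amount,
  clamped to ≥ −30 nt so overlaps stay biologically plausible;
- ``promoter_gain`` / ``promoter_loss``: a gene's promoter flag toggles.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .genome_io import (
    Gene,
    MotifHit,
    Replicon,
    write_annotations,
    write_homology,
    write_motif_hits,
)

PROMOTER_OFFSET = 75  # motif center this many nt upstream of the start site
MOTIF_WIDTH = 14  # a BRE-TATA-like basal promoter element


@dataclass
class SimConfig:
    """Study conditions for the generator (rates are events per unit branch
    length; the default rate ordering promoter ≫ gap ≫ reorder mirrors the
    relative prevalence of these modification modes in real prokaryotic
    operon evolution)."""

    n_species: int = 8
    n_families: int = 30
    operon_size_range: tuple[int, int] = (1, 5)
    gene_length_range: tuple[int, int] = (300, 1500)
    intra_gap_range: tuple[int, int] = (0, 40)
    inter_gap_range: tuple[int, int] = (200, 800)
    promoter_head_prob: float = 0.8
    promoter_internal_prob: float = 0.2
    content_gain: float = 0.1
    content_loss: float = 0.05
    reorder: float = 0.002
    gap_resize: float = 0.24
    promoter_gain: float = 0.5
    promoter_loss: float = 0.5
    gain_prepend_prob: float = 0.45
    gain_append_prob: float = 0.45
    gain_insert_prob: float = 0.10
    gap_delta_range: tuple[int, int] = (30, 60)
    min_gap: int = -30
    circular: bool = False
    branch_length_mean: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.content_gain,
            self.content_loss,
            self.reorder,
            self.gap_resize,
            self.promoter_gain,
            self.promoter_loss,
        ):
            if r < 0:
                raise ValueError("event rates must be ≥ 0")
        s = self.gain_prepend_prob + self.gain_append_prob + self.gain_insert_prob
        if abs(s - 1.0) > 1e-9:
            raise ValueError("gain position probabilities must sum to 1")


@dataclass
class SimGene:
    family: str
    length: int
    promoter: bool


@dataclass
class SimOperon:
    """Genes in transcription order with intra-operon gaps between them."""

    strand: str
    genes: list[SimGene]
    gaps: list[int]


@dataclass
class Genome:
    operons: list[SimOperon]

    def n_genes(self) -> int:
        return sum(len(op.genes) for op in self.operons)


def simulate_tree(n_species: int, seed: int, branch_length_mean: float = 0.5) -> str:
    """A random bifurcating species tree with exponential branch lengths."""
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    subtrees = [f"S{i + 1:02d}" for i in range(n_species)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        la, lb = rng.exponential(branch_length_mean, size=2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(merged)
    return subtrees[0] + ";"


def make_root_genome(cfg: SimConfig, rng: np.random.Generator) -> Genome:
    """An operon-structured root genome over ``n_families`` fresh families."""
    fams = [f"F{i + 1:04d}" for i in range(cfg.n_families)]
    operons: list[SimOperon] = []
    i = 0
    while i < len(fams):
        size = int(rng.integers(cfg.operon_size_range[0], cfg.operon_size_range[1] + 1))
        size = min(size, len(fams) - i)
        strand = "+" if rng.random() < 0.5 else "-"
        genes = []
        for k in range(size):
            genes.append(
                SimGene(
                    family=fams[i + k],
                    length=int(
                        rng.integers(
                            cfg.gene_length_range[0], cfg.gene_length_range[1] + 1
                        )
                    ),
                    promoter=rng.random()
                    < (
                        cfg.promoter_head_prob
                        if k == 0
                        else cfg.promoter_internal_prob
                    ),
                )
            )
        gaps = [
            int(rng.integers(cfg.intra_gap_range[0], cfg.intra_gap_range[1] + 1))
            for _ in range(size - 1)
        ]
        operons.append(SimOperon(strand=strand, genes=genes, gaps=gaps))
        i += size
    return Genome(operons=operons)


EVENT_KINDS = (
    "content_gain",
    "content_loss",
    "reorder",
    "gap_resize",
    "promoter_gain",
    "promoter_loss",
)


class _SimState:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.gain_counter = 0


def _draw_event(
    genome: Genome, kind: str, cfg: SimConfig, state: _SimState
) -> dict | None:
    """Draw the concrete parameters of one event; None if inapplicable."""
    rng = state.rng
    ops = genome.operons
    if kind == "content_gain":
        oi = int(rng.integers(len(ops)))
        op = ops[oi]
        r = rng.random()
        if r < cfg.gain_prepend_prob:
            pos_class = "prepend"
            pos = 0
        elif r < cfg.gain_prepend_prob + cfg.gain_append_prob:
            pos_class = "append"
            pos = len(op.genes)
        else:
            if len(op.genes) < 2:
                pos_class = "append"
                pos = len(op.genes)
            else:
                pos_class = "insertion"
                pos = int(rng.integers(1, len(op.genes)))
        state.gain_counter += 1
        return {
            "kind": kind,
            "operon": oi,
            "position": pos,
            "position_class": pos_class,
            "family": f"G{state.gain_counter:04d}",
            "gene_length": int(
                rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1)
            ),
            "gap": int(
                rng.integers(cfg.intra_gap_range[0], cfg.intra_gap_range[1] + 1)
            ),
            "promoter": bool(rng.random() < cfg.promoter_internal_prob),
        }
    if kind == "content_loss":
        if genome.n_genes() <= 1:
            return None
        oi = int(rng.integers(len(ops)))
        gi = int(rng.integers(len(ops[oi].genes)))
        return {"kind": kind, "operon": oi, "gene": gi}
    if kind == "reorder":
        multi = [i for i, op in enumerate(ops) if len(op.genes) >= 2]
        if not multi:
            return None
        oi = multi[int(rng.integers(len(multi)))]
        gi = int(rng.integers(len(ops[oi].genes) - 1))
        return {"kind": kind, "operon": oi, "gene": gi}
    if kind == "gap_resize":
        multi = [i for i, op in enumerate(ops) if len(op.genes) >= 2]
        if not multi:
            return None
        oi = multi[int(rng.integers(len(multi)))]
        gi = int(rng.integers(len(ops[oi].gaps)))
        mag = int(rng.integers(cfg.gap_delta_range[0], cfg.gap_delta_range[1] + 1))
        delta = mag if rng.random() < 0.5 else -mag
        return {"kind": kind, "operon": oi, "gap": gi, "delta": delta}
    if kind in ("promoter_gain", "promoter_loss"):
        want = kind == "promoter_loss"
        candidates = [
            (i, j)
            for i, op in enumerate(ops)
            for j, g in enumerate(op.genes)
            if g.promoter is want
        ]
        if not candidates:
            return None
        oi, gi = candidates[int(rng.integers(len(candidates)))]
        return {"kind": kind, "operon": oi, "gene": gi}
    raise ValueError(f"unknown event kind {kind}")


def apply_event(genome: Genome, ev: dict, min_gap: int = -30) -> None:
    """Apply one recorded event in place (used both live and in replay)."""
    kind = ev["kind"]
    op = genome.operons[ev["operon"]]
    if kind == "content_gain":
        pos = ev["position"]
        op.genes.insert(
            pos,
            SimGene(
                family=ev["family"],
                length=ev["gene_length"],
                promoter=ev["promoter"],
            ),
        )
        if len(op.genes) > 1:
            gap_idx = min(pos, len(op.genes) - 2)
            op.gaps.insert(gap_idx, ev["gap"])
    elif kind == "content_loss":
        gi = ev["gene"]
        op.genes.pop(gi)
        if op.gaps:
            op.gaps.pop(min(gi, len(op.gaps) - 1))
        if not op.genes:
            genome.operons.remove(op)
    elif kind == "reorder":
        gi = ev["gene"]
        op.genes[gi], op.genes[gi + 1] = op.genes[gi + 1], op.genes[gi]
    elif kind == "gap_resize":
        gi = ev["gap"]
        op.gaps[gi] = max(min_gap, op.gaps[gi] + ev["delta"])
    elif kind == "promoter_gain":
        op.genes[ev["gene"]].promoter = True
    elif kind == "promoter_loss":
        op.genes[ev["gene"]].promoter = False
    else:
        raise ValueError(f"unknown event kind {kind}")


@dataclass
class SimResult:
    newick: str
    replicons: dict[str, dict[str, Replicon]]  # species -> replicon_id -> Replicon
    homology: dict[str, str]
    motif_hits: list[MotifHit]
    truth_log: list[dict]
    true_operons: dict[str, Genome]
    root: Genome
    config: SimConfig


def layout_genome(
    genome: Genome, species_id: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[Replicon, dict[str, str], list[MotifHit]]:
    """Assign coordinates to a tip genome and emit its motif hits.

    Operons are laid out left to right with inter-operon spacers; within an
    operon, genes follow transcription order for + operons and reverse
    coordinate order for − operons, preserving the configured gaps. Each
    promoter-flagged gene yields one motif hit centered ``PROMOTER_OFFSET``
    nt upstream of its start site, on the gene's strand.
    """
    rep_id = f"{species_id}_chr"
    cursor = 1 + int(rng.integers(cfg.inter_gap_range[0], cfg.inter_gap_range[1] + 1))
    genes: list[Gene] = []
    homology: dict[str, str] = {}
    hits: list[MotifHit] = []
    idx = 0
    for op in genome.operons:
        coord_genes = op.genes if op.strand == "+" else op.genes[::-1]
        coord_gaps = op.gaps if op.strand == "+" else op.gaps[::-1]
        for k, sg in enumerate(coord_genes):
            if k > 0:
                cursor += coord_gaps[k - 1] + 1
            start = cursor
            end = start + sg.length - 1
            gid = f"{species_id}_{idx:04d}"
            idx += 1
            genes.append(
                Gene(
                    gene_id=gid,
                    species_id=species_id,
                    replicon_id=rep_id,
                    start=start,
                    end=end,
                    strand=op.strand,
                    family_id=sg.family,
                )
            )
            homology[gid] = sg.family
            if sg.promoter:
                center = start - PROMOTER_OFFSET if op.strand == "+" else end + PROMOTER_OFFSET
                hits.append(
                    MotifHit(
                        replicon_id=rep_id,
                        start=center - MOTIF_WIDTH // 2,
                        end=center - MOTIF_WIDTH // 2 + MOTIF_WIDTH - 1,
                        strand=op.strand,
                        score=10.0,
                        q_value=1e-4,
                        motif_id="BRE-TATA",
                    )
                )
            cursor = end
        cursor += int(
            rng.integers(cfg.inter_gap_range[0], cfg.inter_gap_range[1] + 1)
        )
    length = cursor + PROMOTER_OFFSET + MOTIF_WIDTH
    rep = Replicon(
        replicon_id=rep_id,
        species_id=species_id,
        length=length,
        circular=cfg.circular,
        genes=genes,
    )
    # assign family labels to the sorted genes too (Replicon re-sorts)
    return rep, homology, hits


def _assign_branch_names(node: TreeNode, prefix: str = "root") -> None:
    """Deterministic branch names: tip name, or path-derived for unnamed
    internal nodes (shared by evolve and replay)."""
    for i, child in enumerate(node.children):
        bname = child.name if child.name else f"{prefix}.{i}"
        child.branch_name = bname
        _assign_branch_names(child, bname)


def evolve(
    root: Genome, newick: str, cfg: SimConfig
) -> SimResult:
    """Evolve ``root`` along the tree, emitting tip genomes and a truth log.

    Event counts per branch are Poisson(rate × branch length); an event
    that would empty the genome is rejected, resampled once, and logged.
    Identical config and seed reproduce the output exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    state = _SimState(rng)
    tree = TreeNode.read(io.StringIO(newick))
    _assign_branch_names(tree)
    truth_log: list[dict] = []
    tip_genomes: dict[str, Genome] = {}

    rates = {
        "content_gain": cfg.content_gain,
        "content_loss": cfg.content_loss,
        "reorder": cfg.reorder,
        "gap_resize": cfg.gap_resize,
        "promoter_gain": cfg.promoter_gain,
        "promoter_loss": cfg.promoter_loss,
    }

    def descend(node: TreeNode, genome: Genome) -> None:
        length = node.length or 0.0
        for kind in EVENT_KINDS:
            n_events = rng.poisson(rates[kind] * length)
            for _ in range(n_events):
                ev = _draw_event(genome, kind, cfg, state)
                if ev is None:
                    continue
                ev["branch"] = node.branch_name
                apply_event(genome, ev, min_gap=cfg.min_gap)
                truth_log.append(ev)
        if node.is_tip():
            tip_genomes[node.name] = genome
        else:
            for child in node.children:
                descend(child, copy.deepcopy(genome))

    for child in tree.children:
        descend(child, copy.deepcopy(root))

    layout_rng = np.random.default_rng(cfg.seed + 10_000_019)
    replicons: dict[str, dict[str, Replicon]] = {}
    homology: dict[str, str] = {}
    hits: list[MotifHit] = []
    for sp in sorted(tip_genomes):
        rep, hom, h = layout_genome(tip_genomes[sp], sp, cfg, layout_rng)
        replicons[sp] = {rep.replicon_id: rep}
        homology.update(hom)
        hits.extend(h)
    return SimResult(
        newick=newick,
        replicons=replicons,
        homology=homology,
        motif_hits=hits,
        truth_log=truth_log,
        true_operons=tip_genomes,
        root=root,
        config=cfg,
    )


def replay(root: Genome, newick: str, truth_log: Sequence[dict], min_gap: int = -30
           ) -> dict[str, Genome]:
    """Replay a truth log from the root genome, reproducing tip genomes.

    Events are applied along each root-to-tip path in log order; the result
    must equal the simulator's tip genomes exactly (tested invariant).
    """
    tree = TreeNode.read(io.StringIO(newick))
    _assign_branch_names(tree)
    tips: dict[str, Genome] = {}

    def path_names(node: TreeNode) -> list[str]:
        names = []
        while node.parent is not None:
            names.append(node.branch_name)
            node = node.parent
        return names[::-1]

    for tip in tree.tips():
        lineage = set(path_names(tip))
        genome = copy.deepcopy(root)
        for ev in truth_log:
            if ev["branch"] in lineage:
                apply_event(genome, ev, min_gap=min_gap)
        tips[tip.name] = genome
    return tips


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Tree + root genome + evolution in one call (all seeded from cfg)."""
    rng = np.random.default_rng(cfg.seed)
    newick = simulate_tree(cfg.n_species, seed=cfg.seed, branch_length_mean=cfg.branch_length_mean)
    root = make_root_genome(cfg, rng)
    return evolve(root, newick, cfg)


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, str]:
    """Write the four consumer formats plus the truth log and species map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    species_map_lines = []
    for sp, reps in result.replicons.items():
        p = outdir / f"{sp}.gff3"
        write_annotations(reps.values(), p)
        species_map_lines.append(f"{p}\t{sp}")
        paths[f"annotations:{sp}"] = str(p)
    (outdir / "species_map.tsv").write_text("\n".join(species_map_lines) + "\n")
    write_homology(result.homology, outdir / "homology.tsv")
    (outdir / "tree.nwk").write_text(result.newick + "\n")
    write_motif_hits(result.motif_hits, outdir / "motifs.tsv")
    (outdir / "truth_log.json").write_text(json.dumps(result.truth_log, indent=1))
    (outdir / "sim_config.json").write_text(json.dumps(asdict(result.config), indent=1))
    paths.update(
        {
            "species_map": str(outdir / "species_map.tsv"),
            "homology": str(outdir / "homology.tsv"),
            "tree": str(outdir / "tree.nwk"),
            "motifs": str(outdir / "motifs.tsv"),
            "truth_log": str(outdir / "truth_log.json"),
        }
    )
    return paths
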