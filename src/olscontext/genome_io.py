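"""Input/output for genome annotations, homology maps, motif hits and trees.

All coordinates are 1-based inclusive (GFF3 convention). A gene's "start
site" means the translation start: the ``start`` coordinate on the + strand
and the ``end`` coordinate on the − strand.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: GFF3 feature types considered protein-coding genes by default. RNA
#: features are excluded from operon prediction unless explicitly requested.
DEFAULT_FEATURE_TYPES = ("CDS",)


@dataclass(frozen=True)
class Gene:
    """A single annotated gene (atomic unit of all downstream analyses)."""

    gene_id: str
    species_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    family_id: str | None = None
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def start_site(self) -> int:
        """Translation start: ``start`` for + genes, ``end`` for − genes."""
        return self.start if self.strand == "+" else self.end

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def with_family(self, family_id: str | None) -> "Gene":
        return replace(self, family_id=family_id)


@dataclass
class Replicon:
    """One chromosome/plasmid with its coordinate-sorted genes."""

    replicon_id: str
    species_id: str
    length: int
    circular: bool = False
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id} extends past replicon "
                    f"{self.replicon_id} length {self.length}"
                )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class MotifHit:
    """A single promoter-motif hit (FIMO-style)."""

    replicon_id: str
    start: int
    end: int
    strand: str
    score: float
    q_value: float
    motif_id: str = "motif"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("motif hit end < start")
        if self.strand not in STRANDS:
            raise ValueError(f"bad motif strand {self.strand!r}")

    @property
    def center(self) -> int:
        # integer floor of the midpoint, by convention
        return (self.start + self.end) // 2


def _attr_field(attrs: str, keys: Sequence[str]) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        if k in keys:
            return v
    return None


def read_annotations(
    paths: Iterable[str | Path],
    species: Mapping[str, str],
    fmt: str = "gff3",
    feature_types: Sequence[str] = DEFAULT_FEATURE_TYPES,
    replicon_lengths: Mapping[str, int] | None = None,
    circular: bool = False,
) -> dict[str, dict[str, Replicon]]:
    """Read gene annotations, returning ``{species_id: {replicon_id: Replicon}}``.

    Parameters
    ----------
    paths:
        Annotation files, GFF3 or tabular (TSV with columns replicon_id,
        start, end, strand, gene_id and optionally annotation).
    species:
        Required mapping from each file path (as given) to its species id.
        Species identity is never guessed from filenames.
    feature_types:
        GFF3 feature types to keep (default protein-coding CDS only).
    replicon_lengths:
        Known replicon lengths; when a replicon is absent the length is
        inferred as the maximum gene end and a warning is logged.
    """
    if fmt not in ("gff3", "table"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    genes_by_rep: dict[tuple[str, str], list[Gene]] = {}
    seen_ids: dict[str, set[str]] = {}
    declared_lengths: dict[str, int] = dict(replicon_lengths or {})
    for path in paths:
        key = str(path)
        if key not in species:
            raise KeyError(f"no species id configured for annotation file {key}")
        sp = species[key]
        seen = seen_ids.setdefault(sp, set())
        if fmt == "gff3":
            new, seq_regions = _parse_gff3(path, sp, feature_types)
            for rid, length in seq_regions.items():
                declared_lengths.setdefault(rid, length)
        else:
            new = _parse_table(path, sp)
        for g in new:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id} in species {sp}")
            seen.add(g.gene_id)
            genes_by_rep.setdefault((sp, g.replicon_id), []).append(g)

    out: dict[str, dict[str, Replicon]] = {}
    for (sp, rep_id), genes in genes_by_rep.items():
        if rep_id in declared_lengths:
            length = declared_lengths[rep_id]
        else:
            length = max(g.end for g in genes)
            logger.warning(
                "replicon %s length unknown; inferred %d from annotations",
                rep_id,
                length,
            )
        out.setdefault(sp, {})[rep_id] = Replicon(
            replicon_id=rep_id,
            species_id=sp,
            length=length,
            circular=circular,
            genes=genes,
        )
    return out


def _parse_gff3(
    path: str | Path, species_id: str, feature_types: Sequence[str]
) -> tuple[list[Gene], dict[str, int]]:
    import gffutils

    genes: list[Gene] = []
    seq_regions: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) == 4:
                    seq_regions[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            feat = gffutils.feature.feature_from_line(line)
            if feat.featuretype not in feature_types:
                continue
            gid = _attr_field(
                str(line.split("\t")[8]), ("ID", "Name", "locus_tag", "gene_id")
            )
            if gid is None:
                raise ValueError(f"{path}: feature without identifier: {line!r}")
            if feat.end < feat.start:
                raise ValueError(f"{path}: end < start in record {gid}")
            genes.append(
                Gene(
                    gene_id=gid,
                    species_id=species_id,
                    replicon_id=feat.seqid,
                    start=int(feat.start),
                    end=int(feat.end),
                    strand=feat.strand,
                    annotation=feat.attributes.get("product", [""])[0]
                    if "product" in feat.attributes
                    else "",
                )
            )
    return genes, seq_regions


_TABLE_COLS = ["replicon_id", "start", "end", "strand", "gene_id"]


def _parse_table(path: str | Path, species_id: str) -> list[Gene]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise ValueError(f"{path}: end < start in record {row.gene_id}")
        genes.append(
            Gene(
                gene_id=str(row.gene_id),
                species_id=species_id,
                replicon_id=str(row.replicon_id),
                start=start,
                end=end,
                strand=str(row.strand),
                annotation=str(getattr(row, "annotation", "") or ""),
            )
        )
    return genes


def write_annotations(replicons: Iterable[Replicon], path: str | Path) -> None:
    """Write replicons as GFF3 (CDS features; round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in replicons:
            fh.write(f"##sequence-region {rep.replicon_id} 1 {rep.length}\n")
            for g in rep.genes:
                attrs = f"ID={g.gene_id}"
                if g.annotation:
                    attrs += f";product={g.annotation}"
                fh.write(
                    "\t".join(
                        [
                            rep.replicon_id,
                            "olscontext",
                            "CDS",
                            str(g.start),
                            str(g.end),
                            ".",
                            g.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_homology(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (gene_id, family_id) into a mapping.

    A gene listed under two different families is a hard error; genes absent
    from the table simply have no family.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] < 2:
        raise ValueError(f"{path}: homology table needs two columns")
    mapping: dict[str, str] = {}
    for gid, fam in zip(df.iloc[:, 0], df.iloc[:, 1]):
        gid, fam = str(gid), str(fam)
        if gid in mapping and mapping[gid] != fam:
            raise ValueError(
                f"{path}: gene {gid} mapped to both {mapping[gid]} and {fam}"
            )
        mapping[gid] = fam
    return mapping


def write_homology(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, fam in mapping.items():
            fh.write(f"{gid}\t{fam}\n")


_FIMO_RENAMES = {
    "sequence name": "sequence_name",
    "p-value": "p_value",
    "q-value": "q_value",
}


def read_motif_hits(path: str | Path, q_threshold: float = 0.001) -> list[MotifHit]:
    """Read FIMO-style TSV motif hits, dropping hits with q-value > threshold.

    The default threshold of 0.001 matches the promoter-motif significance
    cutoff used throughout; pass ``q_threshold=1.0`` to keep everything.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    df = df.rename(columns=_FIMO_RENAMES)
    if "strand" not in df.columns:
        raise ValueError(f"{path}: FIMO table missing strand column")
    for col in ("sequence_name", "start", "stop", "q_value"):
        if col not in df.columns:
            raise ValueError(f"{path}: FIMO table missing column {col}")
    n_before = len(df)
    df = df[df["q_value"].astype(float) <= q_threshold]
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d motif hits with q-value > %g", dropped, q_threshold)
    hits = []
    for row in df.itertuples(index=False):
        s, e = int(row.start), int(row.stop)
        hits.append(
            MotifHit(
                replicon_id=str(row.sequence_name),
                start=min(s, e),
                end=max(s, e),
                strand=str(row.strand),
                score=float(getattr(row, "score", 0.0)),
                q_value=float(row.q_value),
                motif_id=str(getattr(row, "motif_id", "motif")),
            )
        )
    return hits


def write_motif_hits(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "motif_id\tsequence_name\tstart\tstop\tstrand\tscore\tp-value\tq-value\n"
        )
        for h in hits:
            fh.write(
                f"{h.motif_id}\t{h.replicon_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.score}\t{h.q_value}\t{h.q_value}\n"
            )


def patristic_distances(newick: str | Path) -> DistanceMatrix:
    """Pairwise patristic distances: sum of branch lengths along tip paths.

    Accepts a Newick string or a path to one. Every edge must carry a branch
    length and tip names must be unique.
    """
    text = str(newick)
    p = Path(text) if len(text) < 4096 and "\n" not in text else None
    if p is not None and p.exists():
        text = p.read_text()
    tree = TreeNode.read(io.StringIO(text))
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf names in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                f"missing branch length on node {node.name or '<internal>'}"
            )
    if len(tips) == 1:
        return DistanceMatrix([[0.0]], ids=names)
    return tree.tip_tip_distances()
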