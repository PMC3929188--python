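"""Gene models, category membership maps, and the enrichment universe.

Gene models carry the exon-union length that serves as the "kb" in RPKM.
Category maps are flat gene lists (GO terms, KEGG pathways, transcription
factor families); no ontology-graph propagation is performed.

Coordinate conventions: files (GFF3, the gene-model TSV ``location`` column)
use 1-based inclusive coordinates; all internal interval arithmetic is
0-based half-open. Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

NAMESPACES = ("GO", "KEGG", "TF")

GENE_MODEL_TSV_COLUMNS = ("gene_id", "exon_length", "location", "description")
CATEGORY_TSV_COLUMNS = ("category_id", "label", "gene_id")

_LOCATION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+\-.])\)$")


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene with its exon-union length.

    ``start``/``end`` are 1-based inclusive genomic coordinates of the gene
    span. ``exons``, when present, holds the merged (disjoint, sorted)
    exon-union intervals in the same convention; when absent the gene span
    itself acts as the exon union for read-overlap purposes.
    """

    gene_id: str
    exon_length: int
    chrom: str
    start: int
    end: int
    strand: str = "."
    description: str = ""
    exons: tuple[tuple[int, int], ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.exon_length < 1:
            raise ValueError(f"{self.gene_id}: exon_length must be >= 1, got {self.exon_length}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def location(self) -> str:
        """``chrom:start-end(strand)`` as written in the gene-model TSV."""
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    def exon_intervals(self) -> tuple[tuple[int, int], ...]:
        """Merged exon intervals (1-based inclusive); the gene span if unknown."""
        if self.exons is not None:
            return self.exons
        return ((self.start, self.end),)


@dataclass(frozen=True)
class CategoryMap:
    """A flat gene category: one GO term, KEGG pathway, or TF family."""

    category_id: str
    label: str
    namespace: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"namespace must be one of {NAMESPACES}, got {self.namespace!r}")
        if not self.members:
            raise ValueError(f"{self.category_id}: category has no members")

    @property
    def size(self) -> int:
        return len(self.members)

    def restrict(self, universe: "Universe") -> "CategoryMap | None":
        """Drop members outside *universe*; None if nothing remains."""
        kept = self.members & universe.gene_ids
        if not kept:
            return None
        return CategoryMap(self.category_id, self.label, self.namespace, kept)


@dataclass(frozen=True)
class Universe:
    """The background gene set within which enrichment counts are taken."""

    gene_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 0-based half-open intervals into a sorted disjoint union.

    Adjacent intervals (end == next start) are coalesced, so splitting an
    exon into abutting pieces does not change the union.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"invalid interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def exon_union(exons_1based: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge 1-based inclusive exon intervals; returns the same convention."""
    zero_based = [(s - 1, e) for s, e in exons_1based]
    return tuple((s + 1, e) for s, e in merge_intervals(zero_based))


def exon_union_length(exons_1based: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by the union of 1-based inclusive exon intervals."""
    return sum(e - s + 1 for s, e in exon_union(exons_1based))


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or the four-column gene-model TSV.

    For GFF3, ``exon_length`` is the length of the union of that gene's exon
    intervals over all transcripts, with overlaps merged. A gene with no
    exon features is a hard error. Duplicate gene ids are a hard error in
    either dialect.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if fmt == "gff3":
        genes = _read_gff3(path)
    elif fmt == "tsv":
        genes = _read_gene_model_tsv(path)
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [
            (ex.start, ex.end)
            for ex in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            raise ValueError(f"gene {gene.id!r} has no exon features in {path}")
        union = exon_union(exons)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                exon_length=sum(e - s + 1 for s, e in union),
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in ("+", "-") else ".",
                description=gene.attributes.get("Note", [""])[0]
                or gene.attributes.get("description", [""])[0],
                exons=union,
            )
        )
    return genes


def _read_gene_model_tsv(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(GENE_MODEL_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene-model TSV is missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        m = _LOCATION_RE.match(row.location)
        if not m:
            raise ValueError(f"{path}: cannot parse location {row.location!r}")
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                exon_length=int(row.exon_length),
                chrom=m["chrom"],
                start=int(m["start"]),
                end=int(m["end"]),
                strand=m["strand"],
                description="" if pd.isna(row.description) else str(row.description),
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write the gene-model TSV dialect (round-trips with read_gene_models)."""
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "exon_length": [g.exon_length for g in genes],
            "location": [g.location for g in genes],
            "description": [g.description for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_category_map(
    path: str | Path,
    namespace: str,
    universe: Universe | None = None,
) -> list[CategoryMap]:
    """Read a category-membership TSV (category_id, label, gene_id).

    Duplicate (category, gene) pairs are collapsed. When a universe is
    supplied, member genes outside it are logged and dropped; categories
    left empty are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(CATEGORY_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: category TSV is missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty category file (namespace %s)", path, namespace)
        return []
    n_categories_before = df["category_id"].nunique()
    if universe is not None:
        outside = ~df["gene_id"].isin(universe.gene_ids)
        if outside.any():
            logger.warning(
                "%s: dropped %d membership rows with gene ids outside the universe",
                path,
                int(outside.sum()),
            )
            df = df[~outside]
    categories: list[CategoryMap] = []
    for cat_id, group in df.groupby("category_id", sort=True):
        labels = group["label"].unique()
        categories.append(
            CategoryMap(str(cat_id), str(labels[0]), namespace, frozenset(group["gene_id"]))
        )
    if len(categories) < n_categories_before:
        logger.warning(
            "%s: %d categories dropped entirely (no members in universe)",
            path,
            n_categories_before - len(categories),
        )
    return categories


def write_category_map(categories: Sequence[CategoryMap], path: str | Path) -> None:
    rows = [
        (c.category_id, c.label, gene)
        for c in sorted(categories, key=lambda c: c.category_id)
        for gene in sorted(c.members)
    ]
    pd.DataFrame(rows, columns=list(CATEGORY_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def make_universe(genes: Sequence[GeneModel] | Iterable[str]) -> Universe:
    """Background universe from gene models (or bare gene ids)."""
    ids = frozenset(g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes)
    if not ids:
        raise ValueError("cannot build a universe from an empty gene set")
    return Universe(ids)
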