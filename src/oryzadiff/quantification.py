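"""RPKM quantification from weighted alignment counts.

Each mapped alignment record contributes weight 1/NH (the reciprocal of the
number of reported genome locations for that read) to the single gene whose
exon union it overlaps. Records overlapping two or more genes are excluded
from gene counts to avoid double counting, but still contribute their weight
to the mapped-read total. Paired-end mates are counted as two independent
records.

Expression is reported as RPB (reads per billion mapped reads) and RPKM
(reads per kilobase of exon model per million mapped reads); "total reads"
in the RPKM denominator means mapped reads, the quantity observable from the
alignment stream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotations import GeneModel

logger = logging.getLogger(__name__)

LEVEL_BINS = ("not_detected", "low", "modest", "high", "extreme")

#: Left-closed RPKM bin edges separating low/modest/high/extreme expression.
LEVEL_BIN_EDGES = (10.0, 100.0, 1000.0)

DEFAULT_EXPRESSED_THRESHOLD = 1.0


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of one read: position, aligned reference span, NH count."""

    read_id: str
    chrom: str | None
    start: int  # 0-based reference start
    end: int  # 0-based exclusive reference end (from CIGAR)
    n_hits: int
    mapped: bool

    def __post_init__(self) -> None:
        if self.n_hits < 1:
            raise ValueError(f"{self.read_id}: NH must be >= 1")
        if self.mapped and self.chrom is None:
            raise ValueError(f"{self.read_id}: mapped record without a position")


@dataclass
class CountTable:
    """Per-gene weighted read counts plus the weighted mapped-read total.

    ``counts`` is indexed by gene_id and covers every annotated gene (zeros
    included); ``total_mapped_reads`` accumulates 1/NH over all mapped
    records, assigned to a gene or not.
    """

    counts: pd.Series
    total_mapped_reads: float

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("negative weighted count")
        if self.total_mapped_reads < 0:
            raise ValueError("negative total_mapped_reads")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total_mapped_reads={self.total_mapped_reads!r}\n")
            fh.write("gene_id\tweighted_count\n")
            for gene_id, count in self.counts.items():
                fh.write(f"{gene_id}\t{count!r}\n")

    @classmethod
    def read(cls, path: str | Path) -> "CountTable":
        total = None
        with open(path) as fh:
            first = fh.readline().strip()
            if not first.startswith("#total_mapped_reads="):
                raise ValueError(f"{path}: missing #total_mapped_reads= header line")
            total = float(first.split("=", 1)[1])
        df = pd.read_csv(path, sep="\t", comment="#")
        counts = pd.Series(df["weighted_count"].values, index=df["gene_id"].values, dtype=float)
        return cls(counts=counts, total_mapped_reads=total)


def iter_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM file (plain text suffices).

    A missing NH tag is treated as NH=1 with a single logged warning.
    """
    warned = False
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                yield AlignmentRecord(rec.query_name, None, -1, -1, 1, False)
                continue
            try:
                nh = int(rec.get_tag("NH"))
            except KeyError:
                if not warned:
                    logger.warning("%s: NH tag absent; treating reads as uniquely mapped", path)
                    warned = True
                nh = 1
            yield AlignmentRecord(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                n_hits=nh,
                mapped=True,
            )


def _exon_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over exon-union intervals (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exon_intervals():
            tree.addi(s - 1, e, g.gene_id)
    return trees


def weighted_gene_counts(
    alignments: Iterable[AlignmentRecord] | str | Path,
    genes: Sequence[GeneModel],
) -> CountTable:
    """Accumulate 1/NH-weighted counts per gene from an alignment stream.

    Assignment rule: an alignment is assigned when at least one aligned base
    overlaps exactly one gene's exon union; alignments overlapping several
    genes are discarded from gene counts (they still count toward the
    mapped-read total), and unmapped records contribute nothing.
    """
    if isinstance(alignments, (str, Path)):
        alignments = iter_sam(alignments)
    trees = _exon_trees(genes)
    counts = {g.gene_id: 0.0 for g in genes}
    total = 0.0
    for rec in alignments:
        if not rec.mapped:
            continue
        w = 1.0 / rec.n_hits
        total += w
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        hit_genes = {iv.data for iv in tree.overlap(rec.start, rec.end)}
        if len(hit_genes) == 1:
            counts[hit_genes.pop()] += w
    return CountTable(
        counts=pd.Series(counts, dtype=float),
        total_mapped_reads=total,
    )


def rpkm(
    weighted_count: float | np.ndarray,
    exon_length: float | np.ndarray,
    total_mapped_reads: float,
) -> float | np.ndarray:
    """Reads per kilobase of exon model per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if np.any(np.asarray(exon_length) < 1):
        raise ValueError("exon_length must be >= 1")
    return weighted_count / ((np.asarray(exon_length) / 1e3) * (total_mapped_reads / 1e6))


def rpb(weighted_count: float | np.ndarray, total_mapped_reads: float) -> float | np.ndarray:
    """Reads per billion mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return 1e9 * weighted_count / total_mapped_reads


def call_expressed(
    rpkm_values: pd.Series | np.ndarray,
    threshold: float = DEFAULT_EXPRESSED_THRESHOLD,
) -> pd.Series | np.ndarray:
    """Expressed iff RPKM strictly exceeds the threshold (default 1)."""
    if threshold <= 0:
        raise ValueError("expressed threshold must be positive")
    return rpkm_values > threshold


def assign_level_bins(
    rpkm_values: pd.Series,
    threshold: float = DEFAULT_EXPRESSED_THRESHOLD,
    edges: Sequence[float] = LEVEL_BIN_EDGES,
) -> pd.Series:
    """Partition genes into expression-level bins.

    Unexpressed genes (RPKM <= threshold) are ``not_detected``; expressed
    genes fall into left-closed right-open bins
    [threshold, e1), [e1, e2), [e2, e3), [e3, inf) labelled
    low / modest / high / extreme.
    """
    e1, e2, e3 = edges
    expressed = call_expressed(rpkm_values, threshold)
    conditions = [
        ~expressed,
        expressed & (rpkm_values < e1),
        expressed & (rpkm_values >= e1) & (rpkm_values < e2),
        expressed & (rpkm_values >= e2) & (rpkm_values < e3),
        expressed & (rpkm_values >= e3),
    ]
    out = np.select(conditions, LEVEL_BINS, default="not_detected")
    return pd.Series(pd.Categorical(out, categories=LEVEL_BINS), index=rpkm_values.index)


def expression_profile(
    table: CountTable,
    genes: Sequence[GeneModel],
    threshold: float = DEFAULT_EXPRESSED_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene expression profile: weighted count, RPB, RPKM, expressed flag, level bin."""
    lengths = pd.Series({g.gene_id: g.exon_length for g in genes}, dtype=float)
    counts = table.counts.reindex(lengths.index, fill_value=0.0)
    df = pd.DataFrame(
        {
            "weighted_count": counts,
            "rpb": rpb(counts.values, table.total_mapped_reads),
            "rpkm": rpkm(counts.values, lengths.values, table.total_mapped_reads),
        },
        index=lengths.index,
    )
    df["expressed"] = call_expressed(df["rpkm"], threshold)
    df["level_bin"] = assign_level_bins(df["rpkm"], threshold)
    df.index.name = "gene_id"
    return df


def bin_expression_levels(profile: pd.DataFrame) -> pd.Series:
    """Counts per expression-level bin; sums to the number of genes."""
    return profile["level_bin"].value_counts().reindex(list(LEVEL_BINS), fill_value=0)


def log2_histogram(
    rpkm_values: pd.Series | np.ndarray,
    bin_width: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of log2(RPKM) over genes with RPKM > 0.

    Bin edges are aligned to integer multiples of ``bin_width`` so that the
    histogram of a fixed profile does not depend on which other genes are
    present. Returns (edges, frequencies); frequencies sum to the number of
    included genes.
    """
    vals = np.asarray(rpkm_values, dtype=float)
    vals = np.log2(vals[vals > 0])
    if vals.size == 0:
        return np.array([]), np.array([], dtype=int)
    lo = math.floor(vals.min() / bin_width) * bin_width
    hi = math.ceil(vals.max() / bin_width) * bin_width
    n_bins = max(1, round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    # np.histogram closes the last bin on the right, which would merge the
    # top edge into the final bin; pad one extra bin so every bin is [a, b).
    edges_padded = np.append(edges, edges[-1] + bin_width)
    freq, _ = np.histogram(vals, bins=edges_padded)
    if freq[-1]:
        edges = edges_padded
    else:
        freq = freq[:-1]
    return edges, freq
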