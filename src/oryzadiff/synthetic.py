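"""Synthetic two-condition study generator with known ground truth.

Emulates the structure of a rice leaf-blade two-temperature experiment:
~half of annotated genes expressed, long-tailed expression (most expressed
genes below 10 RPKM, ~3% above 100), two conditions differing by a planted
set of regulated genes, and gene categories with planted over-representation
among the regulated genes. Counts are drawn per gene per condition from a
Poisson (default) or negative-binomial law whose mean follows the RPKM
identity, so the whole pipeline can be exercised, and its calls scored
against truth, without any sequencing data.

Scaling: true per-condition RPKMs are rescaled so that sum(rpkm * kb)
equals 1e6, which makes the expected empirical RPKM equal the recorded
truth (real RPKM is compositional in the same way).

Three independent RNG streams (annotation / counts / SAM) are derived from
the seed so each artifact can be regenerated on its own.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import CategoryMap, GeneModel
from .quantification import CountTable

_READ_LENGTH = 90


@dataclass(frozen=True)
class CategorySpec:
    """Blueprint for one synthetic category."""

    size: int
    namespace: str = "GO"
    planted: bool = False
    enrichment_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("category size must be >= 1")
        if self.enrichment_factor < 1:
            raise ValueError("planted_enrichment_factor must be >= 1")


def default_categories() -> tuple[CategorySpec, ...]:
    """A small GO/KEGG/TF panel: sizes spanning 20-200, one planted per namespace.

    TF sizes follow the rice transcription-factor super-family sizes
    (WRKY 107, NAC 124, AP2-EREBP 169, bZIP 95, MYB 128, MYB-related 100).
    """
    go = [CategorySpec(s, "GO", planted=(s == 120)) for s in (20, 40, 60, 80, 100, 120, 140, 160, 180, 200)]
    kegg = [CategorySpec(s, "KEGG", planted=(s == 150)) for s in (25, 50, 75, 100, 150, 200)]
    tf = [CategorySpec(s, "TF", planted=(s == 107)) for s in (107, 124, 169, 95, 128, 100)]
    return tuple(go + kegg + tf)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generation parameters.

    Defaults are the scaled-down study conditions: 10,000 genes, half
    expressed, log-normal RPKM with median 3 and log-sd 1.86 (~3% of
    expressed genes above 100 RPKM), a 1M-read library per condition,
    146 genes planted up at 25 degC and 99 down (the published 821/553
    scaled to 10,000 genes), planted fold 8, categories planted at
    enrichment factor 5. ``full_scale()`` gives the full-size preset.
    """

    n_genes: int = 10_000
    frac_expressed: float = 0.5
    rpkm_meanlog: float = math.log(3.0)
    rpkm_sdlog: float = 1.86
    library_size: int = 1_000_000
    n_regulated_up25: int = 146
    n_regulated_dn25: int = 99
    fold_low: float = 8.0
    fold_high: float = 8.0
    planted_min_rpkm: float = 2.0
    dispersion: float | None = None  # NB size parameter; None = Poisson
    categories: tuple[CategorySpec, ...] = field(default_factory=default_categories)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.frac_expressed <= 1:
            raise ValueError("frac_expressed must be in (0, 1]")
        if self.n_regulated_up25 + self.n_regulated_dn25 > self.n_genes:
            raise ValueError("more regulated genes than genes")
        if not 1 <= self.fold_low <= self.fold_high:
            raise ValueError("need 1 <= fold_low <= fold_high")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def full_scale(seed: int = 0) -> SimulationConfig:
    """Full-size preset: 56,143 genes, 25M reads, 821/553 planted regulated genes."""
    return SimulationConfig(
        n_genes=56_143,
        library_size=25_000_000,
        n_regulated_up25=821,
        n_regulated_dn25=553,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """The generative draw: per-gene true RPKM and the planted sets.

    ``regulated`` maps gene_id to the signed planted fold: positive folds
    mean higher at 25 degC (the pipeline's ``up25``), negative higher at
    30 degC.
    """

    true_rpkm_25: pd.Series
    true_rpkm_30: pd.Series
    regulated: pd.Series
    planted_categories: frozenset[str]

    @property
    def regulated_up25(self) -> set[str]:
        return set(self.regulated.index[self.regulated > 0])

    @property
    def regulated_dn25(self) -> set[str]:
        return set(self.regulated.index[self.regulated < 0])

    def write(self, tsv_path: str | Path, json_path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "true_rpkm_25": self.true_rpkm_25,
                "true_rpkm_30": self.true_rpkm_30,
                "planted_fold": self.regulated.reindex(self.true_rpkm_25.index, fill_value=0.0),
            }
        )
        df.index.name = "gene_id"
        df.to_csv(tsv_path, sep="\t")
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "planted_categories": sorted(self.planted_categories),
                    "n_regulated_up25": len(self.regulated_up25),
                    "n_regulated_dn25": len(self.regulated_dn25),
                },
                fh,
                indent=2,
            )


@dataclass
class SimulatedStudy:
    genes: list[GeneModel]
    categories: list[CategoryMap]
    counts_25: CountTable
    counts_30: CountTable
    truth: GroundTruth


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _make_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Single-exon gene models laid out head-to-tail along 12 chromosomes."""
    lengths = rng.integers(500, 5001, size=config.n_genes)
    genes: list[GeneModel] = []
    n_chrom = 12
    per_chrom = math.ceil(config.n_genes / n_chrom)
    pos = 1
    chrom_idx = 1
    on_chrom = 0
    for i, length in enumerate(lengths):
        if on_chrom == per_chrom:
            chrom_idx += 1
            on_chrom = 0
            pos = 1
        gene_id = f"SYN_Os{chrom_idx:02d}g{i:06d}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                exon_length=int(length),
                chrom=f"Chr{chrom_idx}",
                start=pos,
                end=pos + int(length) - 1,
                strand="+" if rng.random() < 0.5 else "-",
                description="synthetic gene",
            )
        )
        pos += int(length) + 200  # 200 bp intergenic gap
        on_chrom += 1
    return genes


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic study: gene models, categories, two count tables, truth."""
    rng_ann = _rng(config.seed, 1)
    rng_counts = _rng(config.seed, 2)

    genes = _make_genes(config, rng_ann)
    gene_ids = np.array([g.gene_id for g in genes])
    kb = np.array([g.exon_length for g in genes]) / 1e3

    n_expressed = round(config.n_genes * config.frac_expressed)
    expressed_idx = rng_ann.choice(config.n_genes, size=n_expressed, replace=False)
    base = np.zeros(config.n_genes)
    base[expressed_idx] = rng_ann.lognormal(
        config.rpkm_meanlog, config.rpkm_sdlog, size=n_expressed
    )

    # Planted regulation: draw from quantifiable expressed genes (true RPKM
    # above planted_min_rpkm), split into up-at-25 and down-at-25 sets.
    eligible = np.flatnonzero(base >= config.planted_min_rpkm)
    n_reg = config.n_regulated_up25 + config.n_regulated_dn25
    if n_reg > eligible.size:
        raise ValueError(
            f"cannot plant {n_reg} regulated genes: only {eligible.size} genes "
            f"have true RPKM >= {config.planted_min_rpkm}"
        )
    chosen = rng_ann.choice(eligible, size=n_reg, replace=False)
    up_idx = chosen[: config.n_regulated_up25]
    dn_idx = chosen[config.n_regulated_up25:]
    folds = np.exp(
        rng_ann.uniform(math.log(config.fold_low), math.log(config.fold_high), size=n_reg)
    )

    rpkm_25 = base.copy()
    rpkm_30 = base.copy()
    rpkm_25[up_idx] *= folds[: config.n_regulated_up25]
    rpkm_30[dn_idx] *= folds[config.n_regulated_up25:]

    # Per-condition compositional rescale: sum(rpkm * kb) = 1e6 so that the
    # expected total read count equals library_size and expected empirical
    # RPKM equals the recorded truth.
    rpkm_25 *= 1e6 / np.sum(rpkm_25 * kb)
    rpkm_30 *= 1e6 / np.sum(rpkm_30 * kb)

    signed = np.concatenate([folds[: config.n_regulated_up25], -folds[config.n_regulated_up25:]])
    truth = GroundTruth(
        true_rpkm_25=pd.Series(rpkm_25, index=gene_ids),
        true_rpkm_30=pd.Series(rpkm_30, index=gene_ids),
        regulated=pd.Series(signed, index=gene_ids[np.concatenate([up_idx, dn_idx])]),
        planted_categories=frozenset(),
    )

    counts_25 = _draw_counts(rpkm_25, kb, gene_ids, config, rng_counts)
    counts_30 = _draw_counts(rpkm_30, kb, gene_ids, config, rng_counts)

    categories, planted_ids = _make_categories(
        config, gene_ids, set(gene_ids[chosen]), rng_ann
    )
    truth.planted_categories = frozenset(planted_ids)

    return SimulatedStudy(genes, categories, counts_25, counts_30, truth)


def _draw_counts(
    rpkm_true: np.ndarray,
    kb: np.ndarray,
    gene_ids: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CountTable:
    mean = rpkm_true * kb * config.library_size / 1e6
    if config.dispersion is None:
        counts = rng.poisson(mean).astype(float)
    else:
        size = config.dispersion
        # NB with mean mu and size r: p = r / (r + mu); variance mu + mu^2/r
        with np.errstate(divide="ignore", invalid="ignore"):
            p = size / (size + mean)
        counts = np.where(mean > 0, rng.negative_binomial(size, np.where(mean > 0, p, 1.0)), 0).astype(float)
    return CountTable(
        counts=pd.Series(counts, index=gene_ids),
        total_mapped_reads=float(counts.sum()),
    )


def _make_categories(
    config: SimulationConfig,
    gene_ids: np.ndarray,
    regulated: set[str],
    rng: np.random.Generator,
) -> tuple[list[CategoryMap], list[str]]:
    """Draw category memberships; planted categories over-sample regulated genes.

    Each member slot of a planted category is filled from the regulated set
    with probability factor * R/N (capped at 1), otherwise uniformly from
    the non-regulated genes. Planting more members than there are regulated
    genes is a hard error.
    """
    N = len(gene_ids)
    R = len(regulated)
    reg_arr = np.array(sorted(regulated))
    nonreg_arr = np.array(sorted(set(gene_ids) - regulated))
    categories: list[CategoryMap] = []
    planted_ids: list[str] = []
    counters = {"GO": 0, "KEGG": 0, "TF": 0}
    tf_labels = ["WRKY", "NAC", "AP2-EREBP", "bZIP", "MYB", "MYB-related", "C2H2", "tify"]
    for spec in config.categories:
        counters[spec.namespace] += 1
        i = counters[spec.namespace]
        if spec.namespace == "GO":
            cat_id, label = f"GO:{7000000 + i:07d}", f"synthetic process {i}"
        elif spec.namespace == "KEGG":
            cat_id, label = f"osa{90000 + i:05d}", f"synthetic pathway {i}"
        else:
            name = tf_labels[(i - 1) % len(tf_labels)]
            cat_id, label = f"TF:{name}", f"Rice transcription factor: {name}"
        if spec.planted:
            p_reg = min(1.0, spec.enrichment_factor * R / N)
            n_from_reg = int(rng.binomial(spec.size, p_reg))
            if n_from_reg > R:
                raise ValueError(
                    f"{cat_id}: planting requires {n_from_reg} regulated members "
                    f"but only {R} regulated genes exist"
                )
            n_from_reg = min(n_from_reg, spec.size)
            members = np.concatenate(
                [
                    rng.choice(reg_arr, size=n_from_reg, replace=False),
                    rng.choice(nonreg_arr, size=spec.size - n_from_reg, replace=False),
                ]
            )
            planted_ids.append(cat_id)
        else:
            members = rng.choice(gene_ids, size=spec.size, replace=False)
        categories.append(
            CategoryMap(cat_id, label, spec.namespace, frozenset(str(m) for m in members))
        )
    return categories, planted_ids


def emit_sam_fixture(
    genes: Sequence[GeneModel],
    n_reads: int = 100,
    seed: int = 0,
    frac_multi: float = 0.2,
    frac_intergenic: float = 0.1,
    read_length: int = _READ_LENGTH,
) -> tuple[str, CountTable]:
    """Small SAM text exercising NH-weighted counting, with its expected counts.

    Reads are placed inside gene spans; a fraction are emitted twice at two
    loci with NH=2, and a fraction fall in intergenic gaps. The expected
    CountTable is computed by an independent per-read enumeration (direct
    scan of every gene against every placement, applying the 1/NH weight and
    the unique-overlap assignment rule), not by the pipeline's counter.
    """
    if n_reads > 10_000:
        raise ValueError("SAM fixtures are capped at 10,000 reads")
    rng = _rng(seed, 3)
    usable = [g for g in genes if g.end - g.start + 1 >= read_length]
    if len(usable) < 2:
        raise ValueError("need at least two genes long enough to hold a read")
    chrom_len: dict[str, int] = {}
    for g in genes:
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.end + 500)

    placements: list[list[tuple[str, int]]] = []  # per read: [(chrom, 1-based pos), ...]
    for _ in range(n_reads):
        u = rng.random()
        if u < frac_intergenic:
            g = usable[rng.integers(len(usable))]
            pos = g.end + 101  # read sits inside the 200 bp intergenic gap
            placements.append([(g.chrom, pos)])
        elif u < frac_intergenic + frac_multi:
            i, j = rng.choice(len(usable), size=2, replace=False)
            locs = []
            for g in (usable[i], usable[j]):
                start = int(rng.integers(g.start, g.end - read_length + 2))
                locs.append((g.chrom, start))
            placements.append(locs)
        else:
            g = usable[rng.integers(len(usable))]
            start = int(rng.integers(g.start, g.end - read_length + 2))
            placements.append([(g.chrom, start)])

    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_len):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}")
    for ridx, locs in enumerate(placements):
        nh = len(locs)
        for chrom, pos in locs:
            lines.append(
                f"read{ridx:05d}\t0\t{chrom}\t{pos}\t255\t{read_length}M\t*\t0\t0\t*\t*\tNH:i:{nh}"
            )
    sam_text = "\n".join(lines) + "\n"

    expected = _enumerate_expected_counts(placements, genes, read_length)
    return sam_text, expected


def _enumerate_expected_counts(
    placements: Sequence[Sequence[tuple[str, int]]],
    genes: Sequence[GeneModel],
    read_length: int,
) -> CountTable:
    """Brute-force per-read weight enumeration (the counting oracle)."""
    counts = {g.gene_id: 0.0 for g in genes}
    total = 0.0
    for locs in placements:
        w = 1.0 / len(locs)
        for chrom, pos in locs:
            total += w
            span = (pos, pos + read_length - 1)  # 1-based inclusive
            hits = []
            for g in genes:
                if g.chrom != chrom:
                    continue
                for es, ee in g.exon_intervals():
                    if span[0] <= ee and es <= span[1]:
                        hits.append(g.gene_id)
                        break
            if len(hits) == 1:
                counts[hits[0]] += w
    return CountTable(
        counts=pd.Series(counts, dtype=float),
        total_mapped_reads=total,
    )


@dataclass
class RecoveryReport:
    """Pipeline-vs-truth metrics for one simulated study."""

    sensitivity: float | None  # fraction of planted regulated genes called at >= fold
    false_positive_rate: float
    n_called: int
    planted_category_ranks: dict[str, int]
    planted_above_all_others: bool | None

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "false_positive_rate": self.false_positive_rate,
            "n_called": self.n_called,
            "planted_category_ranks": dict(self.planted_category_ranks),
            "planted_above_all_others": self.planted_above_all_others,
        }


def recovery_report(
    called_regulated: Sequence[str],
    enrichment_results: pd.DataFrame | None,
    truth: GroundTruth,
    n_genes: int,
) -> RecoveryReport:
    """Score pipeline calls against the planted truth by direct set comparison."""
    called = set(called_regulated)
    planted = set(truth.regulated.index)
    if planted:
        sensitivity = len(called & planted) / len(planted)
    else:
        sensitivity = None
    negatives = n_genes - len(planted)
    fpr = len(called - planted) / negatives if negatives else 0.0

    ranks: dict[str, int] = {}
    above_all: bool | None = None
    if enrichment_results is not None and len(enrichment_results) and truth.planted_categories:
        by_id = enrichment_results.set_index("category_id")
        for cat in sorted(truth.planted_categories):
            if cat in by_id.index:
                ranks[cat] = int(by_id.loc[cat, "rank"])
        planted_mask = enrichment_results["category_id"].isin(truth.planted_categories)
        if planted_mask.any() and (~planted_mask).any():
            above_all = bool(
                enrichment_results.loc[planted_mask, "p_value"].max()
                < enrichment_results.loc[~planted_mask, "p_value"].min()
            )
    return RecoveryReport(
        sensitivity=sensitivity,
        false_positive_rate=fpr,
        n_called=len(called),
        planted_category_ranks=ranks,
        planted_above_all_others=above_all,
    )
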