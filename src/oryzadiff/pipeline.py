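"""End-to-end orchestration: counts -> RPKM -> fold changes -> enrichment -> reports.

Every threshold the analysis uses lives in :class:`AnalysisConfig`, never as
a literal in the stage code, so the published constants (expressed at
>1 RPKM, regulated at 2-fold or higher, class edges 1.5/2/3) are
reproducible and alternatives explorable. Outputs are deterministic for
fixed inputs and config; every file carries a header with the tool version
and a hash of the config that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotations import (
    CategoryMap,
    GeneModel,
    Universe,
    make_universe,
    read_category_map,
    read_gene_models,
)
from .differential import (
    DEFAULT_CLASS_EDGES,
    fold_change_histogram,
    fold_change_table,
    regulation_class_counts,
    select_regulated,
    write_fold_change_table,
)
from .enrichment import enrich_categories, write_enrichment_report, write_expression_scatter
from .quantification import (
    CountTable,
    bin_expression_levels,
    expression_profile,
    log2_histogram,
    weighted_gene_counts,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage's name when any stage aborts."""


@dataclass(frozen=True)
class AnalysisConfig:
    expressed_rpkm_threshold: float = 1.0
    de_fold_threshold: float = 2.0
    class_edges: tuple[float, float, float] = DEFAULT_CLASS_EDGES
    pseudocount_mode: str = "median_nonzero_rpkm"
    universe_mode: str = "all_annotated"  # or "expressed"
    binomial_parameterisation: str = "pathway_n"  # or "regulated_n"
    adjustment: str = "none"  # or "bh"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expressed_rpkm_threshold <= 0 or self.de_fold_threshold < 1:
            raise ValueError("thresholds must be positive (fold threshold >= 1)")
        e1, e2, e3 = self.class_edges
        if not (0 < e1 < e2 < e3):
            raise ValueError("class_edges must be strictly increasing")
        if self.universe_mode not in ("all_annotated", "expressed"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")
        if self.pseudocount_mode != "median_nonzero_rpkm":
            raise ValueError(f"unknown pseudocount_mode {self.pseudocount_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "class_edges" in raw:
            raw["class_edges"] = tuple(raw["class_edges"])
        return cls(**raw)

    def digest(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: AnalysisConfig
    out_dir: Path
    files: dict[str, Path]
    profile_25: pd.DataFrame
    profile_30: pd.DataFrame
    fold_changes: pd.DataFrame
    regulated: pd.Series
    enrichment: dict[str, pd.DataFrame]
    universe: Universe


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"{name}: {exc}") from exc
        return wrapper
    return deco


@_stage("annotations")
def _load_genes(annotation: str | Path | Sequence[GeneModel]) -> list[GeneModel]:
    if isinstance(annotation, (str, Path)):
        return read_gene_models(annotation)
    return list(annotation)


@_stage("quantification")
def _load_counts(source: str | Path | CountTable, genes: Sequence[GeneModel]) -> CountTable:
    if isinstance(source, CountTable):
        return source
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no such counts/alignment file: {path}")
    if path.suffix.lower() == ".sam":
        return weighted_gene_counts(path, genes)
    return CountTable.read(path)


@_stage("annotations")
def _load_categories(
    categories: Mapping[str, str | Path | Sequence[CategoryMap]],
    universe: Universe,
) -> dict[str, list[CategoryMap]]:
    loaded: dict[str, list[CategoryMap]] = {}
    for namespace, source in categories.items():
        if isinstance(source, (str, Path)):
            path = Path(source)
            if not path.exists():
                raise FileNotFoundError(f"no such category file: {path}")
            loaded[namespace] = read_category_map(path, namespace, universe=universe)
        else:
            restricted = (c.restrict(universe) for c in source)
            loaded[namespace] = [c for c in restricted if c is not None]
    return loaded


def run_pipeline(
    annotation: str | Path | Sequence[GeneModel],
    counts_25: str | Path | CountTable,
    counts_30: str | Path | CountTable,
    categories: Mapping[str, str | Path | Sequence[CategoryMap]],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> PipelineResult:
    """Run quantification, differential classification, enrichment, and reporting.

    ``counts_25`` / ``counts_30`` may be count-table TSVs, SAM files (counted
    with NH weighting), or in-memory :class:`CountTable` objects;
    ``categories`` maps namespace (GO/KEGG/TF) to a category TSV or loaded
    category maps. Writes the full report bundle under ``out_dir`` and
    returns the in-memory results.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = [f"oryzadiff {__version__} config={config.digest()}"]
    log_lines = [f"oryzadiff {__version__} config={config.digest()}"]

    genes = _load_genes(annotation)
    log_lines.append(f"annotations: {len(genes)} gene models")

    table_25 = _load_counts(counts_25, genes)
    table_30 = _load_counts(counts_30, genes)

    try:
        profile_25 = expression_profile(table_25, genes, config.expressed_rpkm_threshold)
        profile_30 = expression_profile(table_30, genes, config.expressed_rpkm_threshold)
    except Exception as exc:
        raise PipelineError(f"quantification: {exc}") from exc
    log_lines.append(
        "quantification: expressed %d (25C) / %d (30C) of %d genes"
        % (int(profile_25["expressed"].sum()), int(profile_30["expressed"].sum()), len(genes))
    )

    try:
        fc = fold_change_table(profile_25, profile_30, config.class_edges)
        regulated = select_regulated(fc, config.de_fold_threshold)
    except Exception as exc:
        raise PipelineError(f"differential: {exc}") from exc
    class_counts = regulation_class_counts(fc)
    log_lines.append(
        "differential: reg_class counts "
        + ", ".join(f"{k}={v}" for k, v in class_counts.items())
        + f"; regulated at >= {config.de_fold_threshold}-fold: {len(regulated)}"
    )

    if config.universe_mode == "expressed":
        uni_ids = profile_25.index[profile_25["expressed"] | profile_30["expressed"]]
        universe = make_universe(uni_ids)
    else:
        universe = make_universe(genes)
    category_maps = _load_categories(categories, universe)

    enrichment: dict[str, pd.DataFrame] = {}
    regulated_in_universe = [g for g in regulated.index if g in universe]
    for namespace, maps in category_maps.items():
        if not regulated_in_universe:
            logger.warning("no regulated genes; enrichment for %s skipped", namespace)
            log_lines.append(f"enrichment[{namespace}]: skipped (empty regulated set)")
            continue
        if not maps:
            log_lines.append(f"enrichment[{namespace}]: skipped (no categories)")
            continue
        try:
            enrichment[namespace] = enrich_categories(
                universe,
                regulated_in_universe,
                maps,
                parameterisation=config.binomial_parameterisation,
                adjust=config.adjustment,
            )
        except Exception as exc:
            raise PipelineError(f"enrichment[{namespace}]: {exc}") from exc
        log_lines.append(
            f"enrichment[{namespace}]: {len(enrichment[namespace])} categories, "
            f"R={len(regulated_in_universe)}, N={universe.size}"
        )

    files: dict[str, Path] = {}

    def _write_tsv(key: str, frame: pd.DataFrame, name: str, index: bool) -> None:
        path = out_dir / name
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            frame.to_csv(fh, sep="\t", index=index)
        files[key] = path

    _write_tsv("expression_25", profile_25, "expression_25.tsv", index=True)
    _write_tsv("expression_30", profile_30, "expression_30.tsv", index=True)

    files["fold_change"] = out_dir / "fold_change.tsv"
    write_fold_change_table(fc, genes, files["fold_change"], header_lines=header)

    for sample, profile in (("25", profile_25), ("30", profile_30)):
        edges, freq = log2_histogram(profile["rpkm"])
        hist = pd.DataFrame({"log2_rpkm_bin": edges[:-1] if len(edges) else [], "frequency": freq})
        _write_tsv(f"expression_histogram_{sample}", hist, f"expression_histogram_{sample}.tsv", index=False)

    _write_tsv("fold_change_histogram", fold_change_histogram(fc), "fold_change_histogram.tsv", index=False)

    for namespace, results in enrichment.items():
        path = out_dir / f"enrichment_{namespace}.tsv"
        write_enrichment_report(results, path, header_lines=header)
        files[f"enrichment_{namespace}"] = path

    tf_maps = category_maps.get("TF", [])
    if tf_maps:
        files["expression_scatter"] = out_dir / "expression_scatter.tsv"
        write_expression_scatter(
            profile_25, profile_30, tf_maps, files["expression_scatter"], header_lines=header
        )

    files["run_log"] = out_dir / "run_log.txt"
    files["run_log"].write_text("\n".join(log_lines) + "\n")
    config.to_yaml(out_dir / "config.yaml")
    files["config"] = out_dir / "config.yaml"

    return PipelineResult(
        config=config,
        out_dir=out_dir,
        files=files,
        profile_25=profile_25,
        profile_30=profile_30,
        fold_changes=fc,
        regulated=regulated,
        enrichment=enrichment,
        universe=universe,
    )


def summarize(result: PipelineResult, top: int = 12) -> dict:
    """Run summary: expressed counts, regulation-class counts, top enrichment rows.

    ``top`` mirrors the published tables' twelve-row length.
    """
    class_counts = regulation_class_counts(result.fold_changes)
    summary = {
        "n_genes": int(len(result.fold_changes)),
        "universe_size": int(result.universe.size),
        "n_regulated": int(len(result.regulated)),
        "n_up25": int((result.regulated == "up25").sum()),
        "n_dn25": int((result.regulated == "dn25").sum()),
        "expressed_25": int(result.profile_25["expressed"].sum()),
        "expressed_30": int(result.profile_30["expressed"].sum()),
        "level_bins_25": {k: int(v) for k, v in bin_expression_levels(result.profile_25).items()},
        "level_bins_30": {k: int(v) for k, v in bin_expression_levels(result.profile_30).items()},
        "reg_class_counts": {k: int(v) for k, v in class_counts.items()},
        "top_enrichment": {},
    }
    if not len(result.regulated):
        summary["enrichment_note"] = "enrichment skipped: no regulated genes"
    for namespace, results in result.enrichment.items():
        head = results.head(top)
        summary["top_enrichment"][namespace] = [
            {
                "rank": int(r["rank"]),
                "category_id": r["category_id"],
                "label": r["label"],
                "pathway_size": int(r["pathway_size"]),
                "observed": int(r["observed"]),
                "ratio": float(r["ratio"]),
                "p_value": float(r["p_value"]),
            }
            for _, r in head.iterrows()
        ]
    return summary
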