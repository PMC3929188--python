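"""Median-pseudocount fold changes between the two temperature samples.

With a single library per condition there is no replicate variance to
model, so differential expression is a fold-change classification, not a
per-gene test. To stabilise ratios of lowly expressed genes, each sample's
median RPKM over genes with nonzero RPKM is added to both terms:

    fldchg = (RPKM_30 + m_30) / (RPKM_25 + m_25)

Orientation is fixed throughout: fldchg < 1 means higher expression at
25 degC ("up at 25"). Fold changes are computed for every annotated gene,
not only expressed ones; the choice of enrichment universe is separate.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import GeneModel

REG_CLASSES = (
    "up25_ge3",
    "up25_2to3",
    "up25_1p5to2",
    "unchanged",
    "dn25_1p5to2",
    "dn25_2to3",
    "dn25_ge3",
)

DEFAULT_CLASS_EDGES = (1.5, 2.0, 3.0)

TABLE_COLUMNS = (
    "rpkm_25",
    "rpkm_30",
    "m_25",
    "m_30",
    "adj_25",
    "adj_30",
    "fldchg",
    "log2fc",
    "reg_class",
)


def median_pseudocount(rpkm_values: pd.Series | np.ndarray) -> float:
    """Per-sample pseudocount: the median RPKM over genes with RPKM > 0.

    Zeros are excluded because roughly half of all annotated genes are
    silent in any one sample; a median over all genes would be 0 and leave
    silent-gene ratios undefined.
    """
    vals = np.asarray(rpkm_values, dtype=float)
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("cannot compute a pseudocount from an all-zero sample")
    return float(np.median(vals))


def fold_change(
    rpkm_25: float | np.ndarray,
    rpkm_30: float | np.ndarray,
    m_25: float,
    m_30: float,
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Pseudocount-adjusted ratio (RPKM_30 + m_30)/(RPKM_25 + m_25) and its log2."""
    if m_25 <= 0 or m_30 <= 0:
        raise ValueError("pseudocounts must be positive")
    a25 = np.asarray(rpkm_25, dtype=float)
    a30 = np.asarray(rpkm_30, dtype=float)
    if np.any(a25 < 0) or np.any(a30 < 0):
        raise ValueError("negative RPKM")
    fldchg = (a30 + m_30) / (a25 + m_25)
    out = (fldchg, np.log2(fldchg))
    if np.isscalar(rpkm_25) and np.isscalar(rpkm_30):
        return float(out[0]), float(out[1])
    return out


def classify_regulation(
    fldchg: float | np.ndarray,
    edges: Sequence[float] = DEFAULT_CLASS_EDGES,
) -> str | pd.Categorical:
    """Assign the seven-way regulation class from the adjusted fold change.

    With r = max(fldchg, 1/fldchg): r >= e3 is the ge3 bin, e2 <= r < e3 the
    2to3 bin, e1 <= r < e2 the 1p5to2 bin, and r < e1 unchanged. Direction is
    up-at-25 iff fldchg < 1 (the ratio is 30 degC over 25 degC).
    """
    e1, e2, e3 = edges
    if not (0 < e1 < e2 < e3):
        raise ValueError("class edges must be strictly increasing and positive")
    f = np.asarray(fldchg, dtype=float)
    if np.any(f <= 0):
        raise ValueError("fold change must be positive")
    r = np.maximum(f, 1.0 / f)
    up = f < 1.0
    conditions = [
        up & (r >= e3),
        up & (r >= e2),
        up & (r >= e1),
        r < e1,
        ~up & (r >= e1) & (r < e2),
        ~up & (r >= e2) & (r < e3),
        ~up & (r >= e3),
    ]
    out = np.select(conditions, REG_CLASSES, default="unchanged")
    if np.isscalar(fldchg):
        return str(out)
    return pd.Categorical(out, categories=REG_CLASSES)


def fold_change_table(
    profile_25: pd.DataFrame,
    profile_30: pd.DataFrame,
    edges: Sequence[float] = DEFAULT_CLASS_EDGES,
) -> pd.DataFrame:
    """Build the per-gene fold-change table from two expression profiles.

    Both profiles must cover the same genes (the output of
    :func:`oryzadiff.quantification.expression_profile` on a shared
    annotation). Pseudocounts are computed per sample from the profiles.
    """
    if not profile_25.index.equals(profile_30.index):
        raise ValueError("the two profiles must be indexed by the same genes, in order")
    m25 = median_pseudocount(profile_25["rpkm"])
    m30 = median_pseudocount(profile_30["rpkm"])
    fldchg, log2fc = fold_change(profile_25["rpkm"].values, profile_30["rpkm"].values, m25, m30)
    df = pd.DataFrame(
        {
            "rpkm_25": profile_25["rpkm"],
            "rpkm_30": profile_30["rpkm"],
            "m_25": m25,
            "m_30": m30,
            "adj_25": profile_25["rpkm"] + m25,
            "adj_30": profile_30["rpkm"] + m30,
            "fldchg": fldchg,
            "log2fc": log2fc,
        },
        index=profile_25.index,
    )
    df["reg_class"] = classify_regulation(df["fldchg"].values, edges)
    df.index.name = "gene_id"
    return df


def select_regulated(table: pd.DataFrame, fold: float = 2.0) -> pd.Series:
    """Genes changed by *fold* or more in either direction, with direction labels.

    Returns a Series indexed by gene_id with values ``up25`` / ``dn25``;
    this set is the enrichment foreground.
    """
    if fold < 1:
        raise ValueError("fold threshold must be >= 1")
    f = table["fldchg"]
    r = np.maximum(f, 1.0 / f)
    sel = table.index[r >= fold]
    direction = np.where(f.loc[sel] < 1.0, "up25", "dn25")
    return pd.Series(direction, index=sel, name="direction")


def regulation_class_counts(table: pd.DataFrame) -> pd.Series:
    """Counts per regulation class; sums to the table size."""
    return table["reg_class"].value_counts().reindex(list(REG_CLASSES), fill_value=0)


def fold_change_histogram(
    table: pd.DataFrame,
    bin_width: float = 0.25,
) -> pd.DataFrame:
    """log2 fold-change histogram (bin left edge, frequency) for export."""
    vals = table["log2fc"].values
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width
    edges = lo + bin_width * np.arange(round((hi - lo) / bin_width) + 1)
    freq, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame({"log2_fldchg_bin": edges[:-1], "frequency": freq})


def write_fold_change_table(
    table: pd.DataFrame,
    genes: Sequence[GeneModel],
    path: str,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the per-gene report TSV: annotation columns, RPKM, adjusted RPKM, ratio, class."""
    by_id = {g.gene_id: g for g in genes}
    out = pd.DataFrame(
        {
            "Gene": table.index,
            "Exon-length": [by_id[g].exon_length for g in table.index],
            "Location": [by_id[g].location for g in table.index],
            "Description": [by_id[g].description for g in table.index],
            "RPKM(25)": table["rpkm_25"].values,
            "RPKM(30)": table["rpkm_30"].values,
            "RPKM+median(25)": table["adj_25"].values,
            "RPKM+median(30)": table["adj_30"].values,
            "fldchg": table["fldchg"].values,
            "reg_class": table["reg_class"].values,
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)
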