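"""Binomial over-representation scoring of gene categories.

For a universe of N genes of which R are regulated, a category with n
members in the universe and k members among the regulated genes is scored
with the one-sided upper binomial tail

    P(X >= k),   X ~ Binomial(n, R/N)

computed by exact summation in log space (no normal approximation). An
alternative parameterisation, X ~ Binomial(R, n/N), is available as a
config switch. Only over-representation is ranked by default; depletion
scoring (lower tail) exists but is off.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .annotations import CategoryMap, Universe

logger = logging.getLogger(__name__)

PARAMETERISATIONS = ("pathway_n", "regulated_n")

REPORT_COLUMNS = ("Rank", "Pathway", "Pathway annotation", "Pathway size", "Observed", "Ratio", "P value")

#: Decimal places used for the printed Ratio column, per namespace.
RATIO_DECIMALS = {"GO": 2, "KEGG": 2, "TF": 3}


def binomial_tail(k: int, n: int, p: float, lower: bool = False) -> float:
    """Exact one-sided binomial tail P(X >= k) (or P(X <= k) when lower).

    Summation is carried out in log space over the exact log-pmf terms, so
    the result stays accurate deep into the tail (p-values of order 1e-50
    and below are routine for strongly enriched categories).
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not lower and k == 0:
        return 1.0
    if lower and k == n:
        return 1.0
    j = np.arange(0, k + 1) if lower else np.arange(k, n + 1)
    log_pmf = (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + j * np.log(p)
        + (n - j) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def enrich_categories(
    universe: Universe,
    regulated: Iterable[str],
    categories: Sequence[CategoryMap],
    parameterisation: str = "pathway_n",
    adjust: str = "none",
) -> pd.DataFrame:
    """Score every category for over-representation among regulated genes.

    Returns a ranked DataFrame with one row per category: pathway size n
    (members in the universe), observed k (members among regulated genes),
    ratio k/n, the one-sided binomial tail p-value, and the rank. Categories
    with no members in the universe are skipped with a warning.
    """
    if parameterisation not in PARAMETERISATIONS:
        raise ValueError(f"unknown parameterisation {parameterisation!r}")
    regulated = set(regulated)
    outside = regulated - universe.gene_ids
    if outside:
        logger.warning("%d regulated genes outside the universe are ignored", len(outside))
        regulated &= universe.gene_ids
    R = len(regulated)
    N = universe.size
    if R == 0:
        raise ValueError("the regulated set is empty within the universe")
    rows = []
    for cat in categories:
        members = cat.members & universe.gene_ids
        n = len(members)
        if n == 0:
            logger.warning("category %s has no members in the universe; skipped", cat.category_id)
            continue
        k = len(members & regulated)
        if parameterisation == "pathway_n":
            p_value = binomial_tail(k, n, R / N)
        else:
            p_value = binomial_tail(k, R, n / N)
        rows.append(
            {
                "category_id": cat.category_id,
                "label": cat.label,
                "namespace": cat.namespace,
                "pathway_size": n,
                "observed": k,
                "ratio": k / n,
                "p_value": p_value,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["category_id", "label", "namespace", "pathway_size", "observed", "ratio", "p_value", "rank"]
        )
    df = pd.DataFrame(rows)
    if adjust == "bh":
        df["p_adjusted"] = bh_adjust(df["p_value"].values)
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return rank_results(df)


def rank_results(results: pd.DataFrame) -> pd.DataFrame:
    """Order by ascending p-value, ties broken by descending observed k, then id."""
    df = results.sort_values(
        by=["p_value", "observed", "category_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def family_regulation_fraction(
    family: CategoryMap,
    regulated: Iterable[str],
    universe: Universe | None = None,
) -> tuple[int, int, float]:
    """(observed k, family size n, percent regulated to one decimal place)."""
    members = family.members
    if universe is not None:
        members = members & universe.gene_ids
    n = len(members)
    if n == 0:
        raise ValueError(f"{family.category_id}: no members to compute a fraction over")
    k = len(members & set(regulated))
    return k, n, round(100.0 * k / n, 1)


def format_report(results: pd.DataFrame, top: int | None = 12) -> pd.DataFrame:
    """Printed-table view: Rank / Pathway / annotation / size / Observed / Ratio / P value.

    The Ratio column is rounded per namespace (2 decimals for GO and KEGG,
    3 for TF families); full-precision columns ride along for downstream use.
    """
    df = results if top is None else results.head(top)
    decimals = [RATIO_DECIMALS.get(ns, 2) for ns in df["namespace"]]
    return pd.DataFrame(
        {
            "Rank": df["rank"].values,
            "Pathway": df["label"].values,
            "Pathway annotation": df["category_id"].values,
            "Pathway size": df["pathway_size"].values,
            "Observed": df["observed"].values,
            "Ratio": [round(r, d) for r, d in zip(df["ratio"].values, decimals)],
            "P value": [float(f"{p:.3g}") for p in df["p_value"].values],
            "ratio_full": df["ratio"].values,
            "p_value_full": df["p_value"].values,
        }
    )


def write_enrichment_report(
    results: pd.DataFrame,
    path: str,
    top: int | None = None,
    header_lines: Sequence[str] = (),
) -> None:
    report = format_report(results, top=top)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        report.to_csv(fh, sep="\t", index=False)


def write_expression_scatter(
    profile_25: pd.DataFrame,
    profile_30: pd.DataFrame,
    families: Sequence[CategoryMap],
    path: str,
    header_lines: Sequence[str] = (),
) -> None:
    """Per-gene (log2 RPKM at 25 degC, log2 RPKM at 30 degC, family label) TSV.

    Only genes with nonzero RPKM in both samples are exported (log2 of zero
    is undefined); genes in no family get an empty label.
    """
    label_by_gene: dict[str, str] = {}
    for fam in families:
        for g in fam.members:
            label_by_gene.setdefault(g, fam.label)
    mask = (profile_25["rpkm"] > 0) & (profile_30["rpkm"] > 0)
    idx = profile_25.index[mask]
    df = pd.DataFrame(
        {
            "gene_id": idx,
            "log2_rpkm_25": np.log2(profile_25.loc[idx, "rpkm"].values),
            "log2_rpkm_30": np.log2(profile_30.loc[idx, "rpkm"].values),
            "family": [label_by_gene.get(g, "") for g in idx],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
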