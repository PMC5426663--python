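"""Additive vs non-additive classification of F1 gene expression.

Given an FPKM-like gene × sample matrix for two parents and their F1
hybrid, each gene is compared with each parent at each location with a
two-fold change gate (|log2 fold change| >= 1, inclusive) plus a
replicate-level Welch test on log2(value + pseudocount). Per-gene calls
vs the two parents are combined into the hybrid-expression categories:
above/below both parents ("non-additive"), above/below a single parent,
crossover (up vs one parent, down vs the other) or not differentially
expressed. Cross-location concordance is summarized as the shared DE set,
its direction-agreement fraction and the R² of log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DifferentialCall",
    "GeneCategory",
    "detect_expressed",
    "differential_call",
    "differential_calls_table",
    "classify_gene_category",
    "classify_table",
    "category_counts",
    "cross_location_concordance",
    "CATEGORIES",
]

CATEGORIES = (
    "above_both",
    "below_both",
    "above_P1_only",
    "below_P1_only",
    "above_P2_only",
    "below_P2_only",
    "crossover",
    "not_de",
)


@dataclass
class DifferentialCall:
    gene: str
    comparison: str  # "F1_vs_P1" or "F1_vs_P2"
    location: str
    log2_fold_change: float
    p_value: float
    significant: bool
    direction: str  # "up", "down" or "none"


@dataclass
class GeneCategory:
    gene: str
    location: str
    category: str
    crossover: bool = False


def detect_expressed(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    min_level: float = 1.0,
    location: str | None = None,
) -> set[str]:
    """Genes whose mean expression across a location's samples exceeds
    ``min_level`` (strict). This set is the enrichment background — all
    genes expressed in the tissue at that location."""
    samples = meta["sample"] if location is None else meta.loc[meta["location"] == location, "sample"]
    mean = values[list(samples)].mean(axis=1)
    return set(mean.index[mean > min_level])


def _welch_log(a: np.ndarray, b: np.ndarray, pseudocount: float) -> np.ndarray:
    """Vectorized Welch p-values on log2(x + pseudocount); rows are genes.

    Degenerate rows (zero variance in both groups) get p = 1 when the
    group means agree and p = 0 when they differ: noise-free data should
    be decided by the fold-change gate alone.
    """
    import warnings

    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    zerovar = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    p = np.where(zerovar & equal, 1.0, p)
    p = np.where(zerovar & ~equal, 0.0, p)
    return np.nan_to_num(p, nan=1.0)


def differential_calls_table(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    comparison: str,
    location: str,
    alpha: float = 0.05,
    min_log2_fold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """All genes' F1-vs-parent calls at one location.

    ``comparison`` is ``"F1_vs_P1"`` or ``"F1_vs_P2"`` (any parent
    genotype label after the ``F1_vs_`` prefix). Significance requires
    |log2FC| >= ``min_log2_fold`` (two-fold rule, inclusive) and Welch
    p < ``alpha`` on log2(value + pseudocount) across replicates.
    """
    if not comparison.startswith("F1_vs_"):
        raise ValueError(f"comparison must be 'F1_vs_<parent>', got {comparison!r}")
    parent = comparison[len("F1_vs_") :]
    loc = meta["location"] == location
    f1_samples = meta.loc[loc & (meta["genotype"] == "F1"), "sample"]
    par_samples = meta.loc[loc & (meta["genotype"] == parent), "sample"]
    if len(f1_samples) < 2 or len(par_samples) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = values[list(f1_samples)].to_numpy(dtype=float)
    b = values[list(par_samples)].to_numpy(dtype=float)
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    log2fc = np.log2(m1 + pseudocount) - np.log2(m2 + pseudocount)
    p = _welch_log(a, b, pseudocount)
    significant = (np.abs(log2fc) >= min_log2_fold) & (p < alpha)
    direction = np.where(~significant, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "gene": values.index,
            "comparison": comparison,
            "location": location,
            "log2_fold_change": log2fc,
            "p_value": p,
            "significant": significant,
            "direction": direction,
        }
    ).set_index("gene")


def differential_call(
    values: pd.DataFrame,
    gene: str,
    comparison: str,
    location: str,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    min_log2_fold: float = 1.0,
    pseudocount: float = 1.0,
) -> DifferentialCall:
    """Single-gene convenience wrapper over :func:`differential_calls_table`."""
    row = differential_calls_table(
        values.loc[[gene]], meta, comparison, location, alpha, min_log2_fold, pseudocount
    ).loc[gene]
    return DifferentialCall(
        gene=gene,
        comparison=comparison,
        location=location,
        log2_fold_change=float(row["log2_fold_change"]),
        p_value=float(row["p_value"]),
        significant=bool(row["significant"]),
        direction=str(row["direction"]),
    )


def classify_gene_category(dir_p1: str, dir_p2: str) -> tuple[str, bool]:
    """Map a gene's (direction vs P1, direction vs P2) pair to a category.

    Returns ``(category, crossover)``. Up vs both -> ``above_both``; down
    vs both -> ``below_both`` (the non-additive categories). Opposite
    significant directions are a crossover: flagged, counted in neither
    non-additive category.
    """
    pair = (dir_p1, dir_p2)
    if pair == ("up", "up"):
        return "above_both", False
    if pair == ("down", "down"):
        return "below_both", False
    if pair == ("up", "down") or pair == ("down", "up"):
        return "crossover", True
    if dir_p1 == "up":
        return "above_P1_only", False
    if dir_p1 == "down":
        return "below_P1_only", False
    if dir_p2 == "up":
        return "above_P2_only", False
    if dir_p2 == "down":
        return "below_P2_only", False
    return "not_de", False


def classify_table(calls_p1: pd.DataFrame, calls_p2: pd.DataFrame) -> pd.DataFrame:
    """Per-gene categories from the two parent-comparison call tables."""
    if not calls_p1.index.equals(calls_p2.index):
        calls_p2 = calls_p2.reindex(calls_p1.index)
    cats = []
    cross = []
    for d1, d2 in zip(calls_p1["direction"], calls_p2["direction"]):
        c, x = classify_gene_category(d1, d2)
        cats.append(c)
        cross.append(x)
    return pd.DataFrame(
        {
            "location": calls_p1["location"],
            "category": cats,
            "crossover": cross,
        },
        index=calls_p1.index,
    )


def category_counts(calls_p1: pd.DataFrame, calls_p2: pd.DataFrame) -> pd.Series:
    """Hybrid-expression count table for one location.

    Columns follow the classic layout: genes up/down vs each single
    parent (marginal counts) and up/down vs both parents (the
    non-additive categories, necessarily subsets of the marginals).
    """
    up1 = calls_p1["direction"] == "up"
    dn1 = calls_p1["direction"] == "down"
    up2 = calls_p2["direction"].reindex(calls_p1.index) == "up"
    dn2 = calls_p2["direction"].reindex(calls_p1.index) == "down"
    return pd.Series(
        {
            "total_genes": len(calls_p1),
            "F1_gt_P1": int(up1.sum()),
            "F1_lt_P1": int(dn1.sum()),
            "F1_gt_P2": int(up2.sum()),
            "F1_lt_P2": int(dn2.sum()),
            "F1_gt_both": int((up1 & up2).sum()),
            "F1_lt_both": int((dn1 & dn2).sum()),
        }
    )


def cross_location_concordance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[set[str], float, float]:
    """Concordance of one comparison's DE calls between two locations.

    Returns ``(shared significant genes, direction-agreement fraction,
    R² of log2FC over the shared set)``. R² is NaN when fewer than three
    genes are shared.
    """
    comp_a = set(calls_a["comparison"].unique())
    comp_b = set(calls_b["comparison"].unique())
    if comp_a != comp_b:
        raise ValueError(f"comparisons differ between locations: {comp_a} vs {comp_b}")
    shared = set(calls_a.index[calls_a["significant"]]) & set(
        calls_b.index[calls_b["significant"]]
    )
    if not shared:
        return shared, float("nan"), float("nan")
    idx = sorted(shared)
    da = calls_a.loc[idx, "direction"]
    db = calls_b.loc[idx, "direction"]
    agreement = float((da.to_numpy() == db.to_numpy()).mean())
    if len(idx) < 3:
        return shared, agreement, float("nan")
    fa = calls_a.loc[idx, "log2_fold_change"].to_numpy()
    fb = calls_b.loc[idx, "log2_fold_change"].to_numpy()
    r = np.corrcoef(fa, fb)[0, 1]
    return shared, agreement, float(r**2)
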