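"""Singular enrichment analysis (SEA) of GO terms.

One-sided upper-tail hypergeometric over-representation of a study gene
set against a background of all genes expressed in the tissue, with
Benjamini–Hochberg FDR across the tested terms. Annotation is taken as
flat gene -> term sets; GO-graph ancestor propagation is available as an
opt-in utility but is off by default.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Set

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_annotation",
    "read_gaf_subset",
    "propagate_annotations",
    "sea",
    "enrichment_report",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["term", "description", "k", "n", "K", "N", "p_value", "fdr"]


def read_annotation(path) -> pd.DataFrame:
    """Two-column gene<TAB>term table -> tidy annotation frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation file needs two columns: gene, term")
    df = df.iloc[:, :2]
    df.columns = ["gene", "term"]
    return df.drop_duplicates(ignore_index=True)


def read_gaf_subset(path) -> pd.DataFrame:
    """Minimal GAF reader: object id (col 2) and GO id (col 5)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="!", dtype=str)
    out = df.iloc[:, [1, 4]]
    out.columns = ["gene", "term"]
    return out.drop_duplicates(ignore_index=True)


def propagate_annotations(
    annotation: pd.DataFrame, parents: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Optional ancestor closure: add every ancestor of each annotated term.

    ``parents`` maps term -> direct parent terms (e.g. built from an OBO
    graph). Off by default in the pipeline.
    """
    rows = []
    for gene, term in zip(annotation["gene"], annotation["term"]):
        seen = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for p in parents.get(t, ()):  # cycle-safe
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        rows.extend({"gene": gene, "term": t} for t in seen)
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


def sea(
    study: Set[str],
    background: Set[str],
    annotation: pd.DataFrame,
    min_term_size: int = 5,
    descriptions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the study set.

    For a term annotating K of the N background genes and k of the n
    study genes, p = P(X >= k) with X ~ Hypergeometric(N, K, n). Terms
    with K < ``min_term_size`` are skipped; BH-FDR is computed across the
    tested terms and results are sorted by p. Study genes outside the
    background are dropped (logged).
    """
    background = set(background)
    study = set(study)
    outside = study - background
    if outside:
        logger.info("dropping %d study genes outside the background", len(outside))
        study = study & background
    n = len(study)
    N = len(background)
    if n == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    ann = annotation[annotation["gene"].isin(background)]
    per_term = ann.groupby("term")["gene"]
    rows = []
    for term, genes in per_term:
        gset = set(genes)
        K = len(gset)
        if K < min_term_size:
            continue
        k = len(gset & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p_value": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    res = pd.DataFrame(rows)
    res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    res["description"] = res["term"].map(descriptions or {}).fillna("")
    res = res.sort_values(["p_value", "term"], kind="mergesort", ignore_index=True)
    return res[RESULT_COLUMNS]


def enrichment_report(
    results: pd.DataFrame, alpha: float = 0.05, direction_label: str = ""
) -> pd.DataFrame:
    """Filtered listing of enriched terms (FDR <= alpha).

    When nothing passes, a single ``NONE`` row is emitted so the report
    keeps one row per direction label.
    """
    passing = results[results["fdr"] <= alpha] if len(results) else results
    if len(passing) == 0:
        return pd.DataFrame(
            [{"direction": direction_label, "term": "NONE", "description": "", "p_value": None}]
        )
    out = passing[["term", "description", "p_value", "fdr", "k", "K"]].copy()
    out.insert(0, "direction", direction_label)
    return out.reset_index(drop=True)
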