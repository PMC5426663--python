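"""Allele-specific expression bias from parent-specific SNPs.

The caller works on biallelic sites with per-sample ref/alt read depths
for replicated parental and F1 hybrid samples at one or more locations:

1. mask sites within 2 bp of splice-junction boundaries (misalignment
   risk);
2. keep sites where exactly one parent is effectively homozygous for the
   alternative allele and the other for the reference, in every parental
   replicate at every location, at sufficient depth — these
   parent-specific SNPs let F1 reads be assigned to a parental allele;
3. compute per-replicate and read-pooled origin-allele fractions in the
   F1 at each location;
4. call an allele bias when the majority allele holds strictly more than
   73% of the pooled reads and every replicate falls on the same side of
   0.5 (the fixed threshold matches two standard deviations of the
   fraction distribution; an empirical 0.5 + 2·SD threshold is opt-in);
5. downstream summaries: cross-location fraction concordance and
   switched-bias count, per-gene bias consistency, the
   methylation-associated substitution-class (C→T/G→A) Fisher test and a
   binned fraction histogram split by the alt allele's parent of origin.

Coordinates are 1-based throughout (VCF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiasCall",
    "GeneBiasSummary",
    "junction_boundaries",
    "mask_splice_proximal",
    "call_parent_specific_snps",
    "f1_allele_fractions",
    "classify_bias",
    "bias_call_table",
    "empirical_threshold",
    "cross_location_bias_concordance",
    "summarize_gene_bias",
    "substitution_class_test",
    "bias_histogram",
    "DEFAULT_BIAS_THRESHOLD",
    "METHYLATION_PAIRS",
]

DEFAULT_BIAS_THRESHOLD = 0.73
#: Substitution pairs elevated by deamination of methylcytosine.
METHYLATION_PAIRS = {("C", "T"), ("G", "A")}

SITE_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class BiasCall:
    """Per-SNP, per-location allele-fraction summary.

    Fractions are of the origin parent's allele (the alt allele of the
    parent-specific SNP's origin parent).
    """

    chrom: str
    pos: int
    origin: str
    location: str
    per_replicate_fractions: list[float]
    pooled_fraction: float
    total_depth: int
    evaluable: bool
    biased: bool = False
    favored_allele: str | None = None


@dataclass
class GeneBiasSummary:
    gene: str
    n_snps: int
    n_biased: int
    directions: set[str] = field(default_factory=set)

    @property
    def consistent(self) -> bool:
        return len(self.directions) <= 1


# ---------------------------------------------------------------------------
# Splice masking
# ---------------------------------------------------------------------------

def junction_boundaries(introns: pd.DataFrame) -> pd.DataFrame:
    """1-based exonic boundary positions from 0-based half-open introns.

    For an intron ``[start, end)`` (BED convention) the last exonic base
    on the left is 1-based ``start`` and the first exonic base on the
    right is ``end + 1``; both are listed.
    """
    left = introns[["chrom"]].assign(boundary=introns["start"].astype(np.int64))
    right = introns[["chrom"]].assign(boundary=introns["end"].astype(np.int64) + 1)
    return (
        pd.concat([left, right], ignore_index=True)
        .drop_duplicates()
        .sort_values(["chrom", "boundary"], ignore_index=True)
    )


def mask_splice_proximal(
    sites: pd.DataFrame, junctions: pd.DataFrame, margin: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split sites into (kept, masked) by junction-boundary proximity.

    A site is masked iff it lies within ``margin`` bp (inclusive) of any
    junction boundary on its chromosome. ``junctions`` either has columns
    ``chrom, boundary`` (1-based boundary positions) or ``chrom, start,
    end`` (0-based half-open introns, converted via
    :func:`junction_boundaries`). Chromosomes present in ``sites`` but
    absent from ``junctions`` are kept whole with a warning.
    """
    if junctions.empty:
        return sites, sites.iloc[0:0]
    if "boundary" not in junctions.columns:
        junctions = junction_boundaries(junctions)
    masked = np.zeros(len(sites), dtype=bool)
    site_chroms = set(sites["chrom"].unique())
    junc_chroms = set(junctions["chrom"].unique())
    unmatched = site_chroms - junc_chroms
    if unmatched and junc_chroms:
        warnings.warn(
            f"no junctions for chromosome(s) {sorted(unmatched)}; sites there are not masked",
            stacklevel=2,
        )
    for chrom, grp in junctions.groupby("chrom"):
        b = np.sort(grp["boundary"].to_numpy(dtype=np.int64))
        on = (sites["chrom"] == chrom).to_numpy()
        if not on.any():
            continue
        pos = sites.loc[on, "pos"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(b, pos)
        dist = np.full(len(pos), np.iinfo(np.int64).max)
        left = idx > 0
        dist[left] = np.abs(pos[left] - b[idx[left] - 1])
        right = idx < len(b)
        dist[right] = np.minimum(dist[right], np.abs(b[idx[right]] - pos[right]))
        masked[on] = dist <= margin
    return sites.loc[~masked], sites.loc[masked]


# ---------------------------------------------------------------------------
# Parent-specific SNP calling
# ---------------------------------------------------------------------------

def _genotype_call(ref_count: int, alt_count: int, max_minor_fraction: float) -> str:
    """'ref', 'alt' or 'het' by minor-allele read fraction."""
    depth = ref_count + alt_count
    if depth == 0:
        return "het"
    if alt_count / depth <= max_minor_fraction:
        return "ref"
    if ref_count / depth <= max_minor_fraction:
        return "alt"
    return "het"


def call_parent_specific_snps(
    ad: pd.DataFrame,
    samples: pd.DataFrame,
    parents: Sequence[str] = ("P1", "P2"),
    min_depth: int = 8,
    max_minor_fraction: float = 0.05,
) -> pd.DataFrame:
    """Identify SNPs fixed for opposite alleles in the two parents.

    A site passes iff, at every location and in every parental replicate:
    depth >= ``min_depth``; exactly one parent is effectively homozygous
    for the alt allele (minor-allele read fraction <=
    ``max_minor_fraction``) in all of its replicates; and the other
    parent is effectively homozygous ref in all of its replicates.

    ``ad`` is the long allele-depth table (``chrom, pos, ref, alt,
    sample, ref_count, alt_count``); ``samples`` maps sample ->
    (genotype, location, replicate). Returns one row per passing site
    with its ``origin`` (the alt-carrying parent).
    """
    p1, p2 = parents
    meta = samples.set_index("sample")
    par = ad[ad["sample"].map(meta["genotype"]).isin(parents)].copy()
    par["genotype"] = par["sample"].map(meta["genotype"])
    depth = par["ref_count"] + par["alt_count"]
    par["depth_ok"] = depth >= min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(depth > 0, par["alt_count"] / depth, np.nan)
    par["is_ref"] = par["depth_ok"] & (alt_frac <= max_minor_fraction)
    par["is_alt"] = par["depth_ok"] & ((1 - alt_frac) <= max_minor_fraction)

    grp = par.groupby(SITE_KEY, sort=False)
    agg = grp.agg(
        depth_ok=("depth_ok", "all"),
        n=("sample", "size"),
    )
    for parent in parents:
        sub = par[par["genotype"] == parent].groupby(SITE_KEY, sort=False)
        agg[f"{parent}_all_ref"] = sub["is_ref"].all()
        agg[f"{parent}_all_alt"] = sub["is_alt"].all()
    agg = agg.fillna(False)

    origin_p1 = agg[f"{p1}_all_alt"] & agg[f"{p2}_all_ref"]
    origin_p2 = agg[f"{p2}_all_alt"] & agg[f"{p1}_all_ref"]
    keep = agg["depth_ok"] & (origin_p1 ^ origin_p2)
    out = agg.loc[keep].reset_index()[SITE_KEY]
    out["origin"] = np.where(origin_p1.loc[keep.index[keep]].to_numpy(), p1, p2)
    out["fixed_in_all_parent_reps"] = True
    out["unique_to_one_parent"] = True
    return out


# ---------------------------------------------------------------------------
# F1 fractions and bias classification
# ---------------------------------------------------------------------------

def f1_allele_fractions(
    snp: Mapping,
    f1_ad: pd.DataFrame,
    location: str,
    min_depth: int = 8,
) -> BiasCall:
    """Origin-allele fractions for one SNP in the F1 reps of a location.

    ``snp`` needs ``chrom, pos, ref, alt, origin``; ``f1_ad`` holds that
    site's rows for the location's F1 samples. Replicates below
    ``min_depth`` are excluded; the pooled fraction uses summed counts
    over passing replicates ("fraction of the reads", not a mean of
    fractions). With no passing replicate the call is flagged
    unevaluable.
    """
    depth = (f1_ad["ref_count"] + f1_ad["alt_count"]).to_numpy()
    ok = depth >= min_depth
    # origin parent carries the alt allele of the parent-specific SNP
    origin_counts = f1_ad["alt_count"].to_numpy()
    fracs = [float(o / d) for o, d in zip(origin_counts[ok], depth[ok])]
    pooled_origin = int(origin_counts[ok].sum())
    pooled_depth = int(depth[ok].sum())
    evaluable = pooled_depth > 0
    return BiasCall(
        chrom=str(snp["chrom"]),
        pos=int(snp["pos"]),
        origin=str(snp["origin"]),
        location=location,
        per_replicate_fractions=fracs,
        pooled_fraction=pooled_origin / pooled_depth if evaluable else float("nan"),
        total_depth=pooled_depth,
        evaluable=evaluable,
    )


def classify_bias(
    call: BiasCall,
    threshold: float = DEFAULT_BIAS_THRESHOLD,
    parents: Sequence[str] = ("P1", "P2"),
) -> BiasCall:
    """Set the ``biased`` flag on a call (strict > threshold rule).

    Biased iff the majority allele's pooled fraction strictly exceeds
    ``threshold`` AND every depth-passing replicate's fraction lies on
    the same side of 0.5 as the pooled fraction ("consistently across a
    location"). The favored allele is the majority allele's parent of
    origin.
    """
    if not call.evaluable:
        call.biased = False
        call.favored_allele = None
        return call
    f = call.pooled_fraction
    majority = max(f, 1 - f)
    if f == 0.5:
        call.biased = False
        call.favored_allele = None
        return call
    other = parents[0] if call.origin == parents[1] else parents[1]
    favored = call.origin if f > 0.5 else other
    side = np.sign(f - 0.5)
    consistent = all(np.sign(r - 0.5) == side for r in call.per_replicate_fractions)
    call.biased = bool(majority > threshold and consistent)
    call.favored_allele = favored if call.biased else None
    return call


def bias_call_table(
    ad: pd.DataFrame,
    samples: pd.DataFrame,
    snps: pd.DataFrame,
    min_depth: int = 8,
    threshold: float = DEFAULT_BIAS_THRESHOLD,
    parents: Sequence[str] = ("P1", "P2"),
) -> pd.DataFrame:
    """Fractions + bias classification for every (SNP, location) pair.

    ``snps`` is the parent-specific table from
    :func:`call_parent_specific_snps`. Returns a tidy frame with one row
    per SNP per location.
    """
    meta = samples.set_index("sample")
    f1 = ad[ad["sample"].map(meta["genotype"]) == "F1"].copy()
    f1["location"] = f1["sample"].map(meta["location"])
    f1 = f1.merge(snps[SITE_KEY + ["origin"]], on=SITE_KEY, how="inner")
    rows = []
    for (chrom, pos, ref, alt, origin, location), grp in f1.groupby(
        SITE_KEY + ["origin", "location"], sort=False
    ):
        snp = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "origin": origin}
        call = f1_allele_fractions(snp, grp, str(location), min_depth)
        call = classify_bias(call, threshold, parents)
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "origin": origin,
                "location": location,
                "n_reps": len(call.per_replicate_fractions),
                "pooled_fraction": call.pooled_fraction,
                "total_depth": call.total_depth,
                "evaluable": call.evaluable,
                "biased": call.biased,
                "favored_allele": call.favored_allele,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "origin",
            "location",
            "n_reps",
            "pooled_fraction",
            "total_depth",
            "evaluable",
            "biased",
            "favored_allele",
        ],
    )


def empirical_threshold(
    fractions: Sequence[float],
    fallback: float = DEFAULT_BIAS_THRESHOLD,
    min_fractions: int = 30,
) -> float:
    """Data-driven bias threshold: 0.5 + 2·SD of the pooled fractions.

    The SD is of the fractions about their own mean (sample SD). With
    fewer than ``min_fractions`` values the fixed ``fallback`` threshold
    is returned with a warning. The result is floored at 0.5.
    """
    arr = np.asarray(list(fractions), dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < min_fractions:
        warnings.warn(
            f"only {len(arr)} fractions (< {min_fractions}); using fixed threshold {fallback}",
            stacklevel=2,
        )
        return fallback
    sd = float(arr.std(ddof=1))
    return max(0.5, 0.5 + 2.0 * sd)


# ---------------------------------------------------------------------------
# Downstream summaries
# ---------------------------------------------------------------------------

def cross_location_bias_concordance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[float, float, int]:
    """Between-location concordance of pooled allele fractions.

    Returns ``(r² over all matched SNPs, r² over SNPs biased at either
    location, count of SNPs biased at both locations with opposite
    favored alleles)``. SNPs are matched by (chrom, pos); r² is NaN below
    three matched SNPs.
    """
    m = calls_a.merge(calls_b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    m = m[m["evaluable_a"] & m["evaluable_b"]]

    def _r2(sub: pd.DataFrame) -> float:
        if len(sub) < 3:
            return float("nan")
        r = np.corrcoef(sub["pooled_fraction_a"], sub["pooled_fraction_b"])[0, 1]
        return float(r**2)

    r2_all = _r2(m)
    either = m[m["biased_a"] | m["biased_b"]]
    r2_biased = _r2(either)
    both = m[m["biased_a"] & m["biased_b"]]
    switched = int((both["favored_allele_a"] != both["favored_allele_b"]).sum())
    return r2_all, r2_biased, switched


UNMAPPED_GENE = "__unmapped__"


def summarize_gene_bias(
    calls: pd.DataFrame, snp_to_gene: Mapping[tuple[str, int], str]
) -> list[GeneBiasSummary]:
    """Aggregate SNP bias calls to genes with a consistency flag.

    ``snp_to_gene`` maps (chrom, pos) -> gene id; unmapped SNPs are
    grouped under a sentinel gene. A gene is consistent when all of its
    biased SNPs favor the same parental allele.
    """
    work = calls.copy()
    work["gene"] = [
        snp_to_gene.get((c, int(p)), UNMAPPED_GENE) for c, p in zip(work["chrom"], work["pos"])
    ]
    out = []
    for gene, grp in work.groupby("gene", sort=True):
        snps = grp.drop_duplicates(subset=["chrom", "pos"])
        biased = grp[grp["biased"]].drop_duplicates(subset=["chrom", "pos", "favored_allele"])
        n_biased = grp[grp["biased"]].drop_duplicates(subset=["chrom", "pos"])
        out.append(
            GeneBiasSummary(
                gene=str(gene),
                n_snps=len(snps),
                n_biased=len(n_biased),
                directions=set(biased["favored_allele"].dropna()),
            )
        )
    return out


def substitution_class_test(
    biased: pd.DataFrame, unbiased: pd.DataFrame
) -> tuple[np.ndarray, float, bool]:
    """Fisher exact test of methylation-associated substitutions vs bias.

    A SNP is methylation-associated iff (ref, alt) ∈ {(C,T), (G,A)} —
    the classes inflated by deamination of 5-methylcytosine. Returns the
    2×2 table ``[[biased & assoc, biased & other], [unbiased & assoc,
    unbiased & other]]``, the two-sided Fisher p, and a degenerate-table
    flag (an empty stratum forces p = 1).
    """

    def _assoc(df: pd.DataFrame) -> int:
        return int(sum((r, a) in METHYLATION_PAIRS for r, a in zip(df["ref"], df["alt"])))

    kb = _assoc(biased)
    ku = _assoc(unbiased)
    table = np.array([[kb, len(biased) - kb], [ku, len(unbiased) - ku]])
    degenerate = (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any()
    if degenerate:
        return table, 1.0, True
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p), False


def bias_histogram(
    calls: pd.DataFrame, n_bins: int = 20, parents: Sequence[str] = ("P1", "P2")
) -> pd.DataFrame:
    """Binned origin-allele fraction distribution, one panel per parent.

    For each alt-allele parent of origin, bins the evaluable pooled
    fractions into ``n_bins`` half-open bins over [0, 1] (last bin
    closed) and reports counts as percent of that panel's SNPs.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for parent in parents:
        sub = calls[(calls["origin"] == parent) & calls["evaluable"]]
        counts, _ = np.histogram(sub["pooled_fraction"].to_numpy(dtype=float), bins=edges)
        total = counts.sum()
        pct = 100.0 * counts / total if total else np.zeros_like(counts, dtype=float)
        for lo, hi, c, p in zip(edges[:-1], edges[1:], counts, pct):
            rows.append(
                {
                    "origin": parent,
                    "bin_low": lo,
                    "bin_high": hi,
                    "count": int(c),
                    "percent": float(p),
                }
            )
    return pd.DataFrame(rows)
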