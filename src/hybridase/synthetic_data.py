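"""Truth-parameterized synthetic data for every pipeline stage.

Three generators emulate the inputs of a two-location soybean
hybrid-vs-parents study:

* :func:`generate_trial` — plot-level agronomic data from a randomized
  complete block design (RCBD) with a planted mid-parent heterosis shift,
  Gaussian block effects, polynomial row/column field trends and residual
  noise.
* :func:`generate_expression` — an FPKM-like gene × sample matrix for
  3 genotypes × replicates × locations with genes planted as additive,
  non-additive (above/below both parents), parent-dominant or null.
* :func:`generate_allele_counts` — per-site ref/alt read depths for
  replicated parental and F1 samples, with parent-specific SNPs, planted
  allele bias in the F1, binomial sampling noise, splice-proximal sites
  and residual heterozygosity contaminating one parent.

Every generator is deterministic given its truth record's ``seed`` and
returns the planted truth alongside the data so downstream stages can be
scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialTruth",
    "ExpressionTruth",
    "AseTruth",
    "generate_trial",
    "generate_expression",
    "generate_allele_counts",
    "generate_annotation",
    "DEFAULT_LOCATIONS",
]

DEFAULT_LOCATIONS: tuple[str, str] = ("Kinston", "Clayton")

#: Entries per block mirroring the study design: one F1, three F2 and six
#: replicates of each parent per block.
DEFAULT_REPS_PER_BLOCK: dict[str, int] = {"P1": 6, "P2": 6, "F1": 1, "F2": 3}

DEFAULT_ENTRY_CLASS: dict[str, str] = {
    "P1": "parent1",
    "P2": "parent2",
    "F1": "F1",
    "F2": "F2",
}


class ConfigurationError(ValueError):
    """A truth record or design parameter is invalid."""


# ---------------------------------------------------------------------------
# Field-trial generator
# ---------------------------------------------------------------------------

@dataclass
class TrialTruth:
    """Data-generating truth for one multi-location RCBD trial.

    Trait value of a plot =
    ``entry mean + block effect + row polynomial + column polynomial
    + N(0, residual_sd)`` with block effects drawn ``N(0, block_sd)``
    per (location, block) and polynomials evaluated on grid coordinates
    centered per location. The entry mean is ``genotype_means[g]`` except
    for F1 entries, whose mean is the parents' mid-parent value plus
    ``heterosis_shift`` — so the planted mid-parent contrast equals the
    shift exactly.
    """

    genotype_means: Mapping[str, float] = field(
        default_factory=lambda: {"P1": 2100.0, "P2": 1950.0, "F1": 2025.0, "F2": 2025.0}
    )
    heterosis_shift: float = 190.0
    block_sd: float = 100.0
    residual_sd: float = 200.0
    row_poly: Sequence[float] = ()
    col_poly: Sequence[float] = ()
    n_blocks: int = 5
    reps_per_block: Mapping[str, int] | int = field(
        default_factory=lambda: dict(DEFAULT_REPS_PER_BLOCK)
    )
    locations: Sequence[str] = DEFAULT_LOCATIONS
    entry_class: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ENTRY_CLASS))
    trait: str = "yield"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.block_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if len(self.row_poly) > 5 or len(self.col_poly) > 5:
            raise ConfigurationError("trend polynomials are limited to degree 4")
        if self.n_blocks < 2:
            raise ConfigurationError("an RCBD needs at least 2 blocks")
        if isinstance(self.reps_per_block, int):
            self.reps_per_block = {g: self.reps_per_block for g in self.genotype_means}
        for g in self.reps_per_block:
            if g not in self.entry_class:
                raise ConfigurationError(f"genotype {g!r} has no entry_class")
        # F1 entries derive their mean from the parents' mid-parent value
        unknown = {
            g
            for g in set(self.reps_per_block) - set(self.genotype_means)
            if self.entry_class[g] != "F1"
        }
        if unknown:
            raise ConfigurationError(f"genotypes without a mean: {sorted(unknown)}")


def _eval_poly(coefs: Sequence[float], x: np.ndarray) -> np.ndarray:
    """Evaluate sum_k coefs[k] * x**(k+1) (no constant term; x centered)."""
    out = np.zeros_like(x, dtype=float)
    for k, c in enumerate(coefs):
        out += c * x ** (k + 1)
    return out


def generate_trial(truth: TrialTruth) -> pd.DataFrame:
    """Simulate one plot table for a multi-location RCBD trial.

    Within each location, each block forms one column of the field grid and
    the randomized entry order within the block gives the row coordinate,
    so planted row trends vary within blocks while column trends are
    confounded with blocks (as they are in a real serpentine layout).

    Returns a tidy frame with columns
    ``location, block, row, column, genotype, entry_class, <trait>``.
    """
    rng = np.random.default_rng(truth.seed)
    entries: list[str] = []
    for g, reps in truth.reps_per_block.items():
        if reps < 1:
            raise ConfigurationError(f"reps_per_block for {g!r} must be positive")
        entries.extend([g] * reps)

    by_class = {cls: g for g, cls in truth.entry_class.items() if g in truth.genotype_means}
    has_f1 = any(truth.entry_class[g] == "F1" for g in truth.reps_per_block)
    if has_f1:
        if "parent1" not in by_class or "parent2" not in by_class:
            raise ConfigurationError("an F1 entry needs both parents' means for the mid-parent")
        midparent = (
            truth.genotype_means[by_class["parent1"]] + truth.genotype_means[by_class["parent2"]]
        ) / 2.0

    rows = []
    for location in truth.locations:
        block_eff = rng.normal(0.0, truth.block_sd, size=truth.n_blocks)
        n_rows = len(entries)
        row_coord = np.arange(1, n_rows + 1, dtype=float)
        col_coord = np.arange(1, truth.n_blocks + 1, dtype=float)
        row_trend = _eval_poly(truth.row_poly, row_coord - row_coord.mean())
        col_trend = _eval_poly(truth.col_poly, col_coord - col_coord.mean())
        for b in range(truth.n_blocks):
            order = rng.permutation(n_rows)
            for r, idx in enumerate(order):
                g = entries[idx]
                cls = truth.entry_class[g]
                if cls == "F1":
                    mean = midparent + truth.heterosis_shift
                else:
                    mean = truth.genotype_means[g]
                value = (
                    mean
                    + block_eff[b]
                    + row_trend[r]
                    + col_trend[b]
                    + rng.normal(0.0, truth.residual_sd)
                )
                rows.append(
                    {
                        "location": location,
                        "block": b + 1,
                        "row": r + 1,
                        "column": b + 1,
                        "genotype": g,
                        "entry_class": cls,
                        truth.trait: value,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

EXPRESSION_CATEGORIES = ("additive", "above_both", "below_both", "parent_dominant", "null")


@dataclass
class ExpressionTruth:
    """Truth for a gene × sample FPKM-like matrix.

    Per-gene genotype means are built from a baseline ``b`` (log-normal
    around ``baseline_mean``, floored at 2 FPKM so planted fold changes
    survive the pseudocount) and the planted ``fold``:

    ==================  =========  =========  ==================
    category            P1 mean    P2 mean    F1 mean
    ==================  =========  =========  ==================
    null                b          b          b
    additive            b          b·fold     (P1+P2)/2
    above_both          b          b          b·fold
    below_both          b·fold     b·fold     b
    parent_dominant     b          b·fold     b·fold
    ==================  =========  =========  ==================

    Replicate noise is log-normal with coefficient of variation
    ``replicate_cv`` (mean-preserving); a per-(gene, location) log-normal
    factor with log-sd ``location_effect_sd`` scales all genotypes alike.
    """

    n_genes: int = 33000
    # defaults mirror the observed scale in leaf tissue: ~1% of genes
    # differential vs a single parent, ~25 above both and ~6 below both
    # parents out of ~33k expressed genes
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "additive": 0.01,
            "above_both": 25 / 33000,
            "below_both": 6 / 33000,
            "parent_dominant": 0.005,
        }
    )
    baseline_mean: float = 20.0
    fold: float = 4.0
    replicate_cv: float = 0.2
    location_effect_sd: float = 0.1
    n_replicates: int = 4
    locations: Sequence[str] = DEFAULT_LOCATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive (empty matrix)")
        if self.fold < 1:
            raise ConfigurationError("fold must be >= 1")
        if self.replicate_cv < 0 or self.location_effect_sd < 0:
            raise ConfigurationError("noise parameters must be non-negative")
        if sum(self.category_fractions.values()) > 1 + 1e-12:
            raise ConfigurationError("category fractions exceed 1")
        for c in self.category_fractions:
            if c not in EXPRESSION_CATEGORIES:
                raise ConfigurationError(f"unknown category {c!r}")


def generate_expression(
    truth: ExpressionTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an expression matrix.

    Returns ``(values, meta, gene_truth)`` where ``values`` is gene × sample
    (FPKM-like), ``meta`` has one row per sample
    (``sample, genotype, location, replicate``) and ``gene_truth`` records
    each gene's planted category, baseline and fold.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_genes
    genes = np.array([f"gene{i:05d}" for i in range(n)])

    categories = np.full(n, "null", dtype=object)
    start = 0
    for cat in EXPRESSION_CATEGORIES[:-1]:
        k = int(round(truth.category_fractions.get(cat, 0.0) * n))
        categories[start : start + k] = cat
        start += k
    perm = rng.permutation(n)
    categories = categories[perm]

    baseline = np.exp(rng.normal(np.log(truth.baseline_mean), 0.8, size=n))
    baseline = np.maximum(baseline, 2.0)
    fold = truth.fold

    means = {}  # genotype -> per-gene mean
    p1 = baseline.copy()
    p2 = baseline.copy()
    f1 = baseline.copy()
    add = categories == "additive"
    p2[add] = baseline[add] * fold
    f1[add] = (p1[add] + p2[add]) / 2.0
    up = categories == "above_both"
    f1[up] = baseline[up] * fold
    dn = categories == "below_both"
    p1[dn] = baseline[dn] * fold
    p2[dn] = baseline[dn] * fold
    dom = categories == "parent_dominant"
    p2[dom] = baseline[dom] * fold
    f1[dom] = baseline[dom] * fold
    means = {"P1": p1, "P2": p2, "F1": f1}

    cv = truth.replicate_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    loc_sd = truth.location_effect_sd

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for location in truth.locations:
        loc_factor = (
            np.exp(rng.normal(-0.5 * loc_sd**2, loc_sd, size=n)) if loc_sd > 0 else np.ones(n)
        )
        for genotype in ("P1", "P2", "F1"):
            for rep in range(1, truth.n_replicates + 1):
                sample = f"{genotype}_{location}_r{rep}"
                mu = means[genotype] * loc_factor
                if sigma > 0:
                    noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))
                    vals = mu * noise
                else:
                    vals = mu.copy()
                cols[sample] = vals
                meta_rows.append(
                    {"sample": sample, "genotype": genotype, "location": location, "replicate": rep}
                )

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(meta_rows)
    gene_truth = pd.DataFrame(
        {"gene": genes, "category": categories, "baseline": baseline, "fold": fold}
    ).set_index("gene")
    return values, meta, gene_truth


# ---------------------------------------------------------------------------
# Allele-depth generator
# ---------------------------------------------------------------------------

@dataclass
class AseTruth:
    """Truth for per-site allele-depth tables of parents + F1 hybrid.

    ``n_biased`` SNPs (``round(biased_fraction · n_snps)`` unless given
    explicitly) are planted with the favored allele drawn at
    ``bias_level`` in the F1; the rest are balanced (p = 0.5). Biased SNPs
    are grouped into ``n_biased_genes`` genes (round-robin, so some genes
    carry several biased SNPs, all with a shared favored parent); unbiased
    SNPs get singleton genes. The NMS4-like parent (``P2``) carries
    residual heterozygosity: with probability ``residual_het_rate`` a
    (SNP, parental replicate) pair is switched to a heterozygous genotype,
    which must disqualify the site from the parent-specific list.
    """

    n_snps: int = 4390
    biased_fraction: float = 241 / 4390
    n_biased: int | None = None
    bias_level: float = 0.9
    depth_mean: float = 50.0
    overdispersion_rho: float = 0.0
    residual_het_rate: float = 0.125
    splice_proximal_fraction: float = 0.05
    n_biased_genes: int | None = None
    n_replicates: int = 4
    locations: Sequence[str] = DEFAULT_LOCATIONS
    parents: tuple[str, str] = ("P1", "P2")
    het_parent: str = "P2"
    chrom: str = "Gm01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ConfigurationError("n_snps must be positive")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")
        if not 0 <= self.biased_fraction <= 1:
            raise ConfigurationError("biased_fraction must lie in [0, 1]")
        if not 0.5 < self.bias_level <= 1:
            raise ConfigurationError("bias_level must lie in (0.5, 1]")
        if not 0 <= self.residual_het_rate <= 1:
            raise ConfigurationError("residual_het_rate must lie in [0, 1]")
        if not 0 <= self.splice_proximal_fraction <= 1:
            raise ConfigurationError("splice_proximal_fraction must lie in [0, 1]")
        if not 0 <= self.overdispersion_rho < 1:
            raise ConfigurationError("overdispersion_rho must lie in [0, 1)")


_BASES = np.array(list("ACGT"))


def _binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    """Binomial draws, optionally beta-binomial with correlation ``rho``."""
    if rho <= 0:
        return rng.binomial(n, p)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    pp = rng.beta(a, b)
    return rng.binomial(n, pp)


def generate_allele_counts(
    truth: AseTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate allele-depth data.

    Returns ``(ad, samples, snp_truth, junctions)``:

    * ``ad`` — long table ``chrom, pos, ref, alt, sample, ref_count,
      alt_count`` for every (site, sample) pair;
    * ``samples`` — sample sheet ``sample, genotype, location, replicate``;
    * ``snp_truth`` — per SNP: origin parent of the alt allele, planted
      ``biased`` flag, ``favored_parent``, ``p_origin`` (expected fraction
      of the origin-parent allele in the F1), gene id, splice-proximal
      flag, and whether residual heterozygosity touched a parental rep;
    * ``junctions`` — splice-junction intron intervals as 0-based
      half-open ``chrom, start, end`` (BED convention); the 1-based
      exonic boundaries are ``start`` and ``end + 1``.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_snps
    p1, p2 = truth.parents

    pos = np.sort(rng.choice(np.arange(1000, 1000 + 1000 * n), size=n, replace=False))
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]

    origin = rng.choice(list(truth.parents), size=n)

    n_biased = (
        truth.n_biased if truth.n_biased is not None else int(round(truth.biased_fraction * n))
    )
    if n_biased > n:
        raise ConfigurationError("more biased SNPs requested than SNPs")
    biased = np.zeros(n, dtype=bool)
    biased[rng.choice(n, size=n_biased, replace=False)] = True

    # genes: biased SNPs share genes round-robin; unbiased are singletons
    genes = np.empty(n, dtype=object)
    n_biased_genes = truth.n_biased_genes
    if n_biased_genes is None:
        n_biased_genes = max(1, int(round(n_biased * 191 / 241))) if n_biased else 0
    biased_idx = np.flatnonzero(biased)
    favored = np.empty(n, dtype=object)
    favored[:] = None
    for j, idx in enumerate(biased_idx):
        genes[idx] = f"bgene{j % max(n_biased_genes, 1):05d}"
    # one favored parent per biased gene -> multi-SNP genes are consistent
    gene_favor = {
        f"bgene{g:05d}": rng.choice(list(truth.parents)) for g in range(max(n_biased_genes, 1))
    }
    for idx in biased_idx:
        favored[idx] = gene_favor[genes[idx]]
    for j, idx in enumerate(np.flatnonzero(~biased)):
        genes[idx] = f"ugene{j:05d}"

    # splice-proximal sites placed within 2 bp of an intron's left exonic
    # boundary; junctions are emitted as 0-based half-open intron intervals
    n_prox = int(round(truth.splice_proximal_fraction * n))
    prox = np.zeros(n, dtype=bool)
    prox_idx = rng.choice(n, size=n_prox, replace=False)
    prox[prox_idx] = True
    intron_len = 80
    starts = sorted({int(pos[idx]) - int(rng.integers(-2, 3)) for idx in prox_idx})
    junctions = pd.DataFrame(
        {
            "chrom": truth.chrom,
            "start": starts,
            "end": [s + intron_len for s in starts],
        }
    )

    # expected origin-allele fraction in the F1
    p_origin = np.full(n, 0.5)
    is_fav_origin = favored == origin
    p_origin[biased & is_fav_origin] = truth.bias_level
    p_origin[biased & ~is_fav_origin] = 1.0 - truth.bias_level

    samples_rows = []
    ad_rows = []
    het_touched = np.zeros(n, dtype=bool)
    for location in truth.locations:
        for genotype in (p1, p2, "F1"):
            for rep in range(1, truth.n_replicates + 1):
                sample = f"{genotype}_{location}_r{rep}"
                samples_rows.append(
                    {"sample": sample, "genotype": genotype, "location": location, "replicate": rep}
                )
                depth = rng.poisson(truth.depth_mean, size=n)
                if genotype == "F1":
                    # the origin parent is hom-alt, so the origin-parent
                    # allele fraction is the alt-read fraction
                    alt_count = _binomial(rng, depth, p_origin, truth.overdispersion_rho)
                else:
                    hom_alt = origin == genotype
                    p_alt = np.where(hom_alt, 1.0, 0.0)
                    if genotype == truth.het_parent and truth.residual_het_rate > 0:
                        switch = rng.random(n) < truth.residual_het_rate
                        p_alt = np.where(switch, 0.5, p_alt)
                        het_touched |= switch
                    alt_count = rng.binomial(depth, p_alt)
                ad_rows.append(
                    pd.DataFrame(
                        {
                            "chrom": truth.chrom,
                            "pos": pos,
                            "ref": ref,
                            "alt": alt,
                            "sample": sample,
                            "ref_count": depth - alt_count,
                            "alt_count": alt_count,
                        }
                    )
                )

    ad = pd.concat(ad_rows, ignore_index=True)
    samples = pd.DataFrame(samples_rows)
    snp_truth = pd.DataFrame(
        {
            "chrom": truth.chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "origin": origin,
            "biased": biased,
            "favored_parent": favored,
            "p_origin": p_origin,
            "gene": genes,
            "splice_proximal": prox,
            "het_contaminated": het_touched,
        }
    )
    return ad, samples, snp_truth, junctions


# ---------------------------------------------------------------------------
# Annotation generator (plumbing for the enrichment stage)
# ---------------------------------------------------------------------------

def generate_annotation(
    genes: Sequence[str],
    n_terms: int = 50,
    terms_per_gene: float = 2.0,
    enriched_term: str | None = "GO:9999999",
    enriched_genes: Sequence[str] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Random flat gene→GO table, optionally planting one enriched term.

    Returns a two-column frame ``gene, term``. ``enriched_genes`` all
    receive ``enriched_term`` on top of their random terms.
    """
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    rows = []
    for g in genes:
        k = rng.poisson(terms_per_gene)
        for t in rng.choice(terms, size=min(k, n_terms), replace=False):
            rows.append({"gene": g, "term": t})
    if enriched_term is not None:
        for g in enriched_genes:
            rows.append({"gene": g, "term": enriched_term})
    return pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates(ignore_index=True)


def truth_to_json(truth) -> str:
    """Serialize any truth dataclass to a JSON sidecar string."""
    d = asdict(truth)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
        elif isinstance(v, tuple):
            d[k] = list(v)
    return json.dumps(d, indent=2, default=str)
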