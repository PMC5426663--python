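"""Parent-specific SNP filtering and allele-bias calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hybridase import (
    AseTruth,
    BiasCall,
    bias_call_table,
    bias_histogram,
    call_parent_specific_snps,
    classify_bias,
    cross_location_bias_concordance,
    empirical_threshold,
    f1_allele_fractions,
    generate_allele_counts,
    junction_boundaries,
    mask_splice_proximal,
    substitution_class_test,
    summarize_gene_bias,
)
from conftest import make_ad_table


# ---------------------------------------------------------------------------
# Splice masking
# ---------------------------------------------------------------------------

def _sites(positions, chrom="c1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"}
    )


def test_masking_boundary_definition():
    junctions = pd.DataFrame({"chrom": ["c1"], "boundary": [100]})
    sites = _sites([97, 98, 100, 102, 103])
    kept, masked = mask_splice_proximal(sites, junctions, margin=2)
    assert sorted(masked["pos"]) == [98, 100, 102]
    assert sorted(kept["pos"]) == [97, 103]


def test_empty_junctions_keep_everything():
    sites = _sites([1, 2, 3])
    kept, masked = mask_splice_proximal(sites, pd.DataFrame(columns=["chrom", "boundary"]))
    assert len(kept) == 3 and masked.empty


def test_chromosome_mismatch_warns_and_keeps():
    junctions = pd.DataFrame({"chrom": ["c2"], "boundary": [100]})
    sites = _sites([100])
    with pytest.warns(UserWarning, match="not masked"):
        kept, masked = mask_splice_proximal(sites, junctions)
    assert len(kept) == 1 and masked.empty


def test_bed_interval_to_boundaries_conversion():
    # 0-based half-open intron [100, 180) -> last exonic bases 100 and 181
    introns = pd.DataFrame({"chrom": ["c1"], "start": [100], "end": [180]})
    b = junction_boundaries(introns)
    assert sorted(b["boundary"]) == [100, 181]
    sites = _sites([98, 102, 103, 179, 183, 184])
    kept, masked = mask_splice_proximal(sites, introns, margin=2)
    assert sorted(masked["pos"]) == [98, 102, 179, 183]


def test_masking_monotone_in_margin():
    rng = np.random.default_rng(1)
    sites = _sites(sorted(rng.choice(np.arange(1, 500), 60, replace=False)))
    junctions = pd.DataFrame({"chrom": "c1", "boundary": [50, 200, 390]})
    kept_sizes = [
        len(mask_splice_proximal(sites, junctions, margin=m)[0]) for m in range(0, 6)
    ]
    assert kept_sizes == sorted(kept_sizes, reverse=True)


# ---------------------------------------------------------------------------
# Parent-specific SNP filter vs brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_parent_specific(ad, samples, min_depth=8, minor=0.05):
    """Plain-loop restatement of the filter's textual criteria."""
    meta = {r["sample"]: r for _, r in samples.iterrows()}
    result = []
    for key, grp in ad.groupby(["chrom", "pos", "ref", "alt"]):
        calls = {}  # parent -> list of genotype calls
        depths_ok = True
        for _, row in grp.iterrows():
            g = meta[row["sample"]]["genotype"]
            if g == "F1":
                continue
            d = row["ref_count"] + row["alt_count"]
            if d < min_depth:
                depths_ok = False
                call = "fail"
            elif row["alt_count"] / d <= minor:
                call = "ref"
            elif row["ref_count"] / d <= minor:
                call = "alt"
            else:
                call = "het"
            calls.setdefault(g, []).append(call)
        if not depths_ok or len(calls) < 2:
            continue
        parents = sorted(calls)
        all_alt = [p for p in parents if all(c == "alt" for c in calls[p])]
        all_ref = [p for p in parents if all(c == "ref" for c in calls[p])]
        if len(all_alt) == 1 and len(all_ref) == len(parents) - 1:
            result.append((*key, all_alt[0]))
    return sorted(result)


def _random_toy_table(rng, n_sites):
    """Random ≤20-site allele-depth table exercising all filter branches."""
    samples = []
    for loc in ("K", "C"):
        for g in ("P1", "P2", "F1"):
            for r in (1, 2):
                samples.append((f"{g}_{loc}_{r}", g, loc, r))
    samples = pd.DataFrame(samples, columns=["sample", "genotype", "location", "replicate"])
    rows = []
    for i in range(n_sites):
        pos = 10 * (i + 1)
        for _, s in samples.iterrows():
            d = int(rng.integers(0, 30))
            kind = rng.choice(["ref", "alt", "het"])
            if kind == "ref":
                ac = int(rng.binomial(d, 0.02))
            elif kind == "alt":
                ac = d - int(rng.binomial(d, 0.02))
            else:
                ac = int(rng.binomial(d, 0.5))
            rows.append(("c1", pos, "C", "T", s["sample"], d - ac, ac))
    ad = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample", "ref_count", "alt_count"]
    )
    return ad, samples


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_filter_matches_brute_force_on_random_toy_tables(seed):
    rng = np.random.default_rng(seed)
    ad, samples = _random_toy_table(rng, n_sites=int(rng.integers(5, 21)))
    got = call_parent_specific_snps(ad, samples)
    got_set = sorted(zip(got["chrom"], got["pos"], got["ref"], got["alt"], got["origin"]))
    assert got_set == brute_force_parent_specific(ad, samples)


def test_clean_toy_site_is_the_only_one_returned():
    # 6 sites; only site 30 is cleanly parent-specific (P2 alt, P1 ref)
    recs = []
    samples = []
    for loc in ("K", "C"):
        for g in ("P1", "P2"):
            for r in (1, 2):
                samples.append((f"{g}_{loc}_{r}", g, loc, r))
    patterns = {
        10: {"P1": "alt", "P2": "alt"},  # not unique
        20: {"P1": "het", "P2": "alt"},  # P1 heterozygous
        30: {"P1": "ref", "P2": "alt"},  # clean
        40: {"P1": "ref", "P2": "ref"},  # monomorphic
        50: {"P1": "ref", "P2": "lowdepth"},
        60: {"P1": "alt", "P2": "het"},
    }
    for pos, pat in patterns.items():
        for s, g, loc, r in samples:
            kind = pat[g]
            if kind == "ref":
                rc, ac = 20, 0
            elif kind == "alt":
                rc, ac = 0, 20
            elif kind == "het":
                rc, ac = 10, 10
            else:
                rc, ac = 3, 0
            recs.append(("c1", pos, "A", "G", s, rc, ac))
    ad, smp = make_ad_table(recs, samples)
    got = call_parent_specific_snps(ad, smp)
    assert list(got["pos"]) == [30]
    assert list(got["origin"]) == ["P2"]


def test_one_heterozygous_replicate_rejects_site():
    recs, samples = [], []
    for loc in ("K", "C"):
        for g in ("P1", "P2"):
            for r in (1, 2):
                samples.append((f"{g}_{loc}_{r}", g, loc, r))
    for s, g, loc, r in samples:
        if g == "P2" and loc == "C" and r == 2:
            rc, ac = 10, 10  # het in one of 4 origin-parent reps
        elif g == "P2":
            rc, ac = 0, 20
        else:
            rc, ac = 20, 0
        recs.append(("c1", 10, "A", "G", s, rc, ac))
    ad, smp = make_ad_table(recs, samples)
    assert call_parent_specific_snps(ad, smp).empty


def test_zero_het_rate_keeps_every_clean_site():
    truth = AseTruth(n_snps=150, residual_het_rate=0.0, splice_proximal_fraction=0.0, seed=5)
    ad, samples, snp_truth, _ = generate_allele_counts(truth)
    got = call_parent_specific_snps(ad, samples)
    # only depth can reject; at depth_mean 50 and min_depth 8 essentially none
    assert len(got) >= 0.99 * len(snp_truth)


def test_min_depth_monotonicity(small_ase):
    ad, samples, _, _ = small_ase
    sizes = [len(call_parent_specific_snps(ad, samples, min_depth=d)) for d in (0, 8, 30, 45)]
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# Fractions and bias classification
# ---------------------------------------------------------------------------

def _f1_ad(pairs):
    return pd.DataFrame(
        {
            "sample": [f"F1_r{i}" for i in range(len(pairs))],
            "ref_count": [r for r, a in pairs],
            "alt_count": [a for r, a in pairs],
        }
    )


SNP = {"chrom": "c1", "pos": 10, "ref": "A", "alt": "G", "origin": "P2"}


def test_fraction_hand_arithmetic():
    call = f1_allele_fractions(SNP, _f1_ad([(2, 8), (4, 6)]), "K", min_depth=8)
    assert call.per_replicate_fractions == [pytest.approx(0.8), pytest.approx(0.6)]
    assert call.pooled_fraction == pytest.approx(14 / 20)
    assert call.total_depth == 20


def test_fraction_extremes():
    assert f1_allele_fractions(SNP, _f1_ad([(0, 10), (0, 5)]), "K", 1).pooled_fraction == 1.0
    assert f1_allele_fractions(SNP, _f1_ad([(5, 5), (5, 5)]), "K", 1).pooled_fraction == 0.5


def test_low_depth_replicates_excluded_and_unevaluable_flag():
    call = f1_allele_fractions(SNP, _f1_ad([(2, 3), (1, 2)]), "K", min_depth=8)
    assert not call.evaluable
    assert call.total_depth == 0
    classified = classify_bias(call)
    assert not classified.biased


def _call(pooled_counts, rep_fracs, origin="P2"):
    return BiasCall(
        chrom="c1",
        pos=1,
        origin=origin,
        location="K",
        per_replicate_fractions=rep_fracs,
        pooled_fraction=pooled_counts,
        total_depth=100,
        evaluable=True,
    )


def test_bias_strictly_above_threshold():
    c = classify_bias(_call(0.74, [0.7, 0.76, 0.75]))
    assert c.biased and c.favored_allele == "P2"


def test_pooled_exactly_073_not_biased():
    assert not classify_bias(_call(0.73, [0.73, 0.73])).biased


def test_inconsistent_replicate_blocks_bias():
    assert not classify_bias(_call(0.78, [0.9, 0.85, 0.4])).biased


def test_bias_toward_other_parent():
    c = classify_bias(_call(0.2, [0.25, 0.15]))
    assert c.biased and c.favored_allele == "P1"


def test_ref_alt_swap_symmetry(small_ase):
    ad, samples, _, _ = small_ase
    snps = call_parent_specific_snps(ad, samples)
    calls = bias_call_table(ad, samples, snps)

    swapped = ad.rename(columns={"ref_count": "alt_count", "alt_count": "ref_count"})
    swapped = swapped.rename(columns={"ref": "alt", "alt": "ref"})
    s_snps = call_parent_specific_snps(swapped, samples)
    s_calls = bias_call_table(swapped, samples, s_snps)

    m = calls.merge(s_calls, on=["chrom", "pos", "location"], suffixes=("", "_s"))
    assert len(m) == len(calls) == len(s_calls)
    assert np.allclose(m["pooled_fraction"], 1 - m["pooled_fraction_s"])
    assert (m["biased"] == m["biased_s"]).all()
    biased = m[m["biased"]]
    assert (biased["favored_allele"] == biased["favored_allele_s"]).all()


# ---------------------------------------------------------------------------
# Empirical threshold
# ---------------------------------------------------------------------------

def test_zero_sd_threshold_is_half():
    assert empirical_threshold([0.5] * 40) == 0.5


def test_sd_0115_reproduces_073():
    rng = np.random.default_rng(2)
    fr = rng.normal(0.5, 0.115, 5000)
    fr = 0.5 + (fr - fr.mean())  # recenter
    fr *= 0.115 / fr.std(ddof=1)  # rescale to exact SD about the mean
    fr = fr - fr.mean() + 0.5
    got = empirical_threshold(fr)
    assert got == pytest.approx(0.5 + 2 * np.std(fr, ddof=1), rel=1e-12)
    assert got == pytest.approx(0.73, abs=1e-6)


def test_threshold_matches_direct_formula_on_fixture():
    rng = np.random.default_rng(7)
    fr = rng.beta(20, 20, 100)
    assert empirical_threshold(fr) == pytest.approx(0.5 + 2 * fr.std(ddof=1), rel=1e-12)


def test_few_fractions_falls_back_with_warning():
    with pytest.warns(UserWarning, match="fixed threshold"):
        assert empirical_threshold([0.6] * 10) == 0.73


# ---------------------------------------------------------------------------
# Concordance, gene summary, substitution class, histogram
# ---------------------------------------------------------------------------

def _calls_frame(fracs, biased, favored, location):
    return pd.DataFrame(
        {
            "chrom": "c1",
            "pos": np.arange(1, len(fracs) + 1) * 10,
            "origin": "P2",
            "location": location,
            "pooled_fraction": fracs,
            "evaluable": True,
            "biased": biased,
            "favored_allele": favored,
        }
    )


def test_identical_fractions_r2_one_no_switch():
    f = [0.9, 0.8, 0.5, 0.3, 0.85]
    b = [True, True, False, False, True]
    fav = ["P2", "P2", None, None, "P2"]
    a = _calls_frame(f, b, fav, "K")
    c = _calls_frame(f, b, fav, "C")
    r2_all, r2_biased, switched = cross_location_bias_concordance(a, c)
    assert r2_all == pytest.approx(1.0)
    assert switched == 0


def test_r2_matches_hand_pearson_on_five_snps():
    fa = [0.9, 0.7, 0.55, 0.4, 0.8]
    fb = [0.85, 0.75, 0.5, 0.45, 0.9]
    a = _calls_frame(fa, [False] * 5, [None] * 5, "K")
    b = _calls_frame(fb, [False] * 5, [None] * 5, "C")
    r2_all, _, _ = cross_location_bias_concordance(a, b)
    assert r2_all == pytest.approx(np.corrcoef(fa, fb)[0, 1] ** 2, rel=1e-12)


def test_no_switched_bias_over_seeds():
    switched_total = 0
    for seed in range(20):
        truth = AseTruth(
            n_snps=60,
            bias_level=0.9,
            depth_mean=100.0,
            residual_het_rate=0.0,
            splice_proximal_fraction=0.0,
            seed=17 + seed,
        )
        ad, samples, _, _ = generate_allele_counts(truth)
        snps = call_parent_specific_snps(ad, samples)
        calls = bias_call_table(ad, samples, snps)
        a = calls[calls["location"] == "Kinston"]
        b = calls[calls["location"] == "Clayton"]
        *_, switched = cross_location_bias_concordance(a, b)
        switched_total += switched
    assert switched_total == 0


def test_gene_summary_consistency_flags():
    calls = _calls_frame(
        [0.9, 0.85, 0.2, 0.9, 0.5], [True, True, True, True, False],
        ["P2", "P2", "P1", "P2", None], "K"
    )
    gene_map = {("c1", 10): "gA", ("c1", 20): "gA", ("c1", 30): "gB", ("c1", 40): "gB"}
    out = {s.gene: s for s in summarize_gene_bias(calls, gene_map)}
    assert out["gA"].n_biased == 2 and out["gA"].consistent
    assert out["gB"].n_biased == 2 and not out["gB"].consistent
    assert "__unmapped__" in out


def test_gene_summary_truth_round_trip_totals():
    truth = AseTruth(
        n_snps=482,
        n_biased=241,
        n_biased_genes=191,
        depth_mean=200.0,
        bias_level=0.95,
        residual_het_rate=0.0,
        splice_proximal_fraction=0.0,
        seed=19,
    )
    ad, samples, snp_truth, _ = generate_allele_counts(truth)
    snps = call_parent_specific_snps(ad, samples)
    calls = bias_call_table(ad, samples, snps)
    loc = calls[calls["location"] == "Kinston"]
    gene_map = {(c, int(p)): g for c, p, g in zip(snp_truth.chrom, snp_truth.pos, snp_truth.gene)}
    summaries = summarize_gene_bias(loc, gene_map)
    n_biased_snps = sum(s.n_biased for s in summaries)
    n_biased_genes = sum(1 for s in summaries if s.n_biased > 0)
    assert n_biased_snps == 241
    assert n_biased_genes == 191
    assert all(s.consistent for s in summaries if s.n_biased > 0)


def test_substitution_class_definition_and_symmetric_table():
    biased = pd.DataFrame({"ref": ["C", "A"] * 5, "alt": ["T", "T"] * 5})
    unbiased = pd.DataFrame({"ref": ["C", "A"] * 5, "alt": ["T", "T"] * 5})
    table, p, degenerate = substitution_class_test(biased, unbiased)
    assert table.tolist() == [[5, 5], [5, 5]]
    assert p == pytest.approx(1.0)
    assert not degenerate


def test_fisher_matches_hypergeometric_enumeration():
    from scipy.stats import hypergeom

    biased = pd.DataFrame({"ref": ["C"] * 8 + ["A"] * 2, "alt": ["T"] * 8 + ["T"] * 2})
    unbiased = pd.DataFrame({"ref": ["G"] * 1 + ["A"] * 9, "alt": ["A"] * 1 + ["C"] * 9})
    table, p, _ = substitution_class_test(biased, unbiased)
    assert table.tolist() == [[8, 2], [1, 9]]
    # enumerate all tables with the same margins; two-sided Fisher p
    N, K, n = 20, 9, 10  # total, class-positive, biased
    obs = hypergeom.pmf(8, N, K, n)
    p_oracle = sum(
        hypergeom.pmf(k, N, K, n)
        for k in range(max(0, n + K - N), min(n, K) + 1)
        if hypergeom.pmf(k, N, K, n) <= obs * (1 + 1e-12)
    )
    assert p == pytest.approx(p_oracle, rel=1e-9)


def test_empty_stratum_degenerate():
    biased = pd.DataFrame({"ref": [], "alt": []})
    unbiased = pd.DataFrame({"ref": ["C"], "alt": ["T"]})
    _, p, degenerate = substitution_class_test(biased, unbiased)
    assert p == 1.0 and degenerate


def test_histogram_single_bin_and_normalization():
    calls = _calls_frame([0.5] * 30, [False] * 30, [None] * 30, "K")
    hist = bias_histogram(calls, n_bins=20)
    panel = hist[hist["origin"] == "P2"]
    assert panel["percent"].sum() == pytest.approx(100.0)
    assert (panel["count"] > 0).sum() == 1
    assert panel.loc[panel["count"] > 0, "percent"].iloc[0] == pytest.approx(100.0)


def test_histogram_matches_direct_counting():
    rng = np.random.default_rng(4)
    fr = rng.uniform(0, 1, 50)
    calls = _calls_frame(fr, [False] * 50, [None] * 50, "K")
    hist = bias_histogram(calls, n_bins=10)
    panel = hist[hist["origin"] == "P2"]
    edges = np.linspace(0, 1, 11)
    oracle, _ = np.histogram(fr, bins=edges)
    assert list(panel["count"]) == list(oracle)
    assert panel["percent"].sum() == pytest.approx(100.0)
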