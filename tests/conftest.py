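import numpy as np
import pandas as pd
import pytest

from hybridase import AseTruth, ExpressionTruth, TrialTruth, generate_allele_counts


@pytest.fixture(scope="session")
def small_trial():
    """A single-location RCBD with moderate noise, 30 plots."""
    truth = TrialTruth(
        genotype_means={"P1": 100.0, "P2": 120.0, "F2": 110.0},
        heterosis_shift=15.0,
        block_sd=5.0,
        residual_sd=8.0,
        row_poly=(1.5,),
        n_blocks=5,
        reps_per_block={"P1": 2, "P2": 2, "F1": 1, "F2": 1},
        locations=("Kinston",),
        seed=21,
    )
    from hybridase import generate_trial

    return generate_trial(truth), truth


@pytest.fixture(scope="session")
def noise_free_expression():
    truth = ExpressionTruth(
        n_genes=400,
        replicate_cv=0.0,
        location_effect_sd=0.0,
        category_fractions={
            "additive": 0.10,
            "above_both": 0.05,
            "below_both": 0.05,
            "parent_dominant": 0.05,
        },
        seed=13,
    )
    from hybridase import generate_expression

    values, meta, gene_truth = generate_expression(truth)
    return values, meta, gene_truth


@pytest.fixture(scope="session")
def small_ase():
    """1000 SNPs at the study's depth/bias settings, both locations."""
    truth = AseTruth(n_snps=1000, bias_level=0.9, depth_mean=50.0, seed=17)
    ad, samples, snp_truth, junctions = generate_allele_counts(truth)
    return ad, samples, snp_truth, junctions


def make_ad_table(records, samples):
    """Long allele-depth frame from (chrom, pos, ref, alt, sample, rc, ac) tuples."""
    return pd.DataFrame(
        records, columns=["chrom", "pos", "ref", "alt", "sample", "ref_count", "alt_count"]
    ), pd.DataFrame(samples, columns=["sample", "genotype", "location", "replicate"])
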