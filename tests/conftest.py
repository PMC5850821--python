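import numpy as np
import pandas as pd
import pytest

from tepop.synth import (
    ErrorModel,
    emulate_caller_output,
    make_coverage_tracks,
    make_gene_models,
    make_genome_layout,
    make_te_families,
    simulate_population_tes,
)


@pytest.fixture(scope="session")
def layout():
    return make_genome_layout(2, [300_000, 250_000], arm_fraction=0.5, seed=7)


@pytest.fixture(scope="session")
def families(layout):
    return make_te_families(
        8, {"dna": 0.7, "retro": 0.2, "unknown": 0.1}, (150, 800), seed=3
    )


@pytest.fixture(scope="session")
def population(layout, families):
    """(ref_annotation, truth_events, truth_matrix) for a small panel."""
    return simulate_population_tes(
        layout, families, n_strains=12, n_ref_sites=40, n_novel_sites=60,
        sfs_skew=0.3, arm_bias=0.8, seed=5,
    )


@pytest.fixture(scope="session")
def noiseless_calls(population, layout):
    _, _, truth = population
    model = ErrorModel.noiseless()
    calls = emulate_caller_output(truth, layout, model, seed=9)
    coverage = make_coverage_tracks(layout, truth.strains, model, seed=9)
    return calls, coverage


@pytest.fixture(scope="session")
def gene_models(layout):
    return make_gene_models(layout, gene_density=40, seed=11)


def two_gene_models():
    """Tiny hand-built gene set for annotation unit tests."""
    from tepop.synth.genome import GeneModels

    genes = pd.DataFrame(
        {
            "chrom": ["I", "I"],
            "start": [50_000, 60_000],
            "end": [53_000, 63_000],
            "strand": ["+", "+"],
            "biotype": ["protein_coding", "pseudogene"],
            "phenotype": ["embryonic lethal", "dumpy"],
        },
        index=pd.Index(["gA", "gB"], name="gene_id"),
    )
    features = pd.DataFrame(
        [
            ("gA", "I", 50_000, 50_199, "five_prime_UTR"),
            ("gA", "I", 50_200, 51_000, "CDS"),
            ("gA", "I", 51_001, 51_500, "intron"),
            ("gA", "I", 51_501, 52_800, "CDS"),
            ("gA", "I", 52_801, 53_000, "three_prime_UTR"),
            ("gB", "I", 60_000, 61_000, "CDS"),
            ("gB", "I", 61_001, 61_500, "intron"),
            ("gB", "I", 61_501, 63_000, "CDS"),
        ],
        columns=["gene_id", "chrom", "start", "end", "feature"],
    )
    return GeneModels(genes=genes, features=features)


def small_matrix():
    """Hand-built 3-strain matrix: 3 insertion sites, 3 reference sites."""
    from tepop.matrix import SiteMatrix

    sites = pd.DataFrame(
        {
            "chrom": ["I"] * 6,
            "position": [100, 200, 300, 400, 500, 600],
            "family": ["famA", "famA", "famB", "famA", "famB", "famB"],
            "te_class": ["dna", "dna", "retro", "dna", "retro", "retro"],
            "site_type": ["insertion"] * 3 + ["reference"] * 3,
            "ref_class": [np.nan] * 3 + ["active", "active", "monomorphic"],
        },
        index=pd.Index(
            ["I_100_famA_NR", "I_200_famA_NR", "I_300_famB_NR",
             "I_400_famA_R", "I_500_famB_R", "I_600_famB_R"],
            name="site_id",
        ),
    )
    values = pd.DataFrame(
        {
            "s1": [1, 1, 1, 0, 0, 1.0],
            "s2": [0, 1, 0, 1, 1, 1.0],
            "s3": [0, 0, 0, 1, 0, 1.0],
        },
        index=sites.index,
    )
    return SiteMatrix(sites, values)
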