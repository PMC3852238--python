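import dataclasses
import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from methyldiff import (
    CallingParams,
    Gene,
    GenomeAnnotation,
    SimulationParams,
    call_mcg,
    simulate_annotation,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_params():
    """A quick cohort: ~25k CG site records, default noise."""
    return SimulationParams(genome_length=200_000, n_chromosomes=2, n_genes=30,
                            smrna_loci=10, seed=11)


@pytest.fixture(scope="session")
def noise_free_params(small_params):
    return dataclasses.replace(
        small_params,
        conversion_failure_rate=0.0,
        partial_methylation_level=1.0,
        epipolymorphism_rate=0.0,
        covered_fraction=1.0,
    )


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_params):
    annotation = simulate_annotation(noise_free_params)
    truth, tables = simulate_cohort(annotation, noise_free_params)
    return annotation, truth, tables


@pytest.fixture(scope="session")
def noise_free_callsets(noise_free_cohort):
    _, truth, tables = noise_free_cohort
    return {ind: call_mcg(t, CallingParams()) for ind, t in tables.items()}


@pytest.fixture
def toy_annotation():
    """Hand-built geometry: one gene per strand, a TE over gene1's intron,
    one smRNA locus, 10-kb chromosome."""
    gene_plus = Gene("gplus", "chr1", "+", 3000, 4000,
                     exons=[(3000, 3300), (3700, 4000)])
    gene_minus = Gene("gminus", "chr1", "-", 6000, 7000,
                      exons=[(6000, 6400), (6600, 7000)])
    ann = GenomeAnnotation(
        chromosomes={"chr1": 10_000},
        genes=[gene_plus, gene_minus],
        te_intervals=[("chr1", 3350, 3650), ("chr1", 9000, 9200)],
        smrna_intervals=[("chr1", 500, 600)],
    )
    ann.validate()
    return ann


def make_dmc_table(positions, direction="A", chrom="chr1"):
    return pd.DataFrame({
        "chrom": chrom,
        "pos": list(positions),
        "strand": "+",
        "direction": direction,
    })
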