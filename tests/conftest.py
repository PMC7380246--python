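import numpy as np
import pandas as pd
import pytest

from chillmeth.simulate import SimulationDesign, simulate_experiment


@pytest.fixture(scope="session")
def desk_exp():
    """Desk-scale two-genotype experiment with planted DMRs/DEGs/pairs."""
    return simulate_experiment(SimulationDesign(seed=11))


@pytest.fixture(scope="session")
def single_genotype_design():
    return SimulationDesign(
        seed=13, conditions={"royal_dawn": (0, 173, 348, 516)}
    )


@pytest.fixture(scope="session")
def single_genotype_exp(single_genotype_design):
    return simulate_experiment(single_genotype_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def coverage_filtered(calls_by_sample, min_coverage=5):
    return {
        s: df[(df["n_meth"] + df["n_unmeth"]) >= min_coverage].reset_index(drop=True)
        for s, df in calls_by_sample.items()
    }


@pytest.fixture(scope="session")
def tiny_calls():
    """Hand-written call table on one chromosome for region summaries."""
    rows = [
        ("chr1", 100, "+", 4, 1, "CHH"),
        ("chr1", 120, "-", 3, 2, "CHH"),
        ("chr1", 140, "+", 5, 0, "CHH"),
        ("chr1", 160, "+", 6, 0, "CpG"),
        ("chr1", 180, "-", 0, 6, "CHG"),
        ("chr2", 100, "+", 9, 1, "CpG"),
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
    )
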