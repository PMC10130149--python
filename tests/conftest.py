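"""Shared fixtures: small simulated cohorts and hand-built genotype data.

Heavy simulations are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from driftprint import scenarios
from driftprint.model import GenotypeMatrix, SampleTable
from driftprint.synthetic import (
    DemeSpec,
    DemographyModel,
    MutationModel,
    RecombinationModel,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast two-deme cohort for IO round trips and sanity checks."""
    demo = DemographyModel(
        n_anc=30,
        demes=[DemeSpec("stable", 30, 0, "anadromous", 6),
               DemeSpec("locked", 8, 20, "landlocked", 6)],
        outgroup_divergence=4000,
        burn_in=120,
    )
    return simulate_cohort(
        demo, MutationModel(mu=4e-7), RecombinationModel(length=800_000), seed=42
    )


@pytest.fixture(scope="session")
def two_deme_cohort():
    """One replicate of the standard bottleneck scenario."""
    return scenarios.two_deme_bottleneck(seed=11)


@pytest.fixture(scope="session")
def recovery_replicates():
    """Twenty seeded replicates of the bottleneck signature-recovery run."""
    return scenarios.signature_recovery(20, seed=1)


def make_matrix(genotypes, samples=None, positions=None, chrom="chr1"):
    """Hand-rolled GenotypeMatrix from a nested list of dosage codes."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    positions = positions if positions is not None else np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "ref": "A", "alt": "G",
    })
    return GenotypeMatrix(samples=list(samples), sites=sites, genotypes=g)


def make_sample_table(samples, populations, life_history=None):
    life_history = life_history or ["anadromous"] * len(samples)
    return SampleTable(pd.DataFrame({
        "sample": samples, "population": populations, "life_history": life_history,
    }))
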