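"""Shared fixtures: desk-scale synthetic panels reused across test modules.

All fixtures are deterministic (fixed seeds) and session-scoped where
construction is non-trivial.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from nampanel import assoc, impute, simulate
from nampanel.types import Chromosome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: Reduced three-chromosome genome used by most tests.
TEST_CHROMOSOMES = [
    Chromosome("chr1", 20_000_000, 90.0),
    Chromosome("chr2", 15_000_000, 70.0),
    Chromosome("chr3", 18_000_000, 80.0),
]


@pytest.fixture(scope="session")
def small_panel():
    """3 alternates, 2 chromosomes, ~25 SNPs/Mb."""
    return simulate.build_founder_panel(
        3,
        chromosomes=[Chromosome("chr1", 12_000_000, 60.0),
                     Chromosome("chr2", 10_000_000, 50.0)],
        snp_density=25,
        seed=11,
    )


@pytest.fixture(scope="session")
def ril150_panel():
    """Founder panel for the single-population fixtures."""
    return simulate.build_founder_panel(
        3, chromosomes=TEST_CHROMOSOMES, snp_density=12, seed=21)


@pytest.fixture(scope="session")
def ril150_raw(ril150_panel):
    """F8 population of 150 lines before GBS observation (truth known)."""
    return simulate.breed_ril_population(ril150_panel, "alt01", 150, seed=22)


@pytest.fixture(scope="session")
def ril150_gbs(ril150_panel, ril150_raw):
    """GBS-observed population: 400 markers, 21.6% missing."""
    markers = simulate.sample_gbs_markers(ril150_raw, 400, seed=23)
    return simulate.apply_gbs_observation_model(
        ril150_raw, markers, missing_rate=0.216, geno_error_rate=0.001, seed=24)


@pytest.fixture(scope="session")
def ril150_imputed(ril150_gbs):
    pop, report = impute.conservative_impute(ril150_gbs)
    return pop, report


@pytest.fixture(scope="session")
def ril150_probs(ril150_imputed):
    pop, _ = ril150_imputed
    return impute.genotype_probabilities(
        pop.genotypes, pop.genetic_map, generation=pop.generation)


@pytest.fixture(scope="session")
def mini_nam():
    """14 populations x 25 lines merged on a dense projected SNP index."""
    panel = simulate.build_founder_panel(
        14, chromosomes=TEST_CHROMOSOMES, snp_density=25, seed=31)
    pops = simulate.simulate_study_populations(
        panel, seed=32, lines_per_population=25,
        gbs_markers_per_population=150, missing_rates=0.216)
    imputed, dense = [], []
    for pop in pops:
        ip, _ = impute.conservative_impute(pop)
        imputed.append(ip)
        dense.append(impute.impute_parental_snps(ip, panel))
    nam = assoc.merge_populations(imputed, dense, panel)
    nam, _ = assoc.collapse_perfect_ld(nam)
    return nam
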