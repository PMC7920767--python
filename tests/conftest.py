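import numpy as np
import pytest

from plastovar.alignment import align_plastomes, scan_variants
from plastovar.synthetic import CohortConfig, simulate_plastomes

STANDARD_SEED = 11
STANDARD_LENGTH = 20_000


@pytest.fixture(scope="session")
def cohort():
    """One standard synthetic cohort shared across the suite: three
    genera, seven alder-like individuals across three regions, 34
    planted variants (16 SNPs / 5 InDels / 13 homopolymer)."""
    genomes, truth = simulate_plastomes(CohortConfig(seed=STANDARD_SEED, genome_length=STANDARD_LENGTH))
    return genomes, truth


@pytest.fixture(scope="session")
def focal(cohort):
    genomes, truth = cohort
    alnus = [g for g in genomes if g.taxon == "Alnus"]
    ref = next(g for g in alnus if g.role == "reference")
    return alnus, ref, truth


@pytest.fixture(scope="session")
def focal_scan(focal):
    alnus, ref, truth = focal
    aln = align_plastomes(alnus, ref.id)
    sites = scan_variants(aln)
    regions = {g.id: g.region_label for g in alnus if g.role == "individual"}
    return aln, sites, regions


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
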