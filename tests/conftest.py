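import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bulkseg as bs

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mini_genome() -> bs.GenomeModel:
    """Two-chromosome genome with the default causal loci and ~600 markers."""
    rng = np.random.default_rng(7)
    loci = bs.DEFAULT_CAUSAL_LOCI
    chroms = [("chr02", 45_000_000), ("chr03", 62_000_000)]
    positions = {}
    for name, length in chroms:
        pos = np.sort(rng.choice(length, size=300, replace=False) + 1)
        for locus in loci:
            if locus.chrom == name:
                pos[np.argmin(np.abs(pos - locus.pos))] = locus.pos
        positions[name] = np.unique(pos)
    return bs.GenomeModel(
        chromosomes=chroms,
        recombination_rate=2.0,
        snp_positions=positions,
        causal_loci=loci,
    )


@pytest.fixture(scope="session")
def phenotyped_population(mini_genome) -> bs.F2Population:
    pop = bs.simulate_f2(mini_genome, 4000, seed=11)
    return bs.assign_phenotypes(pop, bs.PhenotypeModel(), seed=12)
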