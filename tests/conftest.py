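import numpy as np
import pytest

from merinosim.founders import (build_founder_population,
                                generate_ancestral_panel, mosaic_copy)
from merinosim.genome import GenomeMap


@pytest.fixture(scope="session")
def small_genome():
    return GenomeMap.uniform(n_chromosomes=2, n_markers=200,
                             chromosome_length=1.0)


@pytest.fixture(scope="session")
def small_founders(small_genome):
    """Deterministic 12-ram / 48-ewe founder population, 200 markers."""
    rng = np.random.default_rng(1234)
    panel = generate_ancestral_panel(small_genome, 30, rng=rng)
    mosaic = mosaic_copy(panel, 150, switch_rate=1.0, rng=rng)
    return build_founder_population(mosaic, n_rams=12, n_ewes=48,
                                    n_random_mating_generations=3,
                                    rng=rng)


def random_pedigree(n, rng, p_founder=0.2):
    """Random valid pedigree (parents precede offspring), for oracles."""
    sire = -np.ones(n, dtype=np.int64)
    dam = -np.ones(n, dtype=np.int64)
    sex = rng.integers(0, 2, size=n)
    sex[:4] = [0, 1, 0, 1]  # guarantee both sexes early on
    for i in range(2, n):
        if rng.random() < p_founder:
            continue
        males = np.flatnonzero(sex[:i] == 0)
        females = np.flatnonzero(sex[:i] == 1)
        if males.size and females.size:
            sire[i] = rng.choice(males)
            dam[i] = rng.choice(females)
    return sire, dam
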