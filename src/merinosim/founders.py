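"""Synthetic founder genotypes and the founder herdbook population.

The real programme rests on ~50K SNP genotypes of 785 herdbook animals;
no such data ships with this package, so founders are emulated in three
steps: (1) an ancestral haplotype panel with a U-shaped Beta allele
frequency spectrum and no linkage disequilibrium, (2) mosaic copying of
those haplotypes with a Poisson template-switch process along the genetic
map, which creates block LD whose decay length is set by the switch rate,
and (3) several generations of random mating to build initial pedigree
relatedness, after which the final generation is assembled into the
configured numbers of breeding rams and ewes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .genome import ConfigurationError, GenomeMap, meiosis_batch
from .population import FEMALE, MALE, Population

__all__ = [
    "HaplotypePanel",
    "FounderPopulation",
    "generate_ancestral_panel",
    "mosaic_copy",
    "build_founder_population",
]


@dataclass
class HaplotypePanel:
    """A set of phased haploid allele sequences over a genome map."""

    genome: GenomeMap
    alleles: np.ndarray  # (n_haplotypes, n_markers) uint8 in {0, 1}

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or \
                self.alleles.shape[1] != self.genome.n_markers:
            raise ConfigurationError("panel shape does not match genome map")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def allele_frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


@dataclass
class FounderPopulation:
    """The assembled founder herdbook: breeding rams plus breeding ewes."""

    population: Population
    ram_ids: np.ndarray
    ewe_ids: np.ndarray

    @property
    def n_rams(self) -> int:
        return self.ram_ids.size

    @property
    def n_ewes(self) -> int:
        return self.ewe_ids.size


def generate_ancestral_panel(genome: GenomeMap, n_ancestral: int,
                             freq_shape: float = 0.5,
                             rng: Optional[np.random.Generator] = None,
                             seed: Optional[int] = None) -> HaplotypePanel:
    """Draw an LD-free ancestral panel.

    Per-marker allele frequencies follow a symmetric
    ``Beta(freq_shape, freq_shape)`` spectrum (the default 0.5 gives the
    U shape typical of sequenced populations after ascertainment-free
    sampling); haplotypes are then independent Bernoulli draws per marker.
    Markers monomorphic in the realized panel are resampled so every
    marker segregates.
    """
    if n_ancestral < 2:
        raise ConfigurationError("need at least two ancestral haplotypes")
    if freq_shape <= 0:
        raise ConfigurationError("freq_shape must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    m = genome.n_markers
    alleles = np.empty((n_ancestral, m), dtype=np.uint8)
    todo = np.arange(m)
    while todo.size:
        p = rng.beta(freq_shape, freq_shape, size=todo.size)
        draw = (rng.random((n_ancestral, todo.size)) < p).astype(np.uint8)
        alleles[:, todo] = draw
        counts = draw.sum(axis=0)
        todo = todo[(counts == 0) | (counts == n_ancestral)]
    return HaplotypePanel(genome, alleles)


def mosaic_copy(panel: HaplotypePanel, n_out: int, switch_rate: float = 1.0,
                mutation_rate: float = 0.0,
                rng: Optional[np.random.Generator] = None,
                seed: Optional[int] = None) -> HaplotypePanel:
    """Create ``n_out`` mosaic haplotypes from an ancestral panel.

    Each output haplotype copies one ancestral template at a time and
    switches to a uniformly chosen template at points of a Poisson
    process with rate ``switch_rate`` per Morgan.  Smaller switch rates
    give longer shared blocks and slower LD decay with distance.  An
    optional per-marker mutation rate flips alleles independently.
    """
    if panel.n_haplotypes == 0:
        raise ConfigurationError("empty ancestral panel")
    if switch_rate <= 0:
        raise ConfigurationError("switch_rate must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    genome = panel.genome
    m = genome.n_markers
    out = np.empty((n_out, m), dtype=np.uint8)
    lengths = genome.chromosome_lengths
    marker_idx = np.arange(m)
    for ci, (sl, pos) in enumerate(zip(genome.chromosome_slices,
                                       genome.positions)):
        L = lengths[ci]
        gmk = marker_idx[sl]
        k = rng.poisson(switch_rate * L, size=n_out)
        for i in range(n_out):
            tpl = rng.integers(0, panel.n_haplotypes, size=k[i] + 1)
            if k[i] == 0:
                out[i, sl] = panel.alleles[tpl[0], gmk]
            else:
                xo = np.sort(rng.uniform(0.0, L, size=k[i]))
                seg = np.searchsorted(xo, pos)
                out[i, sl] = panel.alleles[tpl[seg], gmk]
    if mutation_rate > 0:
        flips = rng.random(out.shape) < mutation_rate
        out ^= flips.astype(np.uint8)
    return HaplotypePanel(genome, out)


def build_founder_population(panel: HaplotypePanel, n_rams: int = 469,
                             n_ewes: int = 7185,
                             n_random_mating_generations: int = 5,
                             genome: Optional[GenomeMap] = None,
                             rng: Optional[np.random.Generator] = None,
                             seed: Optional[int] = None,
                             allow_replacement: bool = True,
                             start_cycle: int = 0,
                             age_sampler: Optional[Callable] = None
                             ) -> FounderPopulation:
    """Assemble the founder herdbook from a haplotype panel.

    Initial diploids are formed by pairing panel haplotypes (sampled with
    replacement when the panel is smaller than needed), then the stated
    number of discrete random-mating generations is simulated with
    recombination, recording pedigree links.  The final generation is
    produced with exactly ``n_rams`` males and ``n_ewes`` females.

    ``age_sampler(n, sex, rng) -> ages`` optionally assigns starting ages
    to the breeding cohorts (used to seed a demographically stable age
    pyramid); founders are then dated ``start_cycle - age``.
    """
    genome = genome or panel.genome
    rng = rng if rng is not None else np.random.default_rng(seed)
    n0 = n_rams + n_ewes
    need = 2 * n0
    if panel.n_haplotypes < need and not allow_replacement:
        raise ConfigurationError(
            f"panel has {panel.n_haplotypes} haplotypes; {need} needed")
    replace = panel.n_haplotypes < need
    picks = rng.choice(panel.n_haplotypes, size=(n0, 2), replace=replace)
    haps0 = panel.alleles[picks]  # (n0, 2, m)

    pop = Population(genome)
    gens = n_random_mating_generations
    # pre-founder generations are dated far enough back that every
    # founder (whatever its sampled age) is younger than its ancestors
    max_age = 15
    base_cycle = start_cycle - max_age - gens - 1

    if gens == 0:
        sex = np.concatenate([np.zeros(n_rams, np.int8) + MALE,
                              np.zeros(n_ewes, np.int8) + FEMALE])
        ids = pop.add_animals(sex, start_cycle, -np.ones(n0, np.int64),
                              -np.ones(n0, np.int64), haps0)
    else:
        n_males0 = n0 // 2
        sex0 = np.concatenate([np.full(n_males0, MALE, np.int8),
                               np.full(n0 - n_males0, FEMALE, np.int8)])
        ids = pop.add_animals(sex0, base_cycle, -np.ones(n0, np.int64),
                              -np.ones(n0, np.int64), haps0)
        for g in range(1, gens + 1):
            males = ids[pop.sex[ids] == MALE]
            females = ids[pop.sex[ids] == FEMALE]
            if g < gens:
                n_m = n0 // 2
                sex = np.concatenate([np.full(n_m, MALE, np.int8),
                                      np.full(n0 - n_m, FEMALE, np.int8)])
            else:
                sex = np.concatenate([np.full(n_rams, MALE, np.int8),
                                      np.full(n_ewes, FEMALE, np.int8)])
            sires = rng.choice(males, size=n0)
            dams = rng.choice(females, size=n0)
            pat = meiosis_batch(pop.haplotypes(sires), genome, rng)
            mat = meiosis_batch(pop.haplotypes(dams), genome, rng)
            haps = np.stack([pat, mat], axis=1)
            new_ids = pop.add_animals(sex, base_cycle + g, sires, dams, haps)
            pop.alive[ids] = False
            ids = new_ids
        pop.prune_haplotypes(ids)

    ram_ids = ids[pop.sex[ids] == MALE]
    ewe_ids = ids[pop.sex[ids] == FEMALE]
    assert ram_ids.size == n_rams and ewe_ids.size == n_ewes
    if age_sampler is not None:
        for cohort, sexname in ((ram_ids, "male"), (ewe_ids, "female")):
            ages = np.asarray(age_sampler(cohort.size, sexname, rng))
            pop.birth_cycle[cohort] = start_cycle - np.minimum(ages, max_age)
    return FounderPopulation(pop, ram_ids, ewe_ids)
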