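"""Diploid genome representation, meiosis and genome-level summaries.

The genome is a set of autosomes with marker positions given in Morgan.
Recombination follows the Haldane model: crossovers are a Poisson process
along each chromosome with no interference, and the starting parental
strand of each chromosome is chosen at random.  Alleles are biallelic and
coded 0/1; a haplotype is a ``uint8`` vector over all markers genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "GenomeMap",
    "Individual",
    "meiosis",
    "meiosis_batch",
    "mate",
    "observed_heterozygosity",
    "mean_pedigree_kinship",
]


class ConfigurationError(ValueError):
    """Raised when a genome or population configuration is inconsistent."""


@dataclass(frozen=True)
class GenomeMap:
    """Layout of markers on autosomes.

    Parameters
    ----------
    positions : list of arrays
        One strictly increasing array of genetic positions (Morgan) per
        chromosome.
    """

    positions: tuple = field(default_factory=tuple)

    def __post_init__(self):
        pos = tuple(np.asarray(p, dtype=np.float64) for p in self.positions)
        if len(pos) == 0:
            raise ConfigurationError("genome must have at least one chromosome")
        for p in pos:
            if p.size == 0:
                raise ConfigurationError("empty chromosome in genome map")
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ConfigurationError(
                    "marker positions must be strictly increasing"
                )
        object.__setattr__(self, "positions", pos)

    @classmethod
    def uniform(cls, n_chromosomes: int = 26, n_markers: int = 50_000,
                chromosome_length: float = 1.0) -> "GenomeMap":
        """Evenly spaced markers on equally sized chromosomes.

        Markers are spread as evenly as possible; the total over
        chromosomes equals ``n_markers`` exactly.
        """
        if n_chromosomes < 1 or n_markers < n_chromosomes:
            raise ConfigurationError("need at least one marker per chromosome")
        base = n_markers // n_chromosomes
        extra = n_markers % n_chromosomes
        positions = []
        for c in range(n_chromosomes):
            m = base + (1 if c < extra else 0)
            # offset by half a spacing so markers sit inside (0, L)
            step = chromosome_length / m
            positions.append((np.arange(m) + 0.5) * step)
        return cls(tuple(positions))

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def n_markers(self) -> int:
        return int(sum(p.size for p in self.positions))

    @property
    def chromosome_lengths(self) -> np.ndarray:
        """Genetic length in Morgan (span covered plus end gaps)."""
        return np.array([p[-1] + (p[0] if p.size else 0.0)
                         for p in self.positions])

    @property
    def chromosome_slices(self) -> list:
        out, start = [], 0
        for p in self.positions:
            out.append(slice(start, start + p.size))
            start += p.size
        return out

    def marker_chromosome(self) -> np.ndarray:
        """Chromosome index of every marker (genome-wide order)."""
        return np.repeat(np.arange(self.n_chromosomes),
                         [p.size for p in self.positions])


@dataclass
class Individual:
    """A single animal.

    ``haplotypes`` is a ``(2, n_markers)`` uint8 array; ``phenotypes`` is
    missing (None) until the phenotyping step of the breeding programme.
    """

    id: int
    sex: str  # "male" | "female"
    birth_cycle: int = 0
    sire_id: int = -1
    dam_id: int = -1
    haplotypes: Optional[np.ndarray] = None
    genotyped: bool = False
    phenotypes: Optional[np.ndarray] = None
    tbv: Optional[np.ndarray] = None
    alive: bool = True
    age: int = 0


def _gamete_phases(genome: GenomeMap, n: int, rng: np.random.Generator) -> np.ndarray:
    """Phase indicator (0/1 = which parental strand) per gamete and marker.

    Crossover counts per chromosome are Poisson with mean equal to the
    chromosome length in Morgan (Haldane, no interference); the strand at
    the start of each chromosome is an independent fair coin.
    """
    m = genome.n_markers
    phases = np.empty((n, m), dtype=np.uint8)
    lengths = genome.chromosome_lengths
    for ci, (sl, pos) in enumerate(zip(genome.chromosome_slices, genome.positions)):
        L = lengths[ci]
        starts = rng.integers(0, 2, size=n)
        k = rng.poisson(L, size=n)
        for i in range(n):
            if k[i] == 0:
                phases[i, sl] = starts[i]
            else:
                xo = np.sort(rng.uniform(0.0, L, size=k[i]))
                n_before = np.searchsorted(xo, pos)
                phases[i, sl] = (starts[i] + n_before) % 2
    return phases


def meiosis_batch(parent_haps: np.ndarray, genome: GenomeMap,
                  rng: np.random.Generator) -> np.ndarray:
    """Produce one gamete per parent from ``(n, 2, m)`` haplotypes."""
    parent_haps = np.asarray(parent_haps)
    n = parent_haps.shape[0]
    phases = _gamete_phases(genome, n, rng)
    rows = np.arange(n)[:, None]
    return parent_haps[rows, phases, np.arange(parent_haps.shape[2])[None, :]]


def meiosis(parent: Individual, genome: GenomeMap,
            rng: np.random.Generator) -> np.ndarray:
    """One gamete from ``parent`` under the Haldane recombination model."""
    if parent.haplotypes is None or parent.haplotypes.shape[0] != 2:
        raise ValueError("parent must carry two haplotypes")
    return meiosis_batch(parent.haplotypes[None, :, :], genome, rng)[0]


def mate(sire: Individual, dam: Individual, sex: str, birth_cycle: int,
         genome: GenomeMap, rng: np.random.Generator,
         id: int = -1) -> Individual:
    """Create an offspring of ``sire`` x ``dam``.

    The offspring receives one recombinant gamete from each parent; it is
    born ungenotyped and unphenotyped.
    """
    if sire.sex != "male" or dam.sex != "female":
        raise ValueError("sire must be male and dam female")
    if not (sire.alive and dam.alive):
        raise ValueError("both parents must be alive")
    haps = np.stack([meiosis(sire, genome, rng), meiosis(dam, genome, rng)])
    return Individual(id=id, sex=sex, birth_cycle=birth_cycle,
                      sire_id=sire.id, dam_id=dam.id, haplotypes=haps)


def observed_heterozygosity(cohort: Sequence, genome: Optional[GenomeMap] = None) -> float:
    """Mean fraction of heterozygous markers over a cohort.

    ``cohort`` may be a sequence of :class:`Individual` or a
    ``(n, 2, m)`` haplotype array.
    """
    if isinstance(cohort, np.ndarray):
        haps = cohort
        if haps.ndim != 3 or haps.shape[0] == 0:
            raise ValueError("empty cohort")
        return float(np.mean(haps[:, 0, :] != haps[:, 1, :]))
    inds = list(cohort)
    if not inds:
        raise ValueError("empty cohort")
    het = [np.mean(ind.haplotypes[0] != ind.haplotypes[1]) for ind in inds]
    return float(np.mean(het))


def mean_pedigree_kinship(cohort_ids: Iterable[int], pedigree) -> float:
    """Average pairwise pedigree kinship ``A_ij / 2`` within a cohort.

    Self-pairs are excluded.  ``pedigree`` is a
    :class:`merinosim.relationship.PedigreeTable`; the additive
    relationship values are obtained on the ancestor-restricted pedigree.
    """
    from .relationship import cohort_relationship

    ids = np.asarray(list(cohort_ids), dtype=np.int64)
    if ids.size < 2:
        raise ValueError("kinship needs at least two individuals")
    A = cohort_relationship(pedigree, ids)
    iu = np.triu_indices(ids.size, k=1)
    return float(np.mean(A[iu]) / 2.0)
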