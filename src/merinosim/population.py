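"""Array-backed population bookkeeping.

The breeding engine works on columnar arrays (one row per animal ever
born) rather than per-animal objects; haplotypes are kept in a side store
and pruned once an animal can no longer contribute (dead and outside the
genomic reference population), which bounds memory over long simulations.
Pedigree inbreeding is maintained incrementally at birth so relationship
computations never re-trace the full pedigree.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .genome import GenomeMap, Individual
from .relationship import PedigreeTable, _inbreeding_ml

MALE, FEMALE = 0, 1

__all__ = ["Population", "MALE", "FEMALE"]


class Population:
    """All animals of one simulation replicate.

    Animal ids are row indices (0-based, birth order).  ``sire``/``dam``
    are ids or -1.  ``tbv``/``phen`` are ``(n, 2)`` arrays (health,
    production); phenotypes are NaN until the phenotyping step.
    """

    def __init__(self, genome: GenomeMap):
        self.genome = genome
        self.sex = np.empty(0, dtype=np.int8)
        self.birth_cycle = np.empty(0, dtype=np.int32)
        self.sire = np.empty(0, dtype=np.int64)
        self.dam = np.empty(0, dtype=np.int64)
        self.alive = np.empty(0, dtype=bool)
        self.genotyped = np.empty(0, dtype=bool)
        self.tbv = np.empty((0, 2))
        self.phen = np.empty((0, 2))
        self.F = np.empty(0)
        self._haps: Dict[int, np.ndarray] = {}

    @property
    def n(self) -> int:
        return self.sex.size

    @property
    def phenotyped(self) -> np.ndarray:
        return ~np.isnan(self.phen[:, 0])

    # -- growth ---------------------------------------------------------
    def add_animals(self, sex, birth_cycle: int, sire, dam,
                    haplotypes: Optional[np.ndarray] = None) -> np.ndarray:
        """Append a cohort; returns the new ids (birth order)."""
        sex = np.asarray(sex, dtype=np.int8)
        k = sex.size
        start = self.n
        self.sex = np.concatenate([self.sex, sex])
        self.birth_cycle = np.concatenate(
            [self.birth_cycle, np.full(k, birth_cycle, dtype=np.int32)])
        self.sire = np.concatenate(
            [self.sire, np.asarray(sire, dtype=np.int64)])
        self.dam = np.concatenate([self.dam, np.asarray(dam, dtype=np.int64)])
        self.alive = np.concatenate([self.alive, np.ones(k, dtype=bool)])
        self.genotyped = np.concatenate(
            [self.genotyped, np.zeros(k, dtype=bool)])
        self.tbv = np.vstack([self.tbv, np.zeros((k, 2))])
        self.phen = np.vstack([self.phen, np.full((k, 2), np.nan)])
        self.F = np.concatenate([self.F, np.zeros(k)])
        _inbreeding_ml(self.sire, self.dam, self.F, start)
        ids = np.arange(start, start + k, dtype=np.int64)
        if haplotypes is not None:
            for i, hid in enumerate(ids):
                self._haps[int(hid)] = haplotypes[i]
        return ids

    # -- haplotype store ------------------------------------------------
    def haplotypes(self, ids) -> np.ndarray:
        """``(k, 2, m)`` haplotypes for animals whose genomes are retained."""
        ids = np.atleast_1d(np.asarray(ids, dtype=np.int64))
        return np.stack([self._haps[int(i)] for i in ids])

    def has_haplotypes(self, ids) -> np.ndarray:
        return np.array([int(i) in self._haps for i in np.atleast_1d(ids)])

    def genotype_dosage(self, ids) -> np.ndarray:
        """Allele-1 counts, ``(k, n_markers)`` int8."""
        haps = self.haplotypes(ids)
        return (haps[:, 0, :] + haps[:, 1, :]).astype(np.int8)

    def prune_haplotypes(self, keep_ids) -> None:
        keep = set(int(i) for i in keep_ids)
        self._haps = {i: h for i, h in self._haps.items() if i in keep}

    # -- views ----------------------------------------------------------
    def age(self, ids, cycle: int) -> np.ndarray:
        return cycle - self.birth_cycle[np.asarray(ids)]

    def individual(self, i: int, cycle: Optional[int] = None) -> Individual:
        i = int(i)
        return Individual(
            id=i,
            sex="male" if self.sex[i] == MALE else "female",
            birth_cycle=int(self.birth_cycle[i]),
            sire_id=int(self.sire[i]),
            dam_id=int(self.dam[i]),
            haplotypes=self._haps.get(i),
            genotyped=bool(self.genotyped[i]),
            phenotypes=None if np.isnan(self.phen[i, 0]) else self.phen[i].copy(),
            tbv=self.tbv[i].copy(),
            alive=bool(self.alive[i]),
            age=0 if cycle is None else int(cycle - self.birth_cycle[i]),
        )

    def pedigree_table(self) -> PedigreeTable:
        """The full recorded pedigree (ids are row indices)."""
        return PedigreeTable(np.arange(self.n, dtype=np.int64),
                             self.sire.copy(), self.dam.copy(),
                             self.birth_cycle.copy())

    # -- copying --------------------------------------------------------
    def copy(self) -> "Population":
        """Deep-enough copy for scenario branching.

        Haplotype arrays themselves are shared (they are never mutated in
        place), only the bookkeeping arrays and the store mapping are
        duplicated.
        """
        new = Population(self.genome)
        for name in ("sex", "birth_cycle", "sire", "dam", "alive",
                     "genotyped", "tbv", "phen", "F"):
            setattr(new, name, getattr(self, name).copy())
        new._haps = dict(self._haps)
        return new
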