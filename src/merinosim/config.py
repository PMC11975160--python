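"""Run configuration: defaults, validation, YAML round-trip.

The default configuration reproduces the full-size programme: a 26-
autosome, 50K-marker genome, 469 breeding rams and 7185 breeding ewes,
ten burn-in plus ten evaluated breeding cycles and 100 replicates.  A
single population scale factor shrinks every cohort for desk-scale work;
:meth:`RunConfig.desk` additionally shrinks the genome (chromosome count
roughly proportional to the scale) so that the ratio of reference-
population size to independently segregating genome segments — the
quantity genomic prediction accuracy hinges on — stays comparable to the
full-size programme.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional

import yaml

from .breeding import SCENARIOS, CohortSpec
from .evaluation import EvalConfig
from .genome import GenomeMap
from .traits import TraitParams

__all__ = ["RunConfig", "load_config", "save_config"]

_DEFAULT_SCENARIOS = list(SCENARIOS)


@dataclass
class RunConfig:
    # population
    scale: float = 1.0
    n_breeding_rams: int = 469
    n_breeding_ewes: int = 7185
    n_male_lambs: int = 6450
    n_female_lambs: int = 6465
    male_selected_prop: float = 0.02
    female_selected_prop: float = 0.20
    lambs_per_ewe: float = 1.8
    lamb_loss: float = 0.1
    litter_probs: tuple = (0.3, 0.6, 0.1)
    # genome
    n_chromosomes: int = 26
    n_markers: int = 50_000
    chromosome_length: float = 1.0
    # founder LD emulation
    n_ancestral: int = 100
    freq_shape: float = 0.5
    switch_rate: float = 1.0
    mutation_rate: float = 0.0
    n_mosaic_haplotypes: int = 1570      # 785 diploid genotype donors
    n_random_mating_generations: int = 5
    # traits
    n_qtl: int = 1000
    trait_mean: float = 100.0
    genetic_variance: float = 10.0
    h2: tuple = (0.1, 0.3)
    genetic_correlation: float = -0.1
    # programme
    n_burnin: int = 10
    n_cycles: int = 10
    window_cycles: int = 10
    pedigree_depth: int = 7
    g_blend_a22: float = 0.05
    cg_tol: float = 1e-8
    cg_maxiter: int = 5000
    # replication
    scenarios: List[str] = field(default_factory=lambda: list(_DEFAULT_SCENARIOS))
    n_runs: int = 100
    n_runs_diversity: int = 20
    base_seed: int = 1
    output_dir: str = "results"

    def __post_init__(self):
        for name in self.scenarios:
            if name not in SCENARIOS:
                raise ValueError(f"unknown scenario name {name!r}")
        for fname in ("scale", "lambs_per_ewe", "switch_rate"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be positive")
        for fname in ("lamb_loss", "mutation_rate"):
            if not 0 <= getattr(self, fname) < 1:
                raise ValueError(f"{fname} must be a rate in [0, 1)")
        if not 0 < self.male_selected_prop <= 1:
            raise ValueError("male_selected_prop must be in (0, 1]")
        if not 0 < self.female_selected_prop <= 1:
            raise ValueError("female_selected_prop must be in (0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        self.litter_probs = tuple(self.litter_probs)
        self.h2 = tuple(self.h2)
        self.cohort_spec()  # triggers CohortSpec validation

    # -- derived objects ------------------------------------------------
    def cohort_spec(self) -> CohortSpec:
        return CohortSpec.from_scale(
            self.scale,
            n_breeding_rams=self.n_breeding_rams,
            n_breeding_ewes=self.n_breeding_ewes,
            n_male_lambs=self.n_male_lambs,
            n_female_lambs=self.n_female_lambs,
            male_selected_prop=self.male_selected_prop,
            female_selected_prop=self.female_selected_prop,
            lambs_per_ewe=self.lambs_per_ewe,
            lamb_loss=self.lamb_loss,
            litter_probs=self.litter_probs,
        )

    def genome_map(self) -> GenomeMap:
        return GenomeMap.uniform(self.n_chromosomes, self.n_markers,
                                 self.chromosome_length)

    def trait_params(self) -> TraitParams:
        return TraitParams(self.n_qtl, self.trait_mean,
                           self.genetic_variance, self.h2,
                           self.genetic_correlation)

    def eval_config(self) -> EvalConfig:
        return EvalConfig(self.window_cycles, self.pedigree_depth,
                          self.g_blend_a22, self.cg_tol, self.cg_maxiter)

    # -- desk scaling ---------------------------------------------------
    @classmethod
    def desk(cls, scale: float = 0.1, n_markers: int = 2000,
             n_runs: int = 20, **kw) -> "RunConfig":
        """Desk-scale configuration.

        Cohort sizes shrink by ``scale``; the genome shrinks to
        ``max(2, round(26 * scale))`` chromosomes so the accuracy of the
        genomic evaluation behaves like the full-size programme despite
        the smaller reference population.
        """
        kw.setdefault("n_chromosomes", max(2, round(26 * scale)))
        kw.setdefault("n_runs_diversity", n_runs)
        # QTL are drawn from the marker panel; cap at half the panel so
        # the architecture stays polygenic on small desk genomes
        kw.setdefault("n_qtl", min(1000, n_markers // 2))
        return cls(scale=scale, n_markers=n_markers, n_runs=n_runs, **kw)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["litter_probs"] = list(self.litter_probs)
        d["h2"] = list(self.h2)
        return d

    @classmethod
    def from_dict(cls, d: Optional[dict]) -> "RunConfig":
        d = dict(d or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    """Load a YAML config; an empty file yields the full default setup."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
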