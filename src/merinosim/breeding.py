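"""One cycle of the herdbook breeding programme.

A breeding cycle follows the programme's annual rhythm: lambing, genetic
evaluation, optional two-stage preselection with genotyping, truncation
selection of new breeding rams (2% of male lambs) and ewes (20% of female
lambs) on an equal-weight total merit index, phenotyping of the selected
animals, and age-dependent replacement of the standing breeding cohorts,
whose sizes stay constant throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional

import numpy as np

from .evaluation import EvalConfig, VarianceComponents, ebv_accuracy, evaluate
from .population import FEMALE, MALE, Population
from .traits import TraitArchitecture, assign_tbv, draw_phenotypes

__all__ = [
    "CohortSpec", "ScenarioConfig", "PopulationState", "SCENARIOS",
    "scenario", "stationary_ages", "produce_lambs", "preselect",
    "select_new_breeders", "cull_and_replace", "run_cycle", "CycleRecord",
]


def _scaled(base: int, scale: float) -> int:
    return int(round(base * scale))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes and demographic rates of the programme.

    Defaults reproduce the full-size herdbook (469 rams, 7185 ewes, 2% /
    20% selected).  ``from_scale`` shrinks every cohort by a global
    factor while holding the selection proportions fixed.  Lamb cohort
    sizes are primary: litters are resampled/truncated so that the 2%
    and 20% selected fractions yield the stated numbers of new breeders
    exactly.
    """

    n_breeding_rams: int = 469
    n_breeding_ewes: int = 7185
    n_male_lambs: int = 6450
    n_female_lambs: int = 6465
    male_selected_prop: float = 0.02
    female_selected_prop: float = 0.20
    lambs_per_ewe: float = 1.8
    lamb_loss: float = 0.1
    litter_probs: tuple = (0.3, 0.6, 0.1)
    culling_weight: Callable = field(default=None, repr=False)

    def __post_init__(self):
        if self.culling_weight is None:
            object.__setattr__(self, "culling_weight",
                               lambda age: age.astype(float) ** 2)
        probs = np.asarray(self.litter_probs)
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("litter probabilities must sum to one")

    @classmethod
    def from_scale(cls, scale: float = 1.0, **kw) -> "CohortSpec":
        base = cls(**kw) if kw else cls()
        return replace(
            base,
            n_breeding_rams=_scaled(base.n_breeding_rams, scale),
            n_breeding_ewes=_scaled(base.n_breeding_ewes, scale),
            n_male_lambs=_scaled(base.n_male_lambs, scale),
            n_female_lambs=_scaled(base.n_female_lambs, scale),
        )

    @property
    def n_new_rams(self) -> int:
        return int(round(self.male_selected_prop * self.n_male_lambs))

    @property
    def n_new_ewes(self) -> int:
        return int(round(self.female_selected_prop * self.n_female_lambs))

    @property
    def mean_litter(self) -> float:
        return float(np.dot([1, 2, 3], self.litter_probs))


@dataclass(frozen=True)
class ScenarioConfig:
    """A genotyping/selection strategy.

    ``male_genotyping_prop``/``female_genotyping_prop`` give the share of
    the lamb cohort genotyped per cycle; a share strictly between 0 and 1
    implies EBV-based preselection of the lambs to genotype.
    """

    name: str
    method: str                       # "PBLUP" | "ssGBLUP"
    male_genotyping_prop: float = 0.0
    female_genotyping_prop: float = 0.0

    def __post_init__(self):
        if self.method not in ("PBLUP", "ssGBLUP"):
            raise ValueError(f"unknown evaluation method {self.method!r}")
        if self.method == "PBLUP" and (self.male_genotyping_prop
                                       or self.female_genotyping_prop):
            raise ValueError("PBLUP scenarios cannot genotype lambs")

    @property
    def preselects_males(self) -> bool:
        return 0.0 < self.male_genotyping_prop < 1.0

    @property
    def preselects_females(self) -> bool:
        return 0.0 < self.female_genotyping_prop < 1.0


SCENARIOS: Dict[str, ScenarioConfig] = {
    "Ped": ScenarioConfig("Ped", "PBLUP", 0.0, 0.0),
    "GSTop25": ScenarioConfig("GSTop25", "ssGBLUP", 0.25, 0.0),
    "GSTop50": ScenarioConfig("GSTop50", "ssGBLUP", 0.50, 0.0),
    "GS100": ScenarioConfig("GS100", "ssGBLUP", 1.0, 0.0),
    "GS100+Top25": ScenarioConfig("GS100+Top25", "ssGBLUP", 1.0, 0.25),
    "GS100+Top50": ScenarioConfig("GS100+Top50", "ssGBLUP", 1.0, 0.50),
    "GS100+100": ScenarioConfig("GS100+100", "ssGBLUP", 1.0, 1.0),
}


def scenario(name: str) -> ScenarioConfig:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of "
            f"{sorted(SCENARIOS)}") from None


@dataclass
class PopulationState:
    """Mutable state carried across breeding cycles."""

    population: Population
    breeding_rams: np.ndarray
    breeding_ewes: np.ndarray
    reference_ids: np.ndarray
    cycle: int = 0

    def copy(self) -> "PopulationState":
        return PopulationState(self.population.copy(),
                               self.breeding_rams.copy(),
                               self.breeding_ewes.copy(),
                               self.reference_ids.copy(), self.cycle)

    def genotype_breeding_rams(self) -> None:
        """Initial genomic reference: all active breeding rams."""
        self.population.genotyped[self.breeding_rams] = True
        self.reference_ids = np.unique(
            np.concatenate([self.reference_ids, self.breeding_rams]))


def stationary_ages(n: int, n_replace: int,
                    rng: np.random.Generator,
                    weight: Optional[Callable] = None,
                    n_iter: int = 80) -> np.ndarray:
    """Sample ages from the stationary distribution of the culling model.

    Simulates the age process alone (replace ``n_replace`` animals per
    cycle, culled with probability proportional to ``weight(age)``) until
    the age pyramid stabilizes; used to give founder cohorts a
    demographically stable starting structure.
    """
    if weight is None:
        weight = lambda age: age.astype(float) ** 2
    ages = np.ones(n, dtype=np.int64)
    for _ in range(n_iter):
        w = np.asarray(weight(ages), dtype=float)
        p = np.full(n, 1.0 / n) if w.sum() <= 0 else w / w.sum()
        culled = rng.choice(n, size=n_replace, replace=False, p=p)
        ages[culled] = 0
        ages += 1
    return ages


def produce_lambs(state: PopulationState, spec: CohortSpec,
                  arch: Optional[TraitArchitecture],
                  rng: np.random.Generator):
    """Mate the breeding cohorts and return (male_ids, female_ids).

    Every ewe is assigned one ram uniformly at random (ram reuse
    allowed); litter sizes come from ``spec.litter_probs`` (mean 1.8) and
    each lamb survives the pre-selection stage with probability
    ``1 - lamb_loss``.  Surviving lambs are then truncated or padded by
    resampling ewe/ram pairs so that the lamb cohorts have exactly the
    configured sizes.
    """
    pop = state.population
    rams, ewes = state.breeding_rams, state.breeding_ewes
    if rams.size == 0 or ewes.size == 0:
        raise ValueError("empty breeding cohorts")
    cycle = state.cycle + 1
    assigned = rng.choice(rams, size=ewes.size, replace=True)
    litter = rng.choice(np.array([1, 2, 3]), size=ewes.size,
                        p=np.asarray(spec.litter_probs))
    dam = np.repeat(ewes, litter)
    sire = np.repeat(assigned, litter)
    survive = rng.random(dam.size) < (1.0 - spec.lamb_loss)
    dam, sire = dam[survive], sire[survive]
    sex = rng.integers(0, 2, size=dam.size).astype(np.int8)

    parts = []
    for s, target in ((MALE, spec.n_male_lambs), (FEMALE, spec.n_female_lambs)):
        idx = np.flatnonzero(sex == s)
        if idx.size >= target:
            idx = rng.choice(idx, size=target, replace=False)
            parts.append((sire[idx], dam[idx]))
        else:
            extra = target - idx.size
            j = rng.integers(0, ewes.size, size=extra)
            parts.append((np.concatenate([sire[idx], assigned[j]]),
                          np.concatenate([dam[idx], ewes[j]])))
    sires = np.concatenate([p[0] for p in parts])
    dams = np.concatenate([p[1] for p in parts])
    sexes = np.concatenate([np.full(spec.n_male_lambs, MALE, np.int8),
                            np.full(spec.n_female_lambs, FEMALE, np.int8)])

    from .genome import meiosis_batch
    pat = meiosis_batch(pop.haplotypes(sires), pop.genome, rng)
    mat = meiosis_batch(pop.haplotypes(dams), pop.genome, rng)
    haps = np.stack([pat, mat], axis=1)
    ids = pop.add_animals(sexes, cycle, sires, dams, haps)
    if arch is not None:
        assign_tbv(pop, ids, arch)
    return ids[:spec.n_male_lambs], ids[spec.n_male_lambs:]


def _top_by_tmi(ids: np.ndarray, tmi_values: np.ndarray, k: int) -> np.ndarray:
    """Top-k by TMI, ties broken by id order (deterministic)."""
    order = np.lexsort((ids, -tmi_values))
    return ids[order[:k]]


def preselect(ids, tmi_values, proportion: float) -> np.ndarray:
    """First-stage ranking: top ``ceil(p * n)`` lambs by TMI."""
    if not 0.0 < proportion <= 1.0:
        raise ValueError("preselection proportion must be in (0, 1]")
    ids = np.asarray(ids)
    if proportion == 1.0:
        return ids.copy()
    k = math.ceil(proportion * ids.size)
    return _top_by_tmi(ids, np.asarray(tmi_values), k)


def select_new_breeders(ids, tmi_values, n_select: int) -> np.ndarray:
    """Truncation selection of the new breeder cohort."""
    ids = np.asarray(ids)
    if n_select > ids.size:
        raise ValueError(
            f"cannot select {n_select} from {ids.size} candidates")
    return _top_by_tmi(ids, np.asarray(tmi_values), n_select)


def cull_and_replace(state: PopulationState, spec: CohortSpec,
                     new_rams: np.ndarray, new_ewes: np.ndarray,
                     rng: np.random.Generator) -> None:
    """Age-weighted culling of old breeders, replacement by new ones.

    Exactly as many breeders are removed as enter, keeping cohort sizes
    constant; culling probability is proportional to ``weight(age)``
    (default age^2, which preferentially removes old animals).
    """
    pop = state.population
    cycle = state.cycle + 1
    for attr, new in (("breeding_rams", new_rams), ("breeding_ewes", new_ewes)):
        cohort = getattr(state, attr)
        k = new.size
        ages = pop.age(cohort, cycle)
        w = np.asarray(spec.culling_weight(ages), dtype=float)
        p = np.full(cohort.size, 1.0 / cohort.size) if w.sum() <= 0 \
            else w / w.sum()
        culled = rng.choice(cohort, size=k, replace=False, p=p)
        pop.alive[culled] = False
        keep = cohort[~np.isin(cohort, culled)]
        setattr(state, attr, np.concatenate([keep, new]))


@dataclass
class CycleRecord:
    """Per-cycle metrics snapshot."""

    cycle: int
    scenario: str
    n_evaluations: int
    n_genotyped_reference: int
    mean_tbv: Dict[str, np.ndarray]
    accuracy: Dict[str, np.ndarray]
    cohorts: Dict[str, np.ndarray]


def run_cycle(state: PopulationState, scen: ScenarioConfig,
              spec: CohortSpec, arch: TraitArchitecture,
              vc: VarianceComponents, streams: Dict[str, np.random.Generator],
              eval_config: EvalConfig = EvalConfig()) -> CycleRecord:
    """Advance the population by one breeding cycle under a scenario.

    Sequence: lambing -> (preselection evaluation, if only part of a lamb
    cohort is genotyped) -> genotyping -> final evaluation -> truncation
    selection -> phenotyping of new breeders -> reference-population
    growth -> age-based culling and replacement.  Scenarios without a
    preselection step (Ped, GS100, GS100+100) perform a single
    evaluation per cycle.
    """
    pop = state.population
    cycle = state.cycle + 1
    male_ids, female_ids = produce_lambs(state, spec, arch, streams["repro"])
    lamb_ids = np.concatenate([male_ids, female_ids])

    presel_m, presel_f = male_ids, female_ids
    n_evals = 0
    if scen.preselects_males or scen.preselects_females:
        res1 = evaluate(pop, cycle, lamb_ids, state.reference_ids, vc,
                        scen.method, eval_config)
        n_evals += 1
        if scen.preselects_males:
            presel_m = preselect(male_ids, res1.tmi_of(male_ids),
                                 scen.male_genotyping_prop)
        if scen.preselects_females:
            presel_f = preselect(female_ids, res1.tmi_of(female_ids),
                                 scen.female_genotyping_prop)

    if scen.male_genotyping_prop > 0:
        pop.genotyped[presel_m] = True
    if scen.female_genotyping_prop > 0:
        pop.genotyped[presel_f] = True

    res = evaluate(pop, cycle, lamb_ids, state.reference_ids, vc,
                   scen.method, eval_config)
    n_evals += 1

    pool_m = presel_m if scen.male_genotyping_prop > 0 else male_ids
    pool_f = presel_f if scen.female_genotyping_prop > 0 else female_ids
    new_rams = select_new_breeders(pool_m, res.tmi_of(pool_m),
                                   spec.n_new_rams)
    new_ewes = select_new_breeders(pool_f, res.tmi_of(pool_f),
                                   spec.n_new_ewes)
    new_breeders = np.concatenate([new_rams, new_ewes])
    draw_phenotypes(pop, new_breeders, arch, streams["phen"])

    # reference population grows by the selected genotyped animals only
    entering = new_breeders[pop.genotyped[new_breeders]]
    if entering.size:
        state.reference_ids = np.concatenate([state.reference_ids, entering])

    # unselected lambs leave the programme; their genotypes are dropped
    unselected = lamb_ids[~np.isin(lamb_ids, new_breeders)]
    pop.alive[unselected] = False
    pop.genotyped[unselected] = False

    cull_and_replace(state, spec, new_rams, new_ewes, streams["cull"])
    state.cycle = cycle
    keep = np.concatenate([np.flatnonzero(pop.alive), state.reference_ids])
    pop.prune_haplotypes(np.unique(keep))

    cohorts = {
        "male_lambs": male_ids,
        "female_lambs": female_ids,
        "new_breeding_rams": new_rams,
        "new_breeding_ewes": new_ewes,
        "breeding_rams": state.breeding_rams,
        "breeding_ewes": state.breeding_ewes,
    }
    mean_tbv = {k: pop.tbv[v].mean(axis=0) for k, v in cohorts.items()}
    accuracy = {k: ebv_accuracy(res, v, pop.tbv[v]) for k, v in cohorts.items()}
    return CycleRecord(cycle, scen.name, n_evals, state.reference_ids.size,
                       mean_tbv, accuracy, cohorts)
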