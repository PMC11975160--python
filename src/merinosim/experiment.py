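"""Replicated scenario comparison with common random numbers.

For every replicate one founder population plus a ten-cycle burn-in under
pedigree-BLUP selection is simulated; each scenario then continues from
an identical copy of that cycle-0 state, with the demographic random
streams (mating, litters, meiosis, residuals, culling) keyed by replicate
and cycle only — not by scenario — so scenario contrasts are paired.
Genetic gain is reported in genetic standard deviations, zeroed at the
cycle-0 cohort means; diversity metrics (pedigree kinship and observed
heterozygosity of the breeding ram cohort) are tracked on a subset of
replicates.
"""

from __future__ import annotations

import logging
import string
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .breeding import (PopulationState, SCENARIOS, ScenarioConfig,
                       run_cycle, scenario, stationary_ages)
from .config import RunConfig
from .evaluation import VarianceComponents
from .founders import (build_founder_population, generate_ancestral_panel,
                       mosaic_copy)
from .genome import mean_pedigree_kinship, observed_heterozygosity
from .traits import assign_tbv, draw_phenotypes, sample_architecture

log = logging.getLogger(__name__)

__all__ = ["run_experiment", "run_replicate", "gain_table",
           "accuracy_table", "paired_tests", "relative_gain",
           "letter_groups"]

# spawn-key phase codes: 0 = founder setup, 1 = burn-in, 2 = scenario cycles
_PURPOSES = {"repro": 0, "phen": 1, "cull": 2}


def _rng(base_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(base_seed, spawn_key=tuple(key)))


def _cycle_streams(base_seed: int, run: int, phase: int, cycle: int
                   ) -> Dict[str, np.random.Generator]:
    return {name: _rng(base_seed, run, phase, cycle + 1000, code)
            for name, code in _PURPOSES.items()}


def _init_state(config: RunConfig, run: int, base_seed: int
                ) -> tuple:
    """Founders, trait architecture and phenotyped starting cohorts."""
    genome = config.genome_map()
    spec = config.cohort_spec()
    panel = generate_ancestral_panel(genome, config.n_ancestral,
                                     config.freq_shape,
                                     rng=_rng(base_seed, run, 0, 0))
    mosaic = mosaic_copy(panel, config.n_mosaic_haplotypes,
                         config.switch_rate, config.mutation_rate,
                         rng=_rng(base_seed, run, 0, 1))

    frac = {"male": spec.n_new_rams / spec.n_breeding_rams,
            "female": spec.n_new_ewes / spec.n_breeding_ewes}

    def age_sampler(n, sexname, rng):
        return stationary_ages(n, max(1, int(round(frac[sexname] * n))), rng,
                               weight=spec.culling_weight)

    founders = build_founder_population(
        mosaic, spec.n_breeding_rams, spec.n_breeding_ewes,
        config.n_random_mating_generations, genome,
        rng=_rng(base_seed, run, 0, 2), start_cycle=-config.n_burnin,
        age_sampler=age_sampler)
    pop = founders.population
    founder_ids = np.concatenate([founders.ram_ids, founders.ewe_ids])
    arch = sample_architecture(genome, pop, founder_ids,
                               config.trait_params(),
                               rng=_rng(base_seed, run, 0, 3))
    assign_tbv(pop, founder_ids, arch)
    draw_phenotypes(pop, founder_ids, arch, _rng(base_seed, run, 0, 4))
    state = PopulationState(pop, founders.ram_ids.copy(),
                            founders.ewe_ids.copy(),
                            np.empty(0, dtype=np.int64),
                            cycle=-config.n_burnin)
    return state, arch


def run_replicate(config: RunConfig, run: int,
                  scenarios: Iterable[ScenarioConfig],
                  base_seed: int, diversity: bool = False) -> List[dict]:
    """One founder + burn-in replicate, all scenarios from its cycle 0."""
    spec = config.cohort_spec()
    ec = config.eval_config()
    state, arch = _init_state(config, run, base_seed)
    vc = VarianceComponents.from_params(arch.params)
    ped_scenario = SCENARIOS["Ped"]
    for c in range(config.n_burnin):
        run_cycle(state, ped_scenario, spec, arch, vc,
                  _cycle_streams(base_seed, run, 1, state.cycle + 1), ec)
    assert state.cycle == 0

    rows: List[dict] = []
    gsd = arch.params.gsd
    base_mean = {
        "breeding_rams": state.population.tbv[state.breeding_rams].mean(0),
        "breeding_ewes": state.population.tbv[state.breeding_ewes].mean(0),
    }

    def emit(scen_name, cycle, cohort, mean_tbv, acc, kin, het, n_geno):
        for t, trait in enumerate(("health", "production")):
            gain = np.nan
            if cohort in base_mean:
                gain = (mean_tbv[t] - base_mean[cohort][t]) / gsd
            rows.append(dict(
                run=run, scenario=scen_name, cycle=cycle, cohort=cohort,
                trait=trait, mean_tbv=mean_tbv[t], gain_gsd=gain,
                accuracy=np.nan if acc is None else acc[t],
                kinship=kin, heterozygosity=het, n_genotyped=n_geno))

    def diversity_metrics(st):
        if not diversity:
            return (np.nan, np.nan)
        rams = st.breeding_rams
        kin = mean_pedigree_kinship(rams, st.population.pedigree_table())
        het = observed_heterozygosity(st.population.haplotypes(rams))
        return kin, het

    kin0, het0 = diversity_metrics(state)
    for scen in scenarios:
        st = state.copy()
        if scen.method == "ssGBLUP":
            st.genotype_breeding_rams()
        for cohort in ("breeding_rams", "breeding_ewes"):
            ids = getattr(st, cohort)
            emit(scen.name, 0, cohort, st.population.tbv[ids].mean(0),
                 None, kin0, het0, st.reference_ids.size)
        for c in range(1, config.n_cycles + 1):
            rec = run_cycle(st, scen, spec, arch, vc,
                            _cycle_streams(base_seed, run, 2, c), ec)
            kin, het = diversity_metrics(st)
            for cohort in rec.mean_tbv:
                emit(scen.name, c, cohort, rec.mean_tbv[cohort],
                     rec.accuracy[cohort],
                     kin if cohort == "breeding_rams" else np.nan,
                     het if cohort == "breeding_rams" else np.nan,
                     rec.n_genotyped_reference)
        log.info("run %d scenario %s done (cycle %d)", run, scen.name,
                 st.cycle)
    return rows


def run_experiment(config: RunConfig,
                   scenarios: Optional[Iterable] = None,
                   n_runs: Optional[int] = None,
                   base_seed: Optional[int] = None,
                   progress: bool = False) -> pd.DataFrame:
    """Run the replicated scenario comparison; returns the metrics trace.

    The trace has one row per (run, scenario, cycle, cohort, trait) with
    columns ``mean_tbv``, ``gain_gsd``, ``accuracy`` and, for the
    breeding ram cohort on the diversity subset of runs, ``kinship`` and
    ``heterozygosity``.
    """
    if scenarios is None:
        scenarios = config.scenarios
    scen_list = [scenario(s) if isinstance(s, str) else s for s in scenarios]
    if not scen_list:
        raise ValueError("scenario list is empty")
    n_runs = config.n_runs if n_runs is None else n_runs
    base_seed = config.base_seed if base_seed is None else base_seed
    rows: List[dict] = []
    for run in range(n_runs):
        diversity = run < min(n_runs, config.n_runs_diversity)
        rows.extend(run_replicate(config, run, scen_list, base_seed,
                                  diversity=diversity))
        if progress:
            print(f"replicate {run + 1}/{n_runs} complete", flush=True)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Summaries
# ----------------------------------------------------------------------

def _paired_pvalue(diff: np.ndarray) -> float:
    if np.allclose(diff.std(ddof=1) if diff.size > 1 else 0.0, 0.0):
        return 1.0 if np.allclose(diff, 0.0) else 0.0
    return float(stats.ttest_rel(diff, np.zeros_like(diff)).pvalue)


def paired_tests(trace: pd.DataFrame, metric: str = "gain_gsd",
                 cycle: int = 10, cohort: str = "breeding_rams",
                 trait: str = "health", alpha: float = 0.05):
    """All pairwise paired t-tests between scenarios at one cycle.

    Runs are paired through the shared replicate seeds.  Returns
    ``(pvalues, letters)``: a scenario-by-scenario p-value DataFrame and
    a compact letter display where two scenarios share a letter iff they
    are not significantly different at ``alpha``.
    """
    sub = trace[(trace.cycle == cycle) & (trace.cohort == cohort)
                & (trace.trait == trait)]
    pivot = sub.pivot_table(index="run", columns="scenario", values=metric)
    if pivot.isna().any().any():
        raise ValueError("traces are not paired across scenarios")
    if len(pivot) < 2:
        raise ValueError("paired tests need at least two runs")
    names = list(pivot.columns)
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                     columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pv = _paired_pvalue(pivot[a].values - pivot[b].values)
            p.loc[a, b] = p.loc[b, a] = pv
    letters = letter_groups(p, pivot.mean(), alpha)
    return p, letters


def letter_groups(pvalues: pd.DataFrame, means: pd.Series,
                  alpha: float = 0.05) -> Dict[str, str]:
    """Compact letter display from a pairwise p-value matrix.

    Letters label maximal cliques of the non-significance graph, ordered
    by clique mean, so any two scenarios share a letter iff their paired
    difference is not significant.
    """
    import networkx as nx

    names = list(pvalues.index)
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if pvalues.loc[a, b] >= alpha:
                g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g),
                     key=lambda c: float(np.mean([means[x] for x in c])))
    assigned: Dict[str, str] = {n: "" for n in names}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for n in clique:
            assigned[n] += letter
    return assigned


def gain_table(trace: pd.DataFrame, cycle: int = 10,
               with_letters: bool = True) -> pd.DataFrame:
    """Cycle-10 genetic gain (gSD) per scenario, cohort and trait."""
    return _summary_table(trace, "gain_gsd", cycle,
                          ("breeding_rams", "breeding_ewes"), with_letters)


def accuracy_table(trace: pd.DataFrame, cycle: int = 10,
                   with_letters: bool = True) -> pd.DataFrame:
    """Cycle-10 EBV accuracy per scenario, cohort and trait."""
    return _summary_table(
        trace, "accuracy", cycle,
        ("male_lambs", "breeding_rams", "female_lambs", "breeding_ewes"),
        with_letters)


def _summary_table(trace, metric, cycle, cohorts, with_letters):
    sub = trace[(trace.cycle == cycle) & trace.cohort.isin(cohorts)]
    n_runs = sub.run.nunique()
    out = (sub.groupby(["scenario", "cohort", "trait"])[metric]
           .agg(["mean", "std"]).reset_index())
    if n_runs < 2:
        out["std"] = np.nan
    if with_letters and n_runs >= 2:
        letters = []
        for _, row in out.iterrows():
            _, lg = paired_tests(trace, metric, cycle, row.cohort, row.trait)
            letters.append(lg[row.scenario])
        out["letters"] = letters
    return out


def relative_gain(trace: pd.DataFrame, scen_name: str, reference: str,
                  cohort: str = "breeding_rams", trait: str = "health",
                  cycle: int = 10) -> float:
    """Percent increase of mean cycle-``cycle`` gain over a reference."""
    def mean_gain(name):
        sub = trace[(trace.scenario == name) & (trace.cycle == cycle)
                    & (trace.cohort == cohort) & (trace.trait == trait)]
        if sub.empty:
            raise ValueError(f"scenario {name!r} not in trace")
        return sub.gain_gsd.mean()

    ref = mean_gain(reference)
    if ref <= 0:
        raise ValueError("reference scenario has non-positive mean gain")
    return 100.0 * (mean_gain(scen_name) - ref) / ref
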