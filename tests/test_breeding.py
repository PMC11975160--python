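"""Breeding-cycle mechanics: lambing, selection, culling, invariants."""

import numpy as np
import pytest

from merinosim.breeding import (CohortSpec, PopulationState, SCENARIOS,
                                cull_and_replace, preselect, produce_lambs,
                                run_cycle, scenario, select_new_breeders,
                                stationary_ages)
from merinosim.evaluation import VarianceComponents
from merinosim.population import FEMALE, MALE
from merinosim.traits import TraitParams, assign_tbv, draw_phenotypes, \
    sample_architecture


@pytest.fixture(scope="module")
def tiny_spec():
    # 12 rams / 48 ewes, lamb cohorts 43/43, 2% -> 1 ram, 20% -> 9 ewes
    return CohortSpec(n_breeding_rams=12, n_breeding_ewes=48,
                      n_male_lambs=43, n_female_lambs=43)


def make_state(small_founders, seed=0):
    f = small_founders
    pop = f.population.copy()
    pop.birth_cycle[np.concatenate([f.ram_ids, f.ewe_ids])] = -1
    return PopulationState(pop, f.ram_ids.copy(), f.ewe_ids.copy(),
                           np.empty(0, dtype=np.int64), cycle=0)


@pytest.fixture
def ready_state(small_founders):
    state = make_state(small_founders)
    ids = np.concatenate([state.breeding_rams, state.breeding_ewes])
    arch = sample_architecture(state.population.genome, state.population,
                               ids, TraitParams(n_qtl=50), seed=9)
    assign_tbv(state.population, ids, arch)
    state.population.phen[:] = np.nan
    draw_phenotypes(state.population, ids, arch, np.random.default_rng(1))
    return state, arch


class TestCohortSpec:
    def test_full_scale_counts(self):
        spec = CohortSpec()
        assert spec.n_new_rams == 129       # 2% of 6450
        assert spec.n_new_ewes == 1293      # 20% of 6465
        assert spec.mean_litter == pytest.approx(1.8)
        # expected surviving lambs per ewe
        assert spec.mean_litter * (1 - spec.lamb_loss) == pytest.approx(1.62)

    def test_scaling_keeps_proportions(self):
        spec = CohortSpec.from_scale(0.1)
        assert spec.n_breeding_rams == 47
        assert spec.n_new_rams == round(0.02 * spec.n_male_lambs)

    def test_scenario_table(self):
        assert SCENARIOS["Ped"].method == "PBLUP"
        assert SCENARIOS["GSTop25"].male_genotyping_prop == 0.25
        assert SCENARIOS["GS100+100"].female_genotyping_prop == 1.0
        assert SCENARIOS["GS100"].preselects_males is False
        with pytest.raises(ValueError):
            scenario("GSTop75")


class TestProduceLambs:
    def test_exact_cohort_sizes_and_parents(self, ready_state, tiny_spec):
        state, arch = ready_state
        males, females = produce_lambs(state, tiny_spec, arch,
                                       np.random.default_rng(2))
        pop = state.population
        assert males.size == tiny_spec.n_male_lambs
        assert females.size == tiny_spec.n_female_lambs
        lambs = np.concatenate([males, females])
        assert np.all(np.isin(pop.sire[lambs], state.breeding_rams))
        assert np.all(np.isin(pop.dam[lambs], state.breeding_ewes))
        assert np.all(pop.sex[males] == MALE)
        assert np.all(pop.sex[females] == FEMALE)
        assert np.all(np.isnan(pop.phen[lambs]))  # no lamb phenotypes


class TestSelection:
    def test_preselect_ceiling_and_ties(self):
        ids = np.arange(20)
        tmi = np.zeros(20)
        top = preselect(ids, tmi, 0.25)
        assert np.array_equal(top, np.arange(5))  # ceil(5), tie by id
        assert preselect(ids, tmi, 1.0).size == 20
        with pytest.raises(ValueError):
            preselect(ids, tmi, 0.0)

    def test_preselect_takes_top_tmi(self):
        rng = np.random.default_rng(0)
        ids = np.arange(100)
        tmi = rng.standard_normal(100)
        top = preselect(ids, tmi, 0.25)
        assert set(top) == set(ids[np.argsort(-tmi)[:25]])

    def test_truncation_optimality(self):
        rng = np.random.default_rng(1)
        ids = np.arange(50)
        tmi = rng.standard_normal(50)
        sel = select_new_breeders(ids, tmi, 10)
        best = np.sort(tmi)[-10:].mean()
        assert tmi[sel].mean() == pytest.approx(best)
        with pytest.raises(ValueError):
            select_new_breeders(ids, tmi, 51)


class TestCulling:
    def test_stationary_age_distribution(self):
        ages = stationary_ages(500, 100, np.random.default_rng(0))
        assert ages.min() >= 1
        # 20% replacement: mean tenure ~ a few cycles, right-skewed
        assert 2.0 < ages.mean() < 6.0

    def test_age_weighted_culling_prefers_old(self, ready_state, tiny_spec):
        state, arch = ready_state
        rng = np.random.default_rng(3)
        males, _ = produce_lambs(state.copy(), tiny_spec, arch, rng)
        culled_ages, survivor_ages = [], []
        for rep in range(1000):
            st = state.copy()
            st.population.birth_cycle[st.breeding_rams] = \
                -rng.integers(1, 8, st.breeding_rams.size)
            old = st.breeding_rams.copy()
            cull_and_replace(st, tiny_spec, males[:3],
                             np.array([], dtype=np.int64), rng)
            culled = old[~np.isin(old, st.breeding_rams)]
            keep = old[np.isin(old, st.breeding_rams)]
            culled_ages.append(st.population.age(culled, 1).mean())
            survivor_ages.append(st.population.age(keep, 1).mean())
        assert np.mean(culled_ages) > np.mean(survivor_ages)

    def test_cohort_sizes_constant(self, ready_state, tiny_spec):
        state, arch = ready_state
        st = state.copy()
        rng = np.random.default_rng(4)
        males, females = produce_lambs(st, tiny_spec, arch, rng)
        new_rams = males[:tiny_spec.n_new_rams]
        new_ewes = females[:tiny_spec.n_new_ewes]
        cull_and_replace(st, tiny_spec, new_rams, new_ewes, rng)
        assert st.breeding_rams.size == tiny_spec.n_breeding_rams
        assert st.breeding_ewes.size == tiny_spec.n_breeding_ewes
        assert np.all(np.isin(new_rams, st.breeding_rams))


class TestRunCycle:
    @pytest.mark.parametrize("name,n_evals", [
        ("Ped", 1), ("GS100", 1), ("GS100+100", 1),
        ("GSTop25", 2), ("GS100+Top50", 2),
    ])
    def test_evaluation_count_per_scenario(self, ready_state, tiny_spec,
                                           name, n_evals):
        state, arch = ready_state
        st = state.copy()
        scen = scenario(name)
        if scen.method == "ssGBLUP":
            st.genotype_breeding_rams()
        vc = VarianceComponents.from_params(arch.params)
        streams = {k: np.random.default_rng(i)
                   for i, k in enumerate(("repro", "phen", "cull"))}
        rec = run_cycle(st, scen, tiny_spec, arch, vc, streams)
        assert rec.n_evaluations == n_evals
        assert st.breeding_rams.size == tiny_spec.n_breeding_rams
        assert st.breeding_ewes.size == tiny_spec.n_breeding_ewes

    def test_reference_population_growth(self, ready_state, tiny_spec):
        # male-genotyping scenario: reference grows by n_new_rams per cycle
        state, arch = ready_state
        st = state.copy()
        st.genotype_breeding_rams()
        n0 = st.reference_ids.size
        vc = VarianceComponents.from_params(arch.params)
        scen = scenario("GS100")
        for c in range(3):
            streams = {k: np.random.default_rng(10 * c + i)
                       for i, k in enumerate(("repro", "phen", "cull"))}
            run_cycle(st, scen, tiny_spec, arch, vc, streams)
        assert st.reference_ids.size == n0 + 3 * tiny_spec.n_new_rams
        pop = st.population
        # reference animals are genotyped and phenotyped
        assert np.all(pop.genotyped[st.reference_ids])
        assert np.all(~np.isnan(pop.phen[st.reference_ids, 0]))

    def test_no_phenotype_before_breeder_entry(self, ready_state, tiny_spec):
        state, arch = ready_state
        st = state.copy()
        vc = VarianceComponents.from_params(arch.params)
        streams = {k: np.random.default_rng(20 + i)
                   for i, k in enumerate(("repro", "phen", "cull"))}
        rec = run_cycle(st, scenario("Ped"), tiny_spec, arch, vc, streams)
        pop = st.population
        males = rec.cohorts["male_lambs"]
        unselected = males[~np.isin(males, rec.cohorts["new_breeding_rams"])]
        assert np.all(np.isnan(pop.phen[unselected]))
        assert np.all(~np.isnan(
            pop.phen[rec.cohorts["new_breeding_rams"], 0]))
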