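import math

import numpy as np
import pytest

import banditea.ea as ea_mod
from banditea.agent import LearningParams
from banditea.ea import (
    CrossoverError,
    CurationConfig,
    EaConfig,
    Member,
    Population,
    clustered_ea,
    curate_parents,
    cut_and_splice,
    ea_run,
    energy_spacing_filter,
    fitness,
    select_parents,
    unclustered_ea,
    uniqueness,
)
from banditea.structures import Structure, parse_formula

C9H7N = parse_formula("C9H7N")

# fast inner-loop settings for the toy calculator
FAST = EaConfig(relax_max_steps=30, crossover_max_retries=30)


def structure_with_energy(energy, seed=0):
    rng = np.random.default_rng(seed)
    return Structure(("C", "C"), rng.uniform(-2, 2, (2, 3)) + 5 * seed, energy=energy)


class TestFitness:
    def test_midpoint(self):
        assert fitness(0.5, 0.0, 1.0) == pytest.approx(0.5)

    def test_best_member_closed_form(self):
        assert fitness(0.0, 0.0, 1.0) == pytest.approx(0.5 * (1 - math.tanh(-1)))
        assert fitness(0.0, 0.0, 1.0) == pytest.approx(0.8807970779778823)

    def test_worst_member_closed_form(self):
        assert fitness(1.0, 0.0, 1.0) == pytest.approx(0.11920292202211755)

    def test_symmetry_about_midpoint(self):
        assert fitness(0.0, 0.0, 1.0) + fitness(1.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_strictly_decreasing(self):
        es = np.linspace(0.0, 1.0, 11)
        fs = [fitness(e, 0.0, 1.0) for e in es]
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_degenerate_population(self):
        assert fitness(-3.0, -3.0, -3.0) == 0.5


class TestUniqueness:
    @pytest.mark.parametrize(
        "n,m,expected", [(0, 0, 1.0), (3, 0, 0.5), (0, 3, 0.5), (3, 3, 0.25)]
    )
    def test_exact_surds(self, n, m, expected):
        assert uniqueness(n, m) == pytest.approx(expected)

    def test_decreasing_in_each_argument(self):
        assert uniqueness(5, 0) < uniqueness(4, 0)
        assert uniqueness(0, 5) < uniqueness(0, 4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            uniqueness(-1, 0)


class TestSelectParents:
    def test_two_member_population_always_both(self):
        pop = Population.from_structures(
            [structure_with_energy(-1.0, 1), structure_with_energy(-2.0, 2)]
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            m1, m2 = select_parents(pop, rng)
            assert m1 is not m2

    def test_zero_weight_members_excluded(self, monkeypatch):
        pop = Population.from_structures(
            [structure_with_energy(-3.0, i) for i in range(3)]
        )
        monkeypatch.setattr(
            ea_mod, "_selection_weights", lambda p: np.array([1.0, 0.0, 0.0])
        )
        rng = np.random.default_rng(1)
        for _ in range(50):
            m1, m2 = select_parents(pop, rng)
            assert pop.members[0] in (m1, m2)

    def test_first_parent_marginals_match_weights(self, monkeypatch):
        weights = np.array([1.0, 2.0, 3.0, 4.0])
        monkeypatch.setattr(ea_mod, "_selection_weights", lambda p: weights.copy())
        pop = Population.from_structures(
            [structure_with_energy(-float(i + 1), i) for i in range(4)]
        )
        rng = np.random.default_rng(2)
        n = 100_000
        counts = np.zeros(4)
        for _ in range(n):
            m1, _ = select_parents(pop, rng)
            counts[next(i for i, m in enumerate(pop.members) if m is m1)] += 1
        expected = weights / weights.sum()
        sigma = np.sqrt(expected * (1 - expected) * n)
        assert np.all(np.abs(counts - expected * n) <= 3 * sigma)

    def test_pairing_counts_incremented(self):
        pop = Population.from_structures(
            [structure_with_energy(-1.0, 1), structure_with_energy(-2.0, 2)]
        )
        select_parents(pop, np.random.default_rng(3))
        assert sum(m.n_pairings for m in pop.members) == 2

    def test_single_member_rejected(self):
        pop = Population.from_structures([structure_with_energy(-1.0)])
        with pytest.raises(ValueError):
            select_parents(pop, np.random.default_rng(0))


@pytest.fixture(scope="module")
def parents():
    from banditea.structures import build_structure

    rng = np.random.default_rng(47)
    return (
        build_structure(C9H7N, rng=rng),
        build_structure(C9H7N, rng=rng),
    )


class TestCutAndSplice:
    def test_stoichiometry_preserved_across_seeds(self, parents):
        p1, p2 = parents
        for seed in range(200):
            child = cut_and_splice(p1, p2, rng=np.random.default_rng(seed))
            assert child.stoichiometry() == {"C": 9, "H": 7, "N": 1}

    def test_identical_parents_child_subset_of_parent_atoms(self, parents):
        p1, _ = parents
        child = cut_and_splice(p1, p1.copy(), rng=np.random.default_rng(3))
        assert child.stoichiometry() == p1.stoichiometry()
        centred = p1.coords - p1.coords.mean(axis=0)
        for sym, xyz in zip(child.symbols, child.coords):
            dists = np.linalg.norm(centred - xyz, axis=1)
            matches = [
                i for i in np.flatnonzero(dists < 1e-9) if p1.symbols[i] == sym
            ]
            assert matches

    def test_min_separation_rule_enforced(self, parents):
        from banditea.structures import COVALENT_RADII

        p1, p2 = parents
        child = cut_and_splice(p1, p2, min_sep_frac=0.70, rng=np.random.default_rng(9))
        radii = np.array([COVALENT_RADII[s] for s in child.symbols])
        for i in range(child.n_atoms):
            for j in range(i + 1, child.n_atoms):
                d = float(np.linalg.norm(child.coords[i] - child.coords[j]))
                assert d >= 0.70 * (radii[i] + radii[j]) - 1e-9

    def test_hopeless_parents_fail_after_retries(self):
        rng = np.random.default_rng(11)
        crowded = Structure(
            tuple(["C"] * 9 + ["H"] * 7 + ["N"]), rng.uniform(-0.05, 0.05, (17, 3))
        )
        with pytest.raises(CrossoverError):
            cut_and_splice(
                crowded, crowded.copy(), rng=np.random.default_rng(0), max_retries=10
            )

    def test_mismatched_parents_rejected(self, parents):
        p1, _ = parents
        other = Structure(("C", "C"), [[0, 0, 0], [1.6, 0, 0]])
        with pytest.raises(ValueError):
            cut_and_splice(p1, other, rng=np.random.default_rng(0))


class TestEaRun:
    @pytest.fixture()
    def population(self, relaxed_library):
        return Population.from_structures(list(relaxed_library[:6]), capacity=6)

    def test_zero_iterations_identity(self, population, calc):
        before = population.energies().copy()
        pop, offspring = ea_run(population, calc, 0, FAST, np.random.default_rng(0))
        np.testing.assert_array_equal(pop.energies(), before)
        assert offspring == []

    def test_best_energy_never_worsens_and_size_constant(self, population, calc):
        best_before = population.best.energy
        pop, offspring = ea_run(population, calc, 15, FAST, np.random.default_rng(1))
        assert pop.best.energy <= best_before
        assert len(pop) == 6
        for child in offspring:
            assert child.energy is not None

    def test_population_stays_sorted(self, population, calc):
        pop, _ = ea_run(population, calc, 10, FAST, np.random.default_rng(2))
        e = pop.energies()
        assert np.all(np.diff(e) >= 0)


class TestEnergySpacingFilter:
    def test_method1_exhaustive_example(self):
        # each of the first three has a neighbour within 0.3
        assert energy_spacing_filter([0.0, 0.1, 0.25, 1.0], 1, 0.3) == [3]

    def test_method2_sequential_example(self):
        assert energy_spacing_filter([0.0, 0.1, 0.25, 1.0], 2, 0.3) == [0, 3]

    def test_vanishing_threshold_keeps_all_distinct(self):
        energies = [0.0, 0.5, 1.25, 3.0]
        for method in (1, 2, 3):
            assert energy_spacing_filter(energies, method, 1e-12) == [0, 1, 2, 3]

    def test_method1_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(53)
        for _ in range(50):
            e = np.sort(rng.uniform(0, 5, size=rng.integers(2, 20)))
            de = float(rng.uniform(0.05, 1.0))
            got = energy_spacing_filter(e, 1, de)
            oracle = [
                i
                for i in range(len(e))
                if not any(j != i and abs(e[j] - e[i]) <= de for j in range(len(e)))
            ]
            assert got == oracle

    def test_method2_gaps_exceed_threshold(self):
        rng = np.random.default_rng(59)
        for _ in range(50):
            e = np.sort(rng.uniform(0, 5, size=rng.integers(2, 25)))
            de = float(rng.uniform(0.05, 1.0))
            kept = e[energy_spacing_filter(e, 2, de)]
            assert np.all(np.diff(kept) > de)
            # maximality: every skipped entry is within delta_e of a kept one below it
            for i, val in enumerate(e):
                if val not in kept:
                    below = kept[kept <= val]
                    assert below.size and val - below.max() <= de


class TestEnergySpacingFilterProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=30),
        st.floats(0.01, 10.0),
    )
    def test_method2_kept_gaps_always_exceed_threshold(self, energies, de):
        e = sorted(energies)
        kept = [e[i] for i in energy_spacing_filter(e, 2, de)]
        assert kept[0] == e[0]
        assert all(b - a > de for a, b in zip(kept, kept[1:]))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=30),
        st.floats(0.01, 10.0),
    )
    def test_method1_kept_entries_have_no_neighbours(self, energies, de):
        e = sorted(energies)
        for i in energy_spacing_filter(e, 1, de):
            assert all(abs(e[j] - e[i]) > de for j in range(len(e)) if j != i)


class TestCurateParents:
    def test_padding_with_lowest_excluded(self):
        pool = [structure_with_energy(e, i) for i, e in enumerate([0.0, 0.1, 0.25, 1.0])]
        cfg = CurationConfig(method=1, delta_e=0.3, target_size=2)
        kept = curate_parents([], pool, cfg)
        assert [s.energy for s in kept] == [0.0, 1.0]

    def test_truncation_to_target_size(self):
        pool = [structure_with_energy(float(i), i) for i in range(10)]
        cfg = CurationConfig(method=2, delta_e=0.5, target_size=4)
        kept = curate_parents([], pool, cfg)
        assert [s.energy for s in kept] == [0.0, 1.0, 2.0, 3.0]

    def test_pool_includes_previous_parents(self):
        parents = [structure_with_energy(-5.0, 99)]
        pool = [structure_with_energy(float(i), i) for i in range(3)]
        cfg = CurationConfig(method=2, delta_e=0.5, target_size=4)
        kept = curate_parents(parents, pool, cfg)
        assert kept[0].energy == -5.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            curate_parents([], [], CurationConfig())


@pytest.fixture(scope="module")
def clusters(relaxed_library):
    # two small clusters from the relaxed fixture library
    return [list(relaxed_library[:6]), list(relaxed_library[6:12])]


class TestDrivers:
    def test_clustered_runs_all_selections_without_success_energy(
        self, clusters, calc
    ):
        cfg = EaConfig(iterations=3, selections=4, relax_max_steps=30)
        cur = CurationConfig(method=1, delta_e=0.3, target_size=4)
        rec = clustered_ea(
            clusters, LearningParams(), cur, calc, cfg, np.random.default_rng(1)
        )
        assert len(rec.entries) == 4
        assert rec.total_iterations == 12
        assert rec.success_iteration is None

    def test_clustered_iteration_budget_bounded(self, clusters, calc):
        cfg = EaConfig(iterations=3, selections=4, relax_max_steps=30)
        cur = CurationConfig(method=3, delta_e=0.3, target_size=4)
        rec = clustered_ea(
            clusters, LearningParams(), cur, calc, cfg, np.random.default_rng(2)
        )
        assert rec.total_iterations <= cfg.selections * cfg.iterations

    def test_clustered_early_stop_on_success(self, clusters, calc):
        cfg = EaConfig(iterations=3, selections=6, relax_max_steps=30)
        cur = CurationConfig(method=2, delta_e=0.3, target_size=4)
        rec = clustered_ea(
            clusters,
            LearningParams(),
            cur,
            calc,
            cfg,
            np.random.default_rng(3),
            success_energy=1e9,
        )
        assert rec.success_iteration == 3
        assert len(rec.entries) == 1

    def test_rigged_low_energy_cluster_is_favoured(
        self, builder_library, relaxed_library, calc
    ):
        # cluster 0 holds barely-relaxed sprawl whose offspring stay high in
        # energy; cluster 1 holds locally optimised structures whose
        # offspring relax deep.  The agent should favour cluster 1.
        sprawl = [calc.relax(s, 5, 0.05) for s in builder_library[:6]]
        compact = list(relaxed_library[6:12])
        cfg = EaConfig(iterations=2, selections=15, relax_max_steps=10)
        cur = CurationConfig(method=2, delta_e=0.3, target_size=4)
        rec = clustered_ea(
            [sprawl, compact],
            LearningParams(79, 3, 19, 68),
            cur,
            calc,
            cfg,
            np.random.default_rng(5),
        )
        picks = [e["cluster"] for e in rec.entries]
        assert picks.count(1) > len(picks) / 2

    def test_undersized_cluster_rejected(self, clusters, calc):
        cur = CurationConfig(method=1, delta_e=0.3, target_size=20)
        with pytest.raises(ValueError):
            clustered_ea(
                clusters, LearningParams(), cur, calc, FAST, np.random.default_rng(0)
            )

    def test_unclustered_zero_iterations_library_minimum(self, relaxed_library, calc):
        rec = unclustered_ea(relaxed_library, calc, 0, np.random.default_rng(0), FAST)
        assert rec.best_energy == pytest.approx(min(s.energy for s in relaxed_library))

    def test_unclustered_running_minimum_non_increasing(self, relaxed_library, calc):
        rec = unclustered_ea(relaxed_library, calc, 25, np.random.default_rng(1), FAST)
        mins = [e["running_min"] for e in rec.entries]
        assert len(mins) == 25
        assert all(a >= b for a, b in zip(mins, mins[1:]))

    def test_unclustered_population_grows(self, relaxed_library, calc):
        rec = unclustered_ea(relaxed_library, calc, 25, np.random.default_rng(2), FAST)
        produced = sum(1 for e in rec.entries if e["offspring_energy"] is not None)
        assert produced > 0
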