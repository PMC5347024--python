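"""Dose-response evaluation, system-matrix assembly, and ODE simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from tumorsched import (
    ClonePharmacodynamics,
    ConfigurationError,
    Environment,
    MutationGraph,
    PharmacodynamicsTable,
    SimulationOverflowError,
    Therapy,
    TreatmentSchedule,
    TumorState,
    build_system_matrix,
    evaluate_growth_rate,
    simulate_schedule,
    total_population,
)
from tumorsched.scenarios import genotype

from conftest import (
    make_single_clone_system,
    random_pd_table,
    random_state,
    random_sublattice,
    single_drug_therapy,
)

ENV = Environment(False)


def make_pd(g0=0.2, gmin=-0.1, ec50=0.5, hill=1.0, therapy="tki"):
    return ClonePharmacodynamics(genotype("L858R"), ENV, therapy,
                                 g0=g0, gmin=gmin, ec50=ec50, hill=hill)


class TestGrowthRate:
    def test_zero_dose_returns_drug_free_rate(self):
        assert evaluate_growth_rate(make_pd(), 0.0) == 0.2

    def test_midpoint_at_ec50_with_unit_hill(self):
        assert evaluate_growth_rate(make_pd(), 0.5) == pytest.approx(0.05)

    def test_saturating_dose_approaches_gmin(self):
        assert evaluate_growth_rate(make_pd(), 1e6) == pytest.approx(-0.1, abs=1e-5)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            evaluate_growth_rate(make_pd(), -0.1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        g0=st.floats(-0.3, 0.3),
        drop=st.floats(0.0, 0.5),
        ec50=st.floats(0.01, 5.0),
        hill=st.floats(0.2, 5.0),
    )
    def test_nonincreasing_in_dose(self, g0, drop, ec50, hill):
        pd_ = make_pd(g0=g0, gmin=g0 - drop, ec50=ec50, hill=hill)
        doses = np.arange(0.0, 10.01, 0.1)
        rates = [evaluate_growth_rate(pd_, d) for d in doses]
        assert all(a >= b - 1e-12 for a, b in zip(rates, rates[1:]))

    def test_invariant_violations_rejected(self):
        with pytest.raises(ConfigurationError):
            make_pd(gmin=0.3)  # gmin > g0
        with pytest.raises(ConfigurationError):
            make_pd(ec50=0.0)
        with pytest.raises(ConfigurationError):
            make_pd(hill=-1.0)


class TestSystemMatrix:
    def test_no_mutation_gives_diagonal_growth_rates(self, rng):
        graph = random_sublattice(rng, mu_range=(0.0, 0.0))
        therapy = single_drug_therapy()
        pds = random_pd_table(rng, graph, [therapy])
        A = build_system_matrix(pds, graph, therapy, ENV)
        expected = np.diag(
            [pds.growth_rate(g, ENV, therapy) for g in graph.nodes]
        )
        np.testing.assert_allclose(A, expected)

    def test_column_sums_equal_growth_rates(self, rng):
        # mutation conserves cells: column j sums to g_j(dose)
        for _ in range(20):
            graph = random_sublattice(rng)
            therapy = single_drug_therapy()
            pds = random_pd_table(rng, graph, [therapy])
            A = build_system_matrix(pds, graph, therapy, ENV)
            expected = [pds.growth_rate(g, ENV, therapy) for g in graph.nodes]
            np.testing.assert_allclose(A.sum(axis=0), expected, atol=1e-14)
            off = A - np.diag(np.diag(A))
            assert np.all(off >= 0)  # Metzler

    def test_triangular_eigenvalues_equal_diagonal(self, rng):
        g1, g2 = genotype("L858R"), genotype("L858R", "V600E")
        g3, g4 = genotype("L858R", "T790M"), genotype("L858R", "V600E", "T790M")
        graph = MutationGraph(
            [g1, g2, g3, g4],
            [(g1, g2, 1e-3), (g1, g3, 2e-3), (g2, g4, 1e-3), (g3, g4, 5e-4)],
        )
        therapy = single_drug_therapy()
        pds = random_pd_table(rng, graph, [therapy])
        A = build_system_matrix(pds, graph, therapy, ENV)
        assert np.allclose(np.tril(A), A)  # topological order -> lower triangular
        eig = np.sort(np.linalg.eigvals(A).real)
        np.testing.assert_allclose(eig, np.sort(np.diag(A)), atol=1e-12)

    def test_missing_pharmacodynamics_names_the_node(self):
        g1, g2 = genotype("L858R"), genotype("L858R", "V600E")
        graph = MutationGraph([g1, g2], [(g1, g2, 1e-6)])
        therapy = single_drug_therapy()
        pds = PharmacodynamicsTable(
            [ClonePharmacodynamics(g1, ENV, therapy.name, 0.1, -0.1, 0.5, 1.0)]
        )
        with pytest.raises(ConfigurationError, match="L858R\\+V600E"):
            build_system_matrix(pds, graph, therapy, ENV)

    def test_edge_must_add_exactly_one_alteration(self):
        g1 = genotype("L858R")
        g3 = genotype("L858R", "V600E", "T790M")
        with pytest.raises(ConfigurationError):
            MutationGraph([g1, g3], [(g1, g3, 1e-6)])


class TestSimulate:
    def test_zero_growth_is_constant(self):
        g, graph, therapy, pds = make_single_clone_system(g0=0.0, gmin=0.0, dose=0.0)
        x0 = TumorState({g: 1000.0}, ENV)
        schedule = TreatmentSchedule(((therapy.with_tki_dose(0.0), 30.0),))
        traj = simulate_schedule(x0, schedule, pds, graph)
        np.testing.assert_allclose(traj.counts[:, 0], 1000.0)

    def test_doubling_closed_form(self):
        g, graph, therapy, pds = make_single_clone_system(
            g0=np.log(2), gmin=np.log(2), dose=0.0
        )
        x0 = TumorState({g: 1000.0}, ENV)
        schedule = TreatmentSchedule(((therapy.with_tki_dose(0.0), 3.0),))
        traj = simulate_schedule(x0, schedule, pds, graph)
        assert traj.final_total == pytest.approx(8000.0, rel=1e-12)

    def test_two_clone_chain_matches_independent_integrator(self):
        ga, gb = genotype("L858R"), genotype("L858R", "T790M")
        graph = MutationGraph([ga, gb], [(ga, gb, 1e-3)])
        therapy = single_drug_therapy(dose=0.0)
        pds = PharmacodynamicsTable([
            ClonePharmacodynamics(ga, ENV, therapy.name, 0.1, 0.1, 0.5, 1.0),
            ClonePharmacodynamics(gb, ENV, therapy.name, 0.2, 0.2, 0.5, 1.0),
        ])
        x0 = TumorState({ga: 10000.0, gb: 0.0}, ENV)
        schedule = TreatmentSchedule(((therapy, 30.0),))
        traj = simulate_schedule(x0, schedule, pds, graph, output_step=1.0)
        A = build_system_matrix(pds, graph, therapy, ENV)
        sol = solve_ivp(lambda t, x: A @ x, (0, 30), [10000.0, 0.0],
                        t_eval=traj.times, rtol=1e-12, atol=1e-6)
        np.testing.assert_allclose(traj.counts, sol.y.T, rtol=1e-8)

    def test_positivity_preserved(self, rng):
        for _ in range(20):
            graph = random_sublattice(rng)
            therapies = [single_drug_therapy("tki", float(d)) for d in (0.2, 1.5)]
            pds = random_pd_table(rng, graph, therapies[:1])
            x0 = random_state(rng, graph)
            schedule = TreatmentSchedule(
                ((therapies[0], 10.0), (therapies[1], 10.0))
            )
            traj = simulate_schedule(x0, schedule, pds, graph)
            assert np.all(traj.counts >= 0)

    def test_mutation_conserves_total_when_rates_equal(self, rng):
        # with all g_i equal, d(total)/dt is independent of the mu values
        labels = ("V600E", "T790M")
        nodes = [genotype("L858R"), genotype("L858R", "V600E"),
                 genotype("L858R", "T790M"),
                 genotype("L858R", "V600E", "T790M")]
        therapy = single_drug_therapy(dose=0.3)
        pds = PharmacodynamicsTable([
            ClonePharmacodynamics(g, ENV, therapy.name, 0.15, -0.05, 0.4, 1.2)
            for g in nodes
        ])
        x0 = TumorState({g: 2500.0 for g in nodes}, ENV)

        def edges(mu):
            out = []
            for u in nodes:
                for lab in labels:
                    if lab not in u.alterations:
                        v = genotype(*(u.alterations | {lab}))
                        out.append((u, v, mu))
            return out

        totals = []
        for mu in (0.0, 1e-3):
            graph = MutationGraph(nodes, edges(mu))
            traj = simulate_schedule(
                x0, TreatmentSchedule(((therapy, 20.0),)), pds, graph
            )
            totals.append(traj.total())
        np.testing.assert_allclose(totals[0], totals[1], rtol=1e-10)

    def test_lower_dose_never_decreases_any_count(self, rng):
        # Metzler comparison: scaling the TKI dose down raises every
        # diagonal entry, so every clone count weakly increases
        graph = random_sublattice(rng)
        therapy = single_drug_therapy(dose=1.0)
        pds = random_pd_table(rng, graph, [therapy])
        x0 = random_state(rng, graph)
        schedule = TreatmentSchedule(((therapy, 15.0),))
        full = simulate_schedule(x0, schedule, pds, graph)
        reduced = simulate_schedule(x0, schedule.scale_tki_dose(0.6), pds, graph)
        assert np.all(reduced.counts >= full.counts - 1e-9 * (1 + full.counts))

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            TreatmentSchedule(())

    def test_overflow_reports_time(self):
        g, graph, therapy, pds = make_single_clone_system(g0=10.0, gmin=10.0)
        x0 = TumorState({g: 1e300}, ENV)
        schedule = TreatmentSchedule(((therapy, 400.0),))
        with pytest.raises(SimulationOverflowError):
            simulate_schedule(x0, schedule, pds, graph)

    def test_first_row_equals_initial_state(self, rng):
        graph = random_sublattice(rng)
        therapy = single_drug_therapy()
        pds = random_pd_table(rng, graph, [therapy])
        x0 = random_state(rng, graph)
        traj = simulate_schedule(x0, TreatmentSchedule(((therapy, 5.0),)),
                                 pds, graph)
        np.testing.assert_allclose(traj.counts[0], x0.vector(graph))
        assert traj.times[0] == 0.0
        assert np.all(np.diff(traj.times) > 0)


class TestTotalPopulation:
    def test_array_state_and_empty(self):
        assert total_population((1000.0, 0.0, 0.0)) == 1000.0
        assert total_population([]) == 0.0
        assert total_population({genotype("L858R"): 42.0}) == 42.0
        x0 = TumorState({genotype("L858R"): 5000.0}, ENV)
        assert total_population(x0) == 5000.0
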