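"""Downstream reachability, evolutionary stability, and minimum stabilizing dose."""

import networkx as nx
import numpy as np
import pytest

from tumorsched import (
    ConfigurationError,
    Environment,
    INFEASIBLE,
    MutationGraph,
    PharmacodynamicsTable,
    ClonePharmacodynamics,
    TreatmentSchedule,
    TumorState,
    classify_initial_subclones,
    downstream_reachable_set,
    evolutionary_stability,
    min_stabilizing_concentration,
    simulate_schedule,
)
from tumorsched.stability import evolutionary_stability_closed_form
from tumorsched.scenarios import genotype, get_scenario

from conftest import (
    make_single_clone_system,
    random_pd_table,
    random_state,
    random_sublattice,
    single_drug_therapy,
)

ENV = Environment(False)


def nx_descendants(graph: MutationGraph, g):
    """Independent oracle: transitive closure via networkx BFS."""
    G = nx.DiGraph()
    G.add_nodes_from(graph.nodes)
    G.add_edges_from((p, c) for p, c, _ in graph.edges)
    return nx.descendants(G, g) | {g}


class TestReachability:
    def test_terminal_node_reaches_only_itself(self):
        ga, gb = genotype("L858R"), genotype("L858R", "T790M")
        graph = MutationGraph([ga, gb], [(ga, gb, 1e-6)])
        assert downstream_reachable_set(gb, graph) == {gb}

    def test_root_reaches_all_in_full_lattice(self):
        from tumorsched import egfr_lattice

        graph = egfr_lattice()
        root = genotype("L858R")
        assert downstream_reachable_set(root, graph) == set(graph.nodes)

    def test_unknown_genotype_rejected(self):
        graph = MutationGraph([genotype("L858R")], [])
        with pytest.raises(ConfigurationError):
            downstream_reachable_set(genotype("L858R", "V600E"), graph)

    def test_matches_networkx_closure_on_random_dags(self, rng):
        for _ in range(100):
            graph = random_sublattice(rng, max_labels=4, keep_prob=0.6)
            for g in graph.nodes:
                assert downstream_reachable_set(g, graph) == nx_descendants(graph, g)


class TestEvolutionaryStability:
    def test_terminal_genotype_is_own_growth_rate(self):
        g, graph, therapy, pds = make_single_clone_system(
            g0=-0.05, gmin=-0.05, dose=0.0
        )
        s = evolutionary_stability(g, therapy, pds, graph, ENV)
        assert s == pytest.approx(-0.05, abs=1e-12)

    def test_two_clone_chain_dominated_by_resistant_descendant(self):
        ga, gb = genotype("L858R"), genotype("L858R", "T790M")
        graph = MutationGraph([ga, gb], [(ga, gb, 1e-6)])
        therapy = single_drug_therapy(dose=0.0)
        pds = PharmacodynamicsTable([
            ClonePharmacodynamics(ga, ENV, therapy.name, 0.1, 0.1, 0.5, 1.0),
            ClonePharmacodynamics(gb, ENV, therapy.name, 0.25, 0.25, 0.5, 1.0),
        ])
        s = evolutionary_stability(ga, therapy, pds, graph, ENV)
        assert s == pytest.approx(0.25, abs=1e-12)

    def test_eigen_equals_triangular_closed_form(self, rng):
        for _ in range(100):
            graph = random_sublattice(rng, max_labels=3)
            therapy = single_drug_therapy(dose=float(rng.uniform(0, 2)))
            pds = random_pd_table(rng, graph, [therapy])
            for g in graph.nodes:
                eig = evolutionary_stability(g, therapy, pds, graph, ENV)
                cf = evolutionary_stability_closed_form(g, therapy, pds, graph, ENV)
                assert eig == pytest.approx(cf, abs=1e-10)

    def test_nonincreasing_in_dose(self, rng):
        graph = random_sublattice(rng)
        therapy = single_drug_therapy(dose=0.0)
        pds = random_pd_table(rng, graph, [therapy])
        root = genotype("L858R")
        doses = np.linspace(0, 5, 30)
        vals = [
            evolutionary_stability(root, therapy.with_tki_dose(d), pds, graph, ENV)
            for d in doses
        ]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_heterogeneous_met_negative_population_fully_stabilized(self):
        # afatinib+trametinib covers every branch of the 89/10/1 mixture
        # when MET is not activated: all stabilities negative
        sc = get_scenario("invitro_heterogeneous_hgf")
        x0 = TumorState(
            {g: f * sc.total_cells for g, f in sc.composition.items()},
            Environment(hgf=False),
        )
        afa_tra = next(t for t in sc.panel if t.name == "AFA+TRA")
        report = classify_initial_subclones(x0, afa_tra, sc.pds, sc.graph)
        assert report.all_response


class TestClassification:
    def test_labels_match_stability_signs(self, rng):
        for _ in range(20):
            graph = random_sublattice(rng)
            therapy = single_drug_therapy(dose=float(rng.uniform(0, 2)))
            pds = random_pd_table(rng, graph, [therapy])
            x0 = random_state(rng, graph)
            report = classify_initial_subclones(x0, therapy, pds, graph)
            assert {e.genotype for e in report.entries} == {
                g for g, c in x0.counts.items() if c > 0
            }
            for e in report.entries:
                s = evolutionary_stability(e.genotype, therapy, pds, graph, ENV)
                expected = ("progression" if s > 0
                            else "response" if s < 0 else "boundary")
                assert e.label == expected

    def test_empty_population_rejected(self):
        g, graph, therapy, pds = make_single_clone_system()
        with pytest.raises(ValueError):
            classify_initial_subclones(
                TumorState({g: 0.0}, ENV), therapy, pds, graph
            )

    def test_progression_label_implies_eventual_regrowth(self, rng):
        # a subclone labeled progression, seeded alone, eventually drives
        # the total above its starting value under the constant therapy
        checked = 0
        while checked < 20:
            graph = random_sublattice(rng, mu_range=(1e-4, 1e-2))
            therapy = single_drug_therapy(dose=float(rng.uniform(0, 2)))
            pds = random_pd_table(rng, graph, [therapy])
            for g in graph.nodes:
                s = evolutionary_stability(g, therapy, pds, graph, ENV)
                if s < 0.02:
                    continue
                x0 = TumorState({g: 1e4}, ENV)
                report = classify_initial_subclones(x0, therapy, pds, graph)
                assert report.label_of(g) == "progression"
                traj = simulate_schedule(
                    x0, TreatmentSchedule(((therapy, 600.0),)), pds, graph,
                    output_step=10.0,
                )
                assert traj.total().max() > x0.total
                checked += 1


class TestMinStabilizingDose:
    def test_already_decaying_returns_zero(self):
        g, graph, therapy, pds = make_single_clone_system(g0=-0.05, gmin=-0.1)
        x0 = TumorState({g: 1000.0}, ENV)
        assert min_stabilizing_concentration(therapy, pds, graph, x0) == 0.0

    def test_single_clone_matches_hill_inversion(self):
        # g(d) = 0 at d* = ec50 * (g0 / -gmin)^(1/hill) = 0.5 * 2 = 1.0 uM
        g, graph, therapy, pds = make_single_clone_system(
            g0=0.2, gmin=-0.1, ec50=0.5, hill=1.0
        )
        x0 = TumorState({g: 1000.0}, ENV)
        d = min_stabilizing_concentration(therapy, pds, graph, x0, tol=1e-4)
        assert abs(d - 1.0) <= 1e-4 + 1e-12

    def test_unstabilizable_population_reported_infeasible(self):
        g, graph, therapy, pds = make_single_clone_system(g0=0.2, gmin=0.05)
        x0 = TumorState({g: 1000.0}, ENV)
        assert min_stabilizing_concentration(therapy, pds, graph, x0) == INFEASIBLE

    def test_met_activated_population_needs_infeasible_erlotinib_dose(self):
        # with MET activation, no erlotinib-based combination dose within
        # bounds stabilizes the full mixture (bypass clones are insensitive)
        sc = get_scenario("invitro_heterogeneous_hgf")
        erl_vem = next(t for t in sc.panel if t.name == "ERL+VEM")
        d = min_stabilizing_concentration(
            erl_vem, sc.pds, sc.graph, sc.initial_state()
        )
        assert d > 1.5  # far beyond the 1.5 uM clinical panel dose
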