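"""Shared fixtures: small genotype systems and random scenario generators."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tumorsched import (
    ClonePharmacodynamics,
    Environment,
    Genotype,
    MutationGraph,
    PharmacodynamicsTable,
    Therapy,
    TumorState,
)
from tumorsched.scenarios import genotype


def single_drug_therapy(name: str = "tki", dose: float = 1.0) -> Therapy:
    return Therapy(name, ((name, dose),), name)


def make_single_clone_system(g0=0.2, gmin=-0.1, ec50=0.5, hill=1.0, dose=1.0):
    """One clone, no mutation, one single-drug therapy."""
    g = genotype("L858R")
    graph = MutationGraph([g], [])
    therapy = single_drug_therapy(dose=dose)
    env = Environment(False)
    pds = PharmacodynamicsTable(
        [ClonePharmacodynamics(g, env, therapy.name, g0=g0, gmin=gmin,
                               ec50=ec50, hill=hill)]
    )
    return g, graph, therapy, pds


def random_sublattice(rng: np.random.Generator, max_labels: int = 3,
                      keep_prob: float = 0.7,
                      mu_range: tuple = (1e-5, 1e-2)) -> MutationGraph:
    """Random acyclic acquisition graph: a sampled sub-lattice of subsets.

    Always contains the founder-only genotype; edges are all one-alteration
    inclusions among the sampled nodes, with rates drawn uniformly.
    """
    n_labels = int(rng.integers(1, max_labels + 1))
    labels = [f"A{i}" for i in range(n_labels)]
    nodes = [genotype("L858R")]
    for r in range(1, n_labels + 1):
        for combo in itertools.combinations(labels, r):
            if rng.random() < keep_prob:
                nodes.append(genotype("L858R", *combo))
    edges = []
    node_set = set(nodes)
    for u in nodes:
        for lab in labels:
            if lab not in u.alterations:
                v = Genotype(u.alterations | {lab})
                if v in node_set:
                    edges.append((u, v, float(rng.uniform(*mu_range))))
    return MutationGraph(nodes, edges)


def random_pd_table(rng: np.random.Generator, graph: MutationGraph,
                    therapies, env: Environment = Environment(False),
                    g_range: tuple = (-0.3, 0.3)) -> PharmacodynamicsTable:
    """Random Hill curves per (node, therapy) in the given environment."""
    table = PharmacodynamicsTable()
    for g in graph.nodes:
        for t in therapies:
            lo, hi = g_range
            a, b = sorted(rng.uniform(lo, hi, size=2))
            table.add(
                ClonePharmacodynamics(
                    g, env, t.name, g0=float(b), gmin=float(a),
                    ec50=float(rng.uniform(0.05, 2.0)),
                    hill=float(rng.uniform(0.5, 3.0)),
                )
            )
    return table


def random_state(rng: np.random.Generator, graph: MutationGraph,
                 env: Environment = Environment(False),
                 total: float = 1e4) -> TumorState:
    w = rng.dirichlet(np.ones(len(graph)))
    return TumorState(
        {g: float(total * wi) for g, wi in zip(graph.nodes, w)}, env
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def single_clone_system():
    return make_single_clone_system()
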