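"""Evolutionary stability of subclones under a fixed therapy.

A subclone present at treatment start can doom a therapy if any genotype
reachable from it by mutation grows under that therapy.  The evolutionary
stability of a subclone is the maximum real part of the eigenvalues of the
system matrix restricted to its downstream reachable set: positive means
that branch can drive progression, negative means every reachable genotype
decays (exponential stability of the branch).

Because the acquisition graph is acyclic the restricted matrix is
triangular, so the eigenvalues are its diagonal entries and the stability
equals max over reachable genotypes of (g_j(dose) - total outgoing mutation
rate of j).  Both routes are computed; the eigensolver is the primary path
and the closed form backs the invariant tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._errors import ConfigurationError
from .dynamics import (
    Environment,
    Genotype,
    MutationGraph,
    PharmacodynamicsTable,
    Therapy,
    TumorState,
    build_system_matrix,
)

__all__ = [
    "StabilityReport",
    "downstream_reachable_set",
    "evolutionary_stability",
    "evolutionary_stability_closed_form",
    "classify_initial_subclones",
    "min_stabilizing_concentration",
    "INFEASIBLE",
]

#: Sentinel returned when no dose within bounds stabilizes the population.
INFEASIBLE = float("inf")


@dataclass(frozen=True)
class SubcloneStability:
    genotype: Genotype
    stability: float  # per day
    label: str  # "response" | "progression" | "boundary"


@dataclass
class StabilityReport:
    """Per-subclone stability values and classifications for one therapy."""

    therapy: Therapy
    environment: Environment
    entries: list  # list[SubcloneStability]

    def label_of(self, genotype: Genotype) -> str:
        for e in self.entries:
            if e.genotype == genotype:
                return e.label
        raise KeyError(genotype.name)

    @property
    def all_response(self) -> bool:
        return all(e.label == "response" for e in self.entries)

    def to_dict(self) -> dict:
        return {
            "therapy": self.therapy.name,
            "environment": self.environment.label,
            "subclones": [
                {
                    "genotype": e.genotype.name,
                    "stability_per_day": e.stability,
                    "classification": e.label,
                }
                for e in self.entries
            ],
        }


def downstream_reachable_set(
    genotype: Genotype, graph: MutationGraph
) -> set[Genotype]:
    """All genotypes reachable from ``genotype`` by mutation, itself included."""
    if genotype not in graph:
        raise ConfigurationError(f"unknown genotype {genotype.name}")
    seen = {genotype}
    frontier = [genotype]
    while frontier:
        g = frontier.pop()
        for child in graph.children(g):
            if child not in seen:
                seen.add(child)
                frontier.append(child)
    return seen


def evolutionary_stability(
    genotype: Genotype,
    therapy: Therapy,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    environment: Environment,
) -> float:
    """Max real eigenvalue of A(u) restricted to the downstream reachable set."""
    reachable = downstream_reachable_set(genotype, graph)
    A = build_system_matrix(pds, graph, therapy, environment)
    idx = sorted(graph.index(g) for g in reachable)
    sub = A[np.ix_(idx, idx)]
    return float(np.max(np.linalg.eigvals(sub).real))


def evolutionary_stability_closed_form(
    genotype: Genotype,
    therapy: Therapy,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    environment: Environment,
) -> float:
    """Triangular closed form: max over reachable j of g_j(dose) - mu_out(j)."""
    reachable = downstream_reachable_set(genotype, graph)
    return max(
        pds.growth_rate(g, environment, therapy) - graph.total_outflow(g)
        for g in reachable
    )


def _label(stability: float) -> str:
    if stability > 0:
        return "progression"
    if stability < 0:
        return "response"
    return "boundary"


def classify_initial_subclones(
    x0: TumorState,
    therapy: Therapy,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
) -> StabilityReport:
    """Stability classification of every subclone present in ``x0``.

    Covers exactly the genotypes with positive initial count; a subclone is
    labeled "progression" when its downstream branch contains a growing
    genotype, "response" when the whole branch decays.
    """
    present = [g for g, c in x0.counts.items() if c > 0]
    if not present:
        raise ValueError("initial population is empty")
    entries = []
    for g in sorted(present, key=graph.index):
        s = evolutionary_stability(g, therapy, pds, graph, x0.environment)
        entries.append(SubcloneStability(g, s, _label(s)))
    return StabilityReport(therapy, x0.environment, entries)


def min_stabilizing_concentration(
    therapy_template: Therapy,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    x0: TumorState,
    dose_bounds: tuple[float, float] = (0.0, 100.0),
    tol: float = 1e-4,
) -> float:
    """Smallest EGFR TKI dose making every initial subclone's branch decay.

    Found by bisection on the dose (partner-drug concentrations fixed at the
    template's values) to absolute tolerance ``tol`` uM.  Returns 0.0 when
    the population already decays at dose 0 and ``INFEASIBLE`` (inf) when
    stability remains nonnegative at the upper bound — strict negativity
    defines stabilization; the boundary value 0 is conservatively treated as
    not stabilized.

    The configured dose-response curves must be nonincreasing in dose
    (guaranteed by the ClonePharmacodynamics invariant gmin <= g0).
    """
    lo, hi = dose_bounds
    if not (0 <= lo < hi):
        raise ValueError("dose bounds must satisfy 0 <= lo < hi")
    present = [g for g, c in x0.counts.items() if c > 0]
    if not present:
        raise ValueError("initial population is empty")

    def worst(dose: float) -> float:
        t = therapy_template.with_tki_dose(dose)
        return max(
            evolutionary_stability(g, t, pds, graph, x0.environment) for g in present
        )

    if worst(lo) < 0:
        return float(lo)
    if worst(hi) >= 0:
        return INFEASIBLE
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if worst(mid) < 0:
            hi = mid
        else:
            lo = mid
    return float(hi)


def stability_dose_sweep(
    therapy_template: Therapy,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    x0: TumorState,
    doses: Iterable[float],
):
    """Stability of each initial subclone across a grid of TKI doses.

    Returns a pandas DataFrame with columns dose_uM, genotype, stability,
    label — the dose-sweep table written by the CLI.
    """
    import pandas as pd

    present = [g for g, c in x0.counts.items() if c > 0]
    rows = []
    for d in doses:
        t = therapy_template.with_tki_dose(d)
        for g in sorted(present, key=graph.index):
            s = evolutionary_stability(g, t, pds, graph, x0.environment)
            rows.append(
                {"dose_uM": float(d), "genotype": g.name, "stability": s,
                 "label": _label(s)}
            )
    return pd.DataFrame(rows)
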