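"""Clonal evolution dynamics of EGFR-mutant lung adenocarcinoma under polytherapy.

The tumor is modeled as a set of subclones (genotypes on an alteration
lattice rooted at the EGFR L858R founder).  Each subclone grows or dies at a
net rate set by a Hill-type dose-response curve in the EGFR TKI
concentration of the applied therapy, and seeds descendant genotypes at
small per-day mutation rates along the lattice edges.  The resulting system

    dx/dt = A(u) x,      A(u) Metzler, u the applied therapy,

is linear and time-invariant within each treatment segment, so trajectories
are propagated exactly with the matrix exponential.

Units throughout: time in days, drug concentrations in micromolar (uM),
populations in cells (continuous, deterministic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._errors import ConfigurationError, SimulationOverflowError

__all__ = [
    "ALTERATIONS",
    "Genotype",
    "Environment",
    "MutationGraph",
    "Therapy",
    "ClonePharmacodynamics",
    "PharmacodynamicsTable",
    "TumorState",
    "TreatmentSchedule",
    "Trajectory",
    "evaluate_growth_rate",
    "build_system_matrix",
    "simulate_schedule",
    "total_population",
]

#: Alteration labels of the modeled lattice.  L858R is the founder event;
#: the others are acquired resistance alterations.
ALTERATIONS = ("L858R", "V600E", "T790M", "METamp")


@dataclass(frozen=True)
class Genotype:
    """A subclone identified by its set of genetic alterations.

    The alteration set uniquely identifies the genotype; the display name is
    purely cosmetic and defaults to a '+'-joined canonical ordering.
    """

    alterations: frozenset
    display_name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "alterations", frozenset(self.alterations))
        if not self.display_name:
            ordered = [a for a in ALTERATIONS if a in self.alterations]
            ordered += sorted(self.alterations.difference(ALTERATIONS))
            object.__setattr__(self, "display_name", "+".join(ordered) or "WT")

    def __eq__(self, other):
        if not isinstance(other, Genotype):
            return NotImplemented
        return self.alterations == other.alterations

    def __hash__(self):
        return hash(self.alterations)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"Genotype({self.display_name})"

    @property
    def name(self) -> str:
        return self.display_name


@dataclass(frozen=True)
class Environment:
    """Assay environment: HGF stimulation phenocopies MET amplification.

    ``hgf=True`` corresponds to 50 ng/ml HGF treatment, ``hgf=False`` to
    0 ng/ml.  The flag is fixed for an entire simulation and selects the
    pharmacodynamic parameter set.
    """

    hgf: bool = False

    @property
    def label(self) -> str:
        return "HGF+" if self.hgf else "HGF-"


class MutationGraph:
    """Directed acyclic acquisition graph over genotypes.

    Each edge adds exactly one alteration to the parent's set and carries a
    nonnegative per-day mutation rate.  Nodes are kept in a topological
    order (parents before children), which makes the system matrix lower
    triangular and its eigenvalues equal to the diagonal.
    """

    def __init__(
        self,
        nodes: Sequence[Genotype],
        edges: Iterable[tuple[Genotype, Genotype, float]],
    ):
        self.nodes: list[Genotype] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ConfigurationError("duplicate genotypes in mutation graph")
        self._index = {g: i for i, g in enumerate(self.nodes)}
        self.edges: list[tuple[Genotype, Genotype, float]] = []
        for parent, child, mu in edges:
            if parent not in self._index or child not in self._index:
                raise ConfigurationError(
                    f"edge endpoint not in graph: {parent.name} -> {child.name}"
                )
            extra = child.alterations - parent.alterations
            if not parent.alterations <= child.alterations or len(extra) != 1:
                raise ConfigurationError(
                    f"edge {parent.name} -> {child.name} must add exactly one alteration"
                )
            if mu < 0:
                raise ConfigurationError("mutation rates must be nonnegative")
            self.edges.append((parent, child, float(mu)))
        self.nodes = self._toposort()
        self._index = {g: i for i, g in enumerate(self.nodes)}

    def _toposort(self) -> list[Genotype]:
        # Kahn's algorithm; stable with respect to the declared node order.
        children: dict[Genotype, list[Genotype]] = {g: [] for g in self.nodes}
        indeg = {g: 0 for g in self.nodes}
        for p, c, _ in self.edges:
            children[p].append(c)
            indeg[c] += 1
        order, ready = [], [g for g in self.nodes if indeg[g] == 0]
        while ready:
            g = ready.pop(0)
            order.append(g)
            for c in children[g]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.nodes):
            raise ConfigurationError("mutation graph contains a cycle")
        return order

    def index(self, genotype: Genotype) -> int:
        try:
            return self._index[genotype]
        except KeyError:
            raise ConfigurationError(f"unknown genotype {genotype.name}") from None

    def __contains__(self, genotype: Genotype) -> bool:
        return genotype in self._index

    def __len__(self) -> int:
        return len(self.nodes)

    def out_edges(self, genotype: Genotype) -> list[tuple[Genotype, float]]:
        return [(c, mu) for p, c, mu in self.edges if p == genotype]

    def total_outflow(self, genotype: Genotype) -> float:
        return sum(mu for _, mu in self.out_edges(genotype))

    def children(self, genotype: Genotype) -> list[Genotype]:
        return [c for c, _ in self.out_edges(genotype)]


@dataclass(frozen=True)
class Therapy:
    """A drug combination applied at fixed concentrations.

    ``concentrations`` maps drug name to dose in micromolar; ``tki_drug``
    names the EGFR TKI entry whose concentration enters the dose-response
    curve (partner-drug effects are absorbed into the per-therapy
    pharmacodynamic parameters).
    """

    name: str
    concentrations: tuple  # tuple of (drug, uM) pairs, hashable
    tki_drug: str

    def __post_init__(self):
        conc = tuple(sorted((d, float(c)) for d, c in dict(self.concentrations).items()))
        object.__setattr__(self, "concentrations", conc)
        if any(c < 0 for _, c in conc):
            raise ConfigurationError(f"therapy {self.name}: negative concentration")
        if self.tki_drug not in dict(conc):
            raise ConfigurationError(
                f"therapy {self.name}: TKI drug {self.tki_drug!r} not among concentrations"
            )

    @property
    def tki_dose(self) -> float:
        return dict(self.concentrations)[self.tki_drug]

    def with_tki_dose(self, dose: float) -> "Therapy":
        """Copy of this therapy with the EGFR TKI concentration replaced."""
        conc = dict(self.concentrations)
        conc[self.tki_drug] = float(dose)
        return Therapy(self.name, tuple(conc.items()), self.tki_drug)


@dataclass(frozen=True)
class ClonePharmacodynamics:
    """Hill-type net growth rate of one clone under one therapy.

    g(d) = gmin + (g0 - gmin) / (1 + (d / ec50)^hill)

    where d is the EGFR TKI concentration in uM.  ``g0`` is the drug-free
    net growth rate, ``gmin`` the asymptotic rate at saturating TKI (may be
    negative, i.e. net kill).  The curve is nonincreasing in dose.
    """

    genotype: Genotype
    environment: Environment
    therapy_name: str
    g0: float
    gmin: float
    ec50: float
    hill: float

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ConfigurationError(f"{self.genotype.name}: ec50 must be > 0")
        if self.hill <= 0:
            raise ConfigurationError(f"{self.genotype.name}: hill must be > 0")
        if self.gmin > self.g0:
            raise ConfigurationError(f"{self.genotype.name}: gmin must be <= g0")

    def growth_rate(self, tki_dose: float) -> float:
        return evaluate_growth_rate(self, tki_dose)


def evaluate_growth_rate(pd_: ClonePharmacodynamics, tki_dose: float) -> float:
    """Net per-day growth rate of a clone at a given EGFR TKI dose (uM).

    Returns ``g0`` at dose 0 and tends to ``gmin`` as the dose grows; the
    curve is nonincreasing in dose because ``gmin <= g0``.
    """
    if tki_dose < 0:
        raise ValueError(f"negative TKI dose {tki_dose}")
    if tki_dose == 0:
        return pd_.g0
    ratio = (tki_dose / pd_.ec50) ** pd_.hill
    return pd_.gmin + (pd_.g0 - pd_.gmin) / (1.0 + ratio)


class PharmacodynamicsTable:
    """Lookup of per-(genotype, environment, therapy) dose-response curves.

    MET-amplified genotypes are MET-activated regardless of HGF status, so a
    table built for one environment may serve METamp clones in the other;
    construction is left to the scenario utilities — this class only stores
    and retrieves.
    """

    def __init__(self, entries: Iterable[ClonePharmacodynamics] = ()):
        self._entries: dict[tuple[Genotype, bool, str], ClonePharmacodynamics] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ClonePharmacodynamics) -> None:
        key = (entry.genotype, entry.environment.hgf, entry.therapy_name)
        self._entries[key] = entry

    def lookup(
        self, genotype: Genotype, environment: Environment, therapy: Therapy | str
    ) -> ClonePharmacodynamics:
        tname = therapy if isinstance(therapy, str) else therapy.name
        key = (genotype, environment.hgf, tname)
        try:
            return self._entries[key]
        except KeyError:
            raise ConfigurationError(
                f"no pharmacodynamics for genotype {genotype.name!r} in "
                f"{environment.label} under therapy {tname!r}"
            ) from None

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self):
        return len(self._entries)

    def growth_rate(
        self, genotype: Genotype, environment: Environment, therapy: Therapy
    ) -> float:
        return self.lookup(genotype, environment, therapy).growth_rate(therapy.tki_dose)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "genotype": e.genotype.name,
                "environment": e.environment.label,
                "therapy": e.therapy_name,
                "g0_per_day": e.g0,
                "gmin_per_day": e.gmin,
                "ec50_uM": e.ec50,
                "hill": e.hill,
            }
            for e in self
        ]
        return pd.DataFrame(rows)


@dataclass
class TumorState:
    """Nonnegative cell counts per genotype in a fixed environment."""

    counts: dict  # Genotype -> cells
    environment: Environment = field(default_factory=Environment)

    def __post_init__(self):
        for g, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {g.name}")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def vector(self, graph: MutationGraph) -> np.ndarray:
        x = np.zeros(len(graph))
        for g, c in self.counts.items():
            x[graph.index(g)] = c
        return x


@dataclass(frozen=True)
class TreatmentSchedule:
    """Piecewise-constant therapy assignment: ordered (therapy, duration) segments."""

    segments: tuple  # tuple of (Therapy, duration_days)

    def __post_init__(self):
        segs = tuple((t, float(d)) for t, d in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("schedule must contain at least one segment")
        if any(d <= 0 for _, d in segs):
            raise ValueError("segment durations must be positive")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments)

    def scale_tki_dose(self, factor: float) -> "TreatmentSchedule":
        """Schedule with every segment's EGFR TKI concentration scaled by ``factor``."""
        if factor < 0:
            raise ValueError("dose scale factor must be nonnegative")
        return TreatmentSchedule(
            tuple((t.with_tki_dose(t.tki_dose * factor), d) for t, d in self.segments)
        )

    def therapy_at(self, t: float) -> Therapy:
        elapsed = 0.0
        for therapy, d in self.segments:
            elapsed += d
            if t < elapsed:
                return therapy
        return self.segments[-1][0]


@dataclass
class Trajectory:
    """Time-indexed matrix of cell counts per genotype under a schedule."""

    times: np.ndarray  # days, strictly increasing from 0
    counts: np.ndarray  # len(times) x len(genotypes), cells
    genotypes: list
    environment: Environment
    schedule: TreatmentSchedule

    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def initial_total(self) -> float:
        return float(self.counts[0].sum())

    @property
    def final_total(self) -> float:
        return float(self.counts[-1].sum())

    @property
    def fold_change(self) -> float:
        return self.final_total / self.initial_total

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: time_days, genotype, environment, cells."""
        rows = []
        for i, t in enumerate(self.times):
            for j, g in enumerate(self.genotypes):
                rows.append(
                    {
                        "time_days": float(t),
                        "genotype": g.name,
                        "environment": self.environment.label,
                        "cells": float(self.counts[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def build_system_matrix(
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    therapy: Therapy,
    environment: Environment,
) -> np.ndarray:
    """Assemble the Metzler rate matrix A(u) for one therapy.

    A[i, i] = g_i(dose) - sum of outgoing mutation rates from i
    A[child, parent] = mu(parent -> child)

    Mutation moves cells between compartments without creating or destroying
    them, so each column sums to the growth rate of its genotype.  Under the
    graph's topological node order A is lower triangular.
    """
    n = len(graph)
    A = np.zeros((n, n))
    for i, g in enumerate(graph.nodes):
        rate = pds.growth_rate(g, environment, therapy)
        A[i, i] = rate - graph.total_outflow(g)
    for parent, child, mu in graph.edges:
        A[graph.index(child), graph.index(parent)] += mu
    return A


def _segment_propagate(
    A: np.ndarray, x0: np.ndarray, rel_times: np.ndarray
) -> np.ndarray:
    """Exact LTI solution x(t) = expm(A t) x0 at each relative time."""
    out = np.empty((len(rel_times), len(x0)))
    with np.errstate(over="ignore", invalid="ignore"):
        for k, t in enumerate(rel_times):
            if t == 0:
                out[k] = x0
            else:
                out[k] = expm(A * t) @ x0
    return out


def simulate_schedule(
    x0: TumorState,
    schedule: TreatmentSchedule,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    output_step: float = 1.0,
) -> Trajectory:
    """Simulate x' = A(u)x under a piecewise-constant treatment schedule.

    Within each segment the system is linear time-invariant and the solution
    is the matrix-exponential closed form, evaluated exactly at each output
    time relative to the segment start.  Counts are clipped at zero only to
    remove negative floating-point dust (the propagator of a Metzler matrix
    is entrywise nonnegative).

    Parameters
    ----------
    output_step:
        Spacing of output times in days; segment boundaries are always
        included.
    """
    if output_step <= 0:
        raise ValueError("output_step must be positive")
    x = x0.vector(graph)
    env = x0.environment
    all_times = [0.0]
    all_counts = [x.copy()]
    t_start = 0.0
    for therapy, duration in schedule.segments:
        A = build_system_matrix(pds, graph, therapy, env)
        n_steps = max(1, math.ceil(duration / output_step - 1e-12))
        rel = np.unique(
            np.append(np.arange(1, n_steps + 1) * output_step, duration)
        )
        rel = rel[rel <= duration + 1e-12]
        rel[-1] = duration
        seg = _segment_propagate(A, x, rel)
        if not np.all(np.isfinite(seg)):
            bad = np.argmax(~np.isfinite(seg).all(axis=1))
            raise SimulationOverflowError(t_start + rel[bad])
        seg = np.clip(seg, 0.0, None)
        all_times.extend(t_start + rel)
        all_counts.extend(seg)
        x = seg[-1].copy()
        t_start += duration
    times = np.asarray(all_times)
    counts = np.vstack(all_counts)
    # drop duplicated boundary points
    keep = np.concatenate(([True], np.diff(times) > 1e-12))
    return Trajectory(times[keep], counts[keep], list(graph.nodes), env, schedule)


def total_population(state_or_row) -> float:
    """Total cell count of a TumorState, mapping, or numeric array."""
    if isinstance(state_or_row, TumorState):
        return state_or_row.total
    if isinstance(state_or_row, Mapping):
        return float(sum(state_or_row.values()))
    return float(np.asarray(state_or_row, dtype=float).sum())
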