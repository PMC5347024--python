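"""Receding-horizon and constrained optimal drug scheduling.

The control problem: over a total horizon T (days), pick one therapy from a
finite panel for each switching-horizon segment of length tau so as to
minimize the tumor cell population.  The receding-horizon solver is greedy
per segment — at each segment start every panel therapy is simulated
forward tau days from the current state and the one minimizing the total
population at segment end is applied; ties are broken by panel declaration
order so results are bit-for-bit reproducible from the configuration.

Two audit paths complement the greedy solver: an exhaustive search over all
schedules with at most k switches on a time grid (the clinically
constrained variant), and full enumeration of every panel assignment (a
testing oracle, guarded by a state-space cap).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from ._errors import ConfigurationError
from .dynamics import (
    MutationGraph,
    PharmacodynamicsTable,
    Therapy,
    TreatmentSchedule,
    Trajectory,
    TumorState,
    build_system_matrix,
    simulate_schedule,
)

__all__ = [
    "ControlProblem",
    "ScheduleSolution",
    "solve_receding_horizon",
    "solve_constrained_switching",
    "enumerate_global_optimum",
]

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS = (30, 15, 10, 5, 3, 1)


@dataclass
class ControlProblem:
    """Specification of the scheduling problem.

    Parameters
    ----------
    T:
        Total treatment horizon in days (default 30).
    tau:
        Switching horizon: the minimum time one therapy must be maintained.
        If tau does not divide T the final segment is truncated.
    panel:
        Candidate therapies, in tie-break priority order.
    objective:
        "end_of_segment_total" (default) minimizes the total population at
        each segment end; "integral_total" minimizes the time-integral of
        the total population over the segment.
    max_switches:
        Cap on the number of therapy changes (None = unlimited).
    switch_grid:
        Allowed switch times for the constrained solver; defaults to
        multiples of tau inside (0, T).
    """

    T: float = 30.0
    tau: float = 30.0
    panel: Sequence[Therapy] = ()
    objective: str = "end_of_segment_total"
    max_switches: int | None = None
    switch_grid: tuple = ()

    def __post_init__(self):
        if not self.panel:
            raise ConfigurationError("therapy panel must be nonempty")
        if self.T <= 0 or self.tau <= 0:
            raise ValueError("horizons must be positive")
        if self.objective not in ("end_of_segment_total", "integral_total"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.max_switches is not None and self.max_switches < 0:
            raise ValueError("max_switches must be >= 0")
        if not self.switch_grid:
            n = math.ceil(self.T / self.tau)
            self.switch_grid = tuple(
                k * self.tau for k in range(1, n) if 0 < k * self.tau < self.T
            )
        for t in self.switch_grid:
            if not (0 < t < self.T):
                raise ValueError(f"switch time {t} outside (0, {self.T})")

    def segment_durations(self) -> list[float]:
        n_full = int(self.T // self.tau)
        durs = [self.tau] * n_full
        rem = self.T - n_full * self.tau
        if rem > 1e-9:
            durs.append(rem)
        return durs


@dataclass
class ScheduleSolution:
    """An optimized schedule, its trajectory, and per-segment objectives."""

    schedule: TreatmentSchedule
    trajectory: Trajectory
    segment_objectives: list = field(default_factory=list)

    @property
    def final_total(self) -> float:
        return self.trajectory.final_total

    @property
    def fold_change(self) -> float:
        return self.trajectory.fold_change

    def to_dict(self) -> dict:
        out, t = [], 0.0
        for therapy, d in self.schedule.segments:
            out.append(
                {
                    "therapy": therapy.name,
                    "start_day": t,
                    "end_day": t + d,
                    "concentrations_uM": dict(therapy.concentrations),
                }
            )
            t += d
        return {"segments": out, "final_total_cells": self.final_total}


class _Propagators:
    """Cache of per-therapy matrices and segment propagators."""

    def __init__(self, problem, pds, graph, environment):
        self.graph = graph
        self.A = {t.name: build_system_matrix(pds, graph, t, environment)
                  for t in problem.panel}
        self._expm_cache: dict[tuple[str, float], np.ndarray] = {}

    def step(self, therapy: Therapy, duration: float) -> np.ndarray:
        key = (therapy.name, round(duration, 12))
        if key not in self._expm_cache:
            self._expm_cache[key] = expm(self.A[therapy.name] * duration)
        return self._expm_cache[key]


def _segment_objective(
    props: _Propagators, therapy: Therapy, x: np.ndarray, duration: float,
    objective: str,
) -> float:
    if objective == "end_of_segment_total":
        return float((props.step(therapy, duration) @ x).sum())
    # integral of total population over the segment, composite Simpson
    n = max(8, int(duration * 4))
    if n % 2:
        n += 1
    ts = np.linspace(0.0, duration, n + 1)
    A = props.A[therapy.name]
    totals = np.array([(expm(A * t) @ x).sum() for t in ts])
    h = duration / n
    return float(h / 3 * (totals[0] + totals[-1]
                          + 4 * totals[1:-1:2].sum() + 2 * totals[2:-1:2].sum()))


def _finalize(
    x0: TumorState,
    therapies: Sequence[Therapy],
    durations: Sequence[float],
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    output_step: float,
    segment_objectives=None,
) -> ScheduleSolution:
    # merge consecutive identical therapies for a tidy schedule, but keep
    # the trajectory sampled at output_step regardless
    segs: list[tuple[Therapy, float]] = []
    for t, d in zip(therapies, durations):
        if segs and segs[-1][0].name == t.name:
            segs[-1] = (t, segs[-1][1] + d)
        else:
            segs.append((t, d))
    schedule = TreatmentSchedule(tuple(segs))
    traj = simulate_schedule(x0, schedule, pds, graph, output_step=output_step)
    return ScheduleSolution(schedule, traj, list(segment_objectives or []))


def solve_receding_horizon(
    x0: TumorState,
    problem: ControlProblem,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    output_step: float = 0.5,
) -> ScheduleSolution:
    """Greedy per-segment minimization over the therapy panel.

    At each successive segment of length tau, every panel therapy is
    simulated from the current state and the one minimizing the objective at
    segment end is selected; the state advances under the winner and the
    procedure repeats until the total horizon is covered.
    """
    props = _Propagators(problem, pds, graph, x0.environment)
    x = x0.vector(graph)
    chosen, values = [], []
    for duration in problem.segment_durations():
        best_idx, best_val = None, None
        for i, therapy in enumerate(problem.panel):
            val = _segment_objective(props, therapy, x, duration, problem.objective)
            if best_val is None or val < best_val - 1e-15:
                best_idx, best_val = i, val
        winner = problem.panel[best_idx]
        chosen.append(winner)
        values.append(best_val)
        x = props.step(winner, duration) @ x
        logger.info(
            "segment t+=%gd: chose %s (objective %.6g, total %.6g cells)",
            duration, winner.name, best_val, float(x.sum()),
        )
    return _finalize(
        x0, chosen, problem.segment_durations(), pds, graph, output_step, values
    )


def _count_switches(names: Sequence[str]) -> int:
    return sum(1 for a, b in zip(names, names[1:]) if a != b)


def solve_constrained_switching(
    x0: TumorState,
    problem: ControlProblem,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    output_step: float = 0.5,
) -> ScheduleSolution:
    """Exhaustive search over schedules with at most ``max_switches`` changes.

    Switches are restricted to ``problem.switch_grid``; every assignment of
    panel therapies to the resulting segments is simulated and the global
    minimizer of the final total population is returned.  Ties are broken by
    (fewer switches, earlier lexicographic panel order).
    """
    k = problem.max_switches
    if k is None:
        raise ConfigurationError("solve_constrained_switching requires max_switches")
    grid = sorted(problem.switch_grid)
    if not grid and k > 0:
        raise ValueError("switch grid is empty but switches are allowed")
    props = _Propagators(problem, pds, graph, x0.environment)
    x_init = x0.vector(graph)
    panel_index = {t.name: i for i, t in enumerate(problem.panel)}

    best = None  # (final_total, n_switches, lex_indices, therapies, durations)
    for s in range(0, k + 1):
        for switch_times in itertools.combinations(grid, s):
            bounds = [0.0, *switch_times, problem.T]
            durations = [b - a for a, b in zip(bounds, bounds[1:])]
            for assign in itertools.product(problem.panel, repeat=s + 1):
                names = [t.name for t in assign]
                if s > 0 and any(a == b for a, b in zip(names, names[1:])):
                    continue  # covered by a smaller-s combination
                x = x_init
                for therapy, d in zip(assign, durations):
                    x = props.step(therapy, d) @ x
                final = float(x.sum())
                key = (
                    final,
                    _count_switches(names),
                    tuple(panel_index[n] for n in names),
                )
                if best is None or key < (best[0], best[1], best[2]):
                    best = (*key, assign, durations)
    final, _, _, assign, durations = best
    return _finalize(x0, assign, durations, pds, graph, output_step)


def enumerate_global_optimum(
    x0: TumorState,
    problem: ControlProblem,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    max_states: int = 10**6,
    output_step: float = 0.5,
) -> ScheduleSolution:
    """Evaluate every full panel assignment; testing oracle for the greedy path.

    Refuses when |panel|^(number of segments) exceeds ``max_states``.  Ties
    are broken by lexicographic panel order.
    """
    durations = problem.segment_durations()
    n_states = len(problem.panel) ** len(durations)
    if n_states > max_states:
        raise ValueError(
            f"{n_states} candidate schedules exceed the guard of {max_states}"
        )
    props = _Propagators(problem, pds, graph, x0.environment)
    x_init = x0.vector(graph)
    best = None
    for idx_assign in itertools.product(range(len(problem.panel)), repeat=len(durations)):
        x = x_init
        for i, d in zip(idx_assign, durations):
            x = props.step(problem.panel[i], d) @ x
        key = (float(x.sum()), idx_assign)
        if best is None or key < best[:2]:
            best = (key[0], idx_assign)
    _, idx_assign = best
    assign = [problem.panel[i] for i in idx_assign]
    return _finalize(x0, assign, durations, pds, graph, output_step)
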