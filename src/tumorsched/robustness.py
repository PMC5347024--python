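"""Robustness of optimized schedules to EGFR TKI dose reductions.

In combination regimens the EGFR TKI is the component most likely to be
dose-reduced for toxicity, so robustness is probed by scaling only the TKI
concentration of every scheduled therapy by (1 - p), leaving partner drugs
at panel dose, and re-simulating the schedule that was optimized at nominal
dose (no re-optimization by default).  Outcomes follow the fold-change
classification: final/initial < 0.7 is response, > 1.2 progression,
otherwise stable.

Because the system matrix is Metzler and the dose-response curves are
nonincreasing in dose, reducing the TKI dose can only increase every
clone's count at every time, so the fold change is nondecreasing in p —
this monotonicity is asserted on every sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    MutationGraph,
    PharmacodynamicsTable,
    Trajectory,
    TreatmentSchedule,
    TumorState,
    simulate_schedule,
)
from .scheduler import DEFAULT_HORIZONS, ControlProblem, solve_receding_horizon

__all__ = [
    "OutcomeRule",
    "classify_outcome",
    "dose_reduction_sweep",
    "max_tolerated_reduction",
    "switching_benefit_table",
]

DEFAULT_REDUCTIONS = tuple(np.round(np.arange(0.0, 0.901, 0.05), 10))


@dataclass(frozen=True)
class OutcomeRule:
    """Fold-change thresholds for response / stability / progression.

    Response shrinks the initial population by more than 30% (fold < 0.7);
    progression grows it by more than 20% (fold > 1.2); anything between is
    stable.  Inequalities are strict: boundary values fall into "stable".
    """

    response_threshold: float = 0.7
    progression_threshold: float = 1.2

    def __post_init__(self):
        if not (self.response_threshold < 1.0 < self.progression_threshold):
            raise ValueError("thresholds must satisfy response < 1 < progression")

    def classify(self, fold_change: float) -> str:
        if fold_change < self.response_threshold:
            return "response"
        if fold_change > self.progression_threshold:
            return "progression"
        return "stable"


def classify_outcome(
    x0: TumorState, trajectory: Trajectory, rule: OutcomeRule = OutcomeRule()
) -> str:
    """Outcome label of a completed trajectory relative to the initial total."""
    initial = x0.total
    if initial <= 0:
        raise ValueError("initial population must be positive")
    return rule.classify(trajectory.final_total / initial)


def dose_reduction_sweep(
    schedule: TreatmentSchedule,
    x0: TumorState,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    reductions: Sequence[float] = DEFAULT_REDUCTIONS,
    rule: OutcomeRule = OutcomeRule(),
    output_step: float = 1.0,
) -> pd.DataFrame:
    """Simulate a fixed schedule under a grid of EGFR TKI dose reductions.

    For each reduction fraction p the TKI concentration of every segment is
    scaled by (1 - p) — partner drugs unchanged — and the fold change and
    outcome are recorded.  The schedule is the one optimized at nominal
    dose; it is deliberately not re-optimized.

    Returns a DataFrame with columns reduction, fold_change, outcome;
    raises if the recorded fold changes are not nondecreasing in p (which
    would indicate a non-monotone configured dose-response).
    """
    rows = []
    for p in reductions:
        if not (0.0 <= p < 1.0):
            raise ValueError(f"reduction fraction {p} outside [0, 1)")
        perturbed = schedule.scale_tki_dose(1.0 - p)
        traj = simulate_schedule(x0, perturbed, pds, graph, output_step=output_step)
        fold = traj.final_total / x0.total
        rows.append({"reduction": float(p), "fold_change": fold,
                     "outcome": rule.classify(fold)})
    df = pd.DataFrame(rows).sort_values("reduction", ignore_index=True)
    folds = df["fold_change"].to_numpy()
    if np.any(np.diff(folds) < -1e-9 * np.maximum(folds[:-1], 1.0)):
        raise RuntimeError(
            "fold change decreased under dose reduction; "
            "configured dose-response curves are not monotone"
        )
    return df


def max_tolerated_reduction(
    schedule: TreatmentSchedule,
    x0: TumorState,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    criterion: str = "reduction",
    grid_step: float = 0.05,
    max_reduction: float = 0.9,
    rule: OutcomeRule = OutcomeRule(),
) -> tuple[float, bool]:
    """Largest dose-reduction fraction still meeting an efficacy criterion.

    criterion "reduction": final total below the initial total (any tumor
    shrinkage); criterion "response": fold change below the response
    threshold (default 0.7).  By sweep monotonicity the returned grid value
    is the tolerance boundary up to one grid step.

    Returns (fraction, ok_at_zero); ``ok_at_zero`` is False when the
    criterion already fails with no reduction, in which case 0.0 is
    returned with that warning flag.
    """
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    if criterion not in ("reduction", "response"):
        raise ValueError(f"unknown criterion {criterion!r}")
    grid = np.round(np.arange(0.0, max_reduction + 1e-9, grid_step), 10)
    table = dose_reduction_sweep(schedule, x0, pds, graph, reductions=grid, rule=rule)
    limit = 1.0 if criterion == "reduction" else rule.response_threshold
    ok = table["fold_change"].to_numpy() < limit
    if not ok[0]:
        return 0.0, False
    last = int(np.max(np.nonzero(ok)))
    # monotonicity makes the passing set a prefix; take the largest passing p
    return float(table["reduction"].iloc[last]), True


def switching_benefit_table(
    scenarios: Iterable,
    pds: PharmacodynamicsTable,
    graph: MutationGraph,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    T: float = 30.0,
    objective: str = "end_of_segment_total",
    output_step: float = 1.0,
) -> pd.DataFrame:
    """Fold-change benefit of switching across horizons, per scenario.

    For each scenario (anything exposing ``name``, ``initial_state()`` and
    ``panel``) and each switching horizon tau, the receding-horizon problem
    is solved, the winning schedule simulated, and the final/initial fold
    change recorded.  Fold changes are also normalized by the constant
    (tau = T) strategy's fold change, and summed across horizons per
    scenario — small sums mean switching helps.

    Columns: scenario, n_subclones, horizon_days, fold_change,
    normalized_fold_change, fold_change_sum.
    """
    horizons = list(horizons)
    if T not in horizons:
        horizons = [T, *horizons]
    rows = []
    for sc in scenarios:
        x0 = sc.initial_state()
        folds = {}
        for tau in horizons:
            problem = ControlProblem(T=T, tau=tau, panel=tuple(sc.panel),
                                     objective=objective)
            try:
                sol = solve_receding_horizon(x0, problem, pds, graph,
                                             output_step=output_step)
            except Exception as err:
                raise RuntimeError(
                    f"scheduling failed for scenario {sc.name!r}, tau={tau}"
                ) from err
            folds[tau] = sol.fold_change
        constant_fold = folds[T]
        fold_sum = float(sum(folds.values()))
        n_subclones = sum(1 for c in x0.counts.values() if c > 0)
        for tau in horizons:
            rows.append(
                {
                    "scenario": sc.name,
                    "n_subclones": n_subclones,
                    "horizon_days": float(tau),
                    "fold_change": folds[tau],
                    "normalized_fold_change": folds[tau] / constant_fold,
                    "fold_change_sum": fold_sum,
                }
            )
    return pd.DataFrame(rows)
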