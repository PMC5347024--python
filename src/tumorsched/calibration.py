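"""Parameter estimation from growth/viability assays.

Calibration is two-stage: (1) the net per-day growth rate of each
(clone, environment, therapy, dose) condition is the least-squares slope of
ln(cell count) against time across replicates; (2) a four-parameter Hill
curve (g0, gmin, ec50, hill) is fitted to the per-dose rates by bounded
nonlinear least squares with deterministic multi-start.  The two stages are
independently testable and mirror how growth rates are read off exponential
assay data in practice.

Single end-point viability readouts (e.g. a 72 h viability ratio) can be
converted to net rates via ln(treated/untreated)/t plus the untreated
growth rate; such rates are flagged as endpoint-derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._errors import FitConvergenceError, InsufficientDataError
from .dynamics import ClonePharmacodynamics, Environment, Genotype

__all__ = [
    "GrowthAssayRecord",
    "RateEstimate",
    "DoseResponseFit",
    "estimate_net_growth_rates",
    "fit_dose_response",
    "rate_from_endpoint_viability",
    "calibrate_condition",
]

HILL_BOUNDS = (0.2, 5.0)
EC50_BOUNDS = (1e-4, 1e3)


@dataclass(frozen=True)
class GrowthAssayRecord:
    """One well measurement of a growth assay."""

    genotype: Genotype
    environment: Environment
    therapy_name: str
    tki_concentration: float  # uM
    time: float  # days
    replicate: int
    cell_count: float  # cells (or normalized viability signal)

    def __post_init__(self):
        if self.cell_count <= 0:
            raise ValueError("cell_count must be positive")
        if self.time < 0:
            raise ValueError("time must be nonnegative")


@dataclass(frozen=True)
class RateEstimate:
    """Net growth rate estimate with its standard error (per day)."""

    rate: float
    stderr: float
    n_obs: int
    endpoint_derived: bool = False


def estimate_net_growth_rates(
    records: Iterable[GrowthAssayRecord] | pd.DataFrame,
) -> RateEstimate:
    """Slope of ln(count) vs time by least squares across replicates.

    Exact for noiseless exponential data.  Requires at least two distinct
    time points; all counts must be positive.
    """
    if isinstance(records, pd.DataFrame):
        times = records["time_days"].to_numpy(dtype=float)
        counts = records["cell_count"].to_numpy(dtype=float)
    else:
        records = list(records)
        times = np.array([r.time for r in records], dtype=float)
        counts = np.array([r.cell_count for r in records], dtype=float)
    if np.any(counts <= 0):
        raise ValueError("cell counts must be positive for log-linear rate estimation")
    if len(np.unique(times)) < 2:
        raise InsufficientDataError(
            "need at least two distinct time points to estimate a growth rate"
        )
    y = np.log(counts)
    res = stats.linregress(times, y)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return RateEstimate(rate=float(res.slope), stderr=stderr, n_obs=len(times))


def rate_from_endpoint_viability(
    viability_ratio: float, assay_duration: float, untreated_rate: float
) -> RateEstimate:
    """Convert a single end-point viability ratio to a net growth rate.

    A treated/untreated signal ratio v after time t implies a rate
    difference ln(v)/t relative to the untreated net rate.
    """
    if viability_ratio <= 0:
        raise ValueError("viability ratio must be positive")
    if assay_duration <= 0:
        raise ValueError("assay duration must be positive")
    rate = untreated_rate + np.log(viability_ratio) / assay_duration
    return RateEstimate(rate=float(rate), stderr=np.nan, n_obs=1, endpoint_derived=True)


@dataclass
class DoseResponseFit:
    """Result of the Hill-curve fit: parameters plus the residual norm."""

    pharmacodynamics: ClonePharmacodynamics
    residual_norm: float
    n_doses: int


def _hill(params: np.ndarray, doses: np.ndarray) -> np.ndarray:
    g0, delta, log_ec50, hill = params
    gmin = g0 - delta
    ec50 = np.exp(log_ec50)
    with np.errstate(divide="ignore"):
        ratio = np.where(doses > 0, (doses / ec50) ** hill, 0.0)
    return gmin + (g0 - gmin) / (1.0 + ratio)


def fit_dose_response(
    doses: Sequence[float],
    rates: Sequence[float],
    genotype: Genotype | None = None,
    environment: Environment | None = None,
    therapy_name: str = "",
    seed: int = 0,
    n_starts: int = 5,
) -> DoseResponseFit:
    """Fit (g0, gmin, ec50, hill) to per-dose net growth rates.

    Bounded nonlinear least squares over the parametrization
    (g0, delta = g0 - gmin >= 0, log ec50, hill in [0.2, 5]), which encodes
    the constraint gmin <= g0 exactly.  Five deterministic starting points
    (seeded) guard against local minima; the best residual wins, ties broken
    by the lowest ec50.  Noiseless data generated from the model are
    recovered to well below 1e-6 in the rates.
    """
    doses = np.asarray(doses, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if doses.shape != rates.shape:
        raise ValueError("doses and rates must have equal length")
    if len(np.unique(doses)) < 4:
        raise InsufficientDataError("need at least 4 distinct dose levels including 0")
    if 0.0 not in doses:
        raise InsufficientDataError("dose-response fit requires a zero-dose condition")

    g0_init = float(rates[doses == 0].mean())
    gmin_init = float(rates[doses == doses.max()].mean())
    span = max(rates.max() - rates.min(), 1e-3)
    positive_doses = doses[doses > 0]
    ec50_guess = float(np.median(positive_doses))

    rng = np.random.default_rng(seed)
    starts = [
        np.array([g0_init, max(g0_init - gmin_init, 1e-6), np.log(ec50_guess), 1.0])
    ]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    g0_init + 0.1 * span * rng.standard_normal(),
                    max(g0_init - gmin_init, 1e-6) * np.exp(rng.standard_normal()),
                    np.log(ec50_guess) + rng.standard_normal(),
                    float(rng.uniform(*HILL_BOUNDS)),
                ]
            )
        )

    lo = np.array([-np.inf, 0.0, np.log(EC50_BOUNDS[0]), HILL_BOUNDS[0]])
    hi = np.array([np.inf, np.inf, np.log(EC50_BOUNDS[1]), HILL_BOUNDS[1]])

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            sol = optimize.least_squares(
                lambda p: _hill(p, doses) - rates,
                p0,
                bounds=(lo, hi),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        cost = float(np.linalg.norm(sol.fun))
        ec50 = float(np.exp(sol.x[2]))
        key = (round(cost, 12), ec50)
        if best is None or key < best[0]:
            best = (key, sol.x, cost)
    if best is None:
        raise FitConvergenceError(
            f"dose-response fit failed to converge for {therapy_name or 'condition'}; "
            f"doses={doses.tolist()}, rates={rates.tolist()}"
        )
    _, x, cost = best
    g0, delta, log_ec50, hill = x
    pd_ = ClonePharmacodynamics(
        genotype=genotype or Genotype(frozenset({"L858R"})),
        environment=environment or Environment(),
        therapy_name=therapy_name,
        g0=float(g0),
        gmin=float(g0 - delta),
        ec50=float(np.exp(log_ec50)),
        hill=float(hill),
    )
    return DoseResponseFit(pd_, residual_norm=cost, n_doses=len(np.unique(doses)))


def calibrate_condition(
    records: Iterable[GrowthAssayRecord], seed: int = 0
) -> DoseResponseFit:
    """Full two-stage calibration for one (genotype, environment, therapy).

    Groups records by TKI dose, estimates a rate per dose, then fits the
    Hill curve to the rates.
    """
    records = list(records)
    if not records:
        raise InsufficientDataError("no assay records supplied")
    genotype = records[0].genotype
    environment = records[0].environment
    therapy = records[0].therapy_name
    by_dose: dict[float, list[GrowthAssayRecord]] = {}
    for r in records:
        by_dose.setdefault(r.tki_concentration, []).append(r)
    doses = sorted(by_dose)
    rates = [estimate_net_growth_rates(by_dose[d]).rate for d in doses]
    return fit_dose_response(
        doses, rates, genotype=genotype, environment=environment,
        therapy_name=therapy, seed=seed,
    )
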