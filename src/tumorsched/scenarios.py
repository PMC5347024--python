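"""Built-in scenarios, synthetic parameter/assay generation, and config I/O.

Three study scenarios ship with the package:

* ``patient_pretreatment`` — the clinical composition at diagnosis: 94%
  EGFR-L858R, 6% L858R+BRAF-V600E, and 0.01% each of three MET-amplified
  variants (of L858R, of L858R+V600E and of L858R+T790M), treated with
  1 uM erlotinib monotherapy.
* ``invitro_heterogeneous_hgf`` — 89% L858R, 10% L858R+V600E, 1%
  L858R+T790M, HGF-stimulated (MET-activated environment).
* ``invitro_simple`` — 90% L858R, 10% L858R+T790M, HGF-stimulated.

The in-vitro scenarios carry the six-combination panel: 1.5 uM erlotinib or
0.5 uM afatinib with 0.5 uM crizotinib, 0.5 uM trametinib or 5 uM
vemurafenib.

The shipped pharmacodynamics table is SYNTHETIC: a rule-based stand-in
constructed from the qualitative pharmacology of these alterations (see
``reference_pharmacodynamics``), not a transcription of fitted assay
parameters.  A scenario config file can supply a measured table in its
place.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError
from .calibration import GrowthAssayRecord
from .dynamics import (
    ALTERATIONS,
    ClonePharmacodynamics,
    Environment,
    Genotype,
    MutationGraph,
    PharmacodynamicsTable,
    Therapy,
    TumorState,
    evaluate_growth_rate,
)

__all__ = [
    "Scenario",
    "egfr_lattice",
    "paper_panel",
    "reference_pharmacodynamics",
    "load_paper_scenarios",
    "generate_synthetic_pharmacodynamics",
    "generate_synthetic_assay",
    "assay_records_to_dataframe",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
]

logger = logging.getLogger(__name__)

DEFAULT_MUTATION_RATE = 1e-6  # per day; acquisition of one alteration
DEFAULT_TOTAL_CELLS = 5000.0  # seeding density of the growth assays

EGFR_TKIS = ("erlotinib", "afatinib")
PARTNER_DOSES = {"crizotinib": 0.5, "trametinib": 0.5, "vemurafenib": 5.0}
TKI_DOSES = {"erlotinib": 1.5, "afatinib": 0.5}


@dataclass
class Scenario:
    """A named study condition: graph, environment, composition and panel."""

    name: str
    graph: MutationGraph
    environment: Environment
    composition: dict  # Genotype -> fraction
    total_cells: float = DEFAULT_TOTAL_CELLS
    panel: tuple = ()
    pds: PharmacodynamicsTable | None = None

    def __post_init__(self):
        for g in self.composition:
            if g not in self.graph:
                raise ConfigurationError(
                    f"scenario {self.name}: composition genotype {g.name} not in graph"
                )
        s = sum(self.composition.values())
        if abs(s - 1.0) > 1e-9:
            if abs(s - 1.0) > 1e-6:
                warnings.warn(
                    f"scenario {self.name}: fractions sum to {s:.6g}; renormalizing",
                    stacklevel=2,
                )
            self.composition = {g: f / s for g, f in self.composition.items()}

    @property
    def n_subclones(self) -> int:
        return sum(1 for f in self.composition.values() if f > 0)

    def initial_state(self) -> TumorState:
        return TumorState(
            {g: f * self.total_cells for g, f in self.composition.items()},
            self.environment,
        )


def genotype(*alterations: str) -> Genotype:
    """Convenience constructor: genotype("L858R", "T790M")."""
    return Genotype(frozenset(alterations))


def egfr_lattice(
    resistance_alterations: Sequence[str] = ("V600E", "T790M", "METamp"),
    mu: float = DEFAULT_MUTATION_RATE,
) -> MutationGraph:
    """Acquisition lattice rooted at the EGFR-L858R founder.

    Nodes are L858R plus every subset of the given resistance alterations;
    each edge adds one alteration at rate ``mu`` per day.
    """
    extras = list(resistance_alterations)
    nodes = []
    for r in range(len(extras) + 1):
        for combo in itertools.combinations(extras, r):
            nodes.append(genotype("L858R", *combo))
    edges = []
    for g in nodes:
        for a in extras:
            if a not in g.alterations:
                child = Genotype(g.alterations | {a})
                edges.append((g, child, mu))
    return MutationGraph(nodes, edges)


def paper_panel() -> tuple:
    """The six clinically dosed two-drug combinations.

    1.5 uM erlotinib or 0.5 uM afatinib, each combined with 0.5 uM
    crizotinib, 0.5 uM trametinib or 5 uM vemurafenib.
    """
    panel = []
    for tki in EGFR_TKIS:
        for partner, pdose in PARTNER_DOSES.items():
            name = f"{tki[:3].upper()}+{partner[:3].upper()}"
            panel.append(
                Therapy(
                    name=name,
                    concentrations=((tki, TKI_DOSES[tki]), (partner, pdose)),
                    tki_drug=tki,
                )
            )
    return tuple(panel)


def erlotinib_monotherapy(dose: float = 1.0) -> Therapy:
    return Therapy("erlotinib", (("erlotinib", dose),), "erlotinib")


# ---------------------------------------------------------------------------
# Rule-based reference pharmacodynamics (synthetic stand-in)
# ---------------------------------------------------------------------------

_KILL_RATE = -0.45  # per day, saturating TKI with all bypass routes blocked
_BASE_GROWTH = 0.30  # per day, drug-free founder clone
_FITNESS_COST = 0.01  # per extra alteration
_MET_BOOST = 0.02  # MET activation growth advantage
_OFF_TARGET = 0.02  # residual effect on uncovered clones
_EC50_COVERED = 0.15  # uM
_EC50_UNCOVERED = 1.0  # uM (slope is irrelevant when gmin ~ g0)
_HILL = 1.5


def _met_active(g: Genotype, env: Environment) -> bool:
    return "METamp" in g.alterations or env.hgf


def _covered(g: Genotype, env: Environment, therapy: Therapy) -> bool:
    """Does the combination neutralize every active growth route of the clone?

    EGFR axis: erlotinib is defeated by the T790M gatekeeper mutation;
    afatinib retains activity against T790M.  BRAF-V600E bypass requires
    vemurafenib or the downstream MEK inhibitor trametinib.  MET activation
    (METamp or HGF) requires crizotinib; MEK inhibition suffices only in
    clones whose signaling is already MAPK-rewired (V600E or T790M) —
    MET-activated founder cells escape through PI3K/AKT as well.
    """
    drugs = dict(therapy.concentrations)
    tki = therapy.tki_drug
    if drugs.get(tki, 0.0) <= 0:
        return False
    if tki == "erlotinib" and "T790M" in g.alterations:
        return False
    if "V600E" in g.alterations and not (
        "vemurafenib" in drugs or "trametinib" in drugs
    ):
        return False
    if _met_active(g, env):
        mapk_rewired = bool({"V600E", "T790M"} & g.alterations)
        if not ("crizotinib" in drugs or ("trametinib" in drugs and mapk_rewired)):
            return False
    return True


def _drug_free_rate(g: Genotype, env: Environment) -> float:
    n_extra = len(g.alterations) - 1
    return _BASE_GROWTH - _FITNESS_COST * n_extra + (
        _MET_BOOST if _met_active(g, env) else 0.0
    )


def reference_pharmacodynamics(
    graph: MutationGraph,
    therapies: Iterable[Therapy],
    environments: Sequence[Environment] = (Environment(False), Environment(True)),
) -> PharmacodynamicsTable:
    """Synthetic rule-based dose-response table for the built-in scenarios.

    Each (clone, environment, therapy) entry is derived from the coverage
    rule in ``_covered``: when the combination neutralizes every active
    route, saturating TKI yields net kill (gmin = -0.45/day); otherwise the
    clone is essentially insensitive (gmin = g0 - 0.02).  Drug-free rates
    carry a small fitness cost per alteration and a growth boost under MET
    activation.  This table is a synthetic stand-in constructed for
    qualitative realism, not a set of measured assay fits; supply a
    calibrated table through the scenario config for quantitative work.
    """
    table = PharmacodynamicsTable()
    for env in environments:
        for g in graph.nodes:
            g0 = _drug_free_rate(g, env)
            for t in therapies:
                if _covered(g, env, t):
                    entry = ClonePharmacodynamics(
                        g, env, t.name, g0=g0, gmin=_KILL_RATE,
                        ec50=_EC50_COVERED, hill=_HILL,
                    )
                else:
                    entry = ClonePharmacodynamics(
                        g, env, t.name, g0=g0, gmin=g0 - _OFF_TARGET,
                        ec50=_EC50_UNCOVERED, hill=_HILL,
                    )
                table.add(entry)
    return table


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

def load_paper_scenarios() -> list[Scenario]:
    """The three built-in study scenarios with panel and synthetic parameters."""
    scenarios = []

    # Patient at diagnosis: lattice over all three resistance alterations;
    # the three MET-amplified variants each pre-exist at 0.01% of the total,
    # remaining mass split 94/6; the vector is renormalized.
    patient_graph = egfr_lattice(("V600E", "T790M", "METamp"))
    patient_env = Environment(hgf=False)
    patient_therapies = (*paper_panel(), erlotinib_monotherapy(1.0))
    patient_comp = {
        genotype("L858R"): 0.94,
        genotype("L858R", "V600E"): 0.06,
        genotype("L858R", "METamp"): 0.0001,
        genotype("L858R", "V600E", "METamp"): 0.0001,
        genotype("L858R", "T790M", "METamp"): 0.0001,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scenarios.append(
            Scenario(
                name="patient_pretreatment",
                graph=patient_graph,
                environment=patient_env,
                composition=patient_comp,
                total_cells=DEFAULT_TOTAL_CELLS,
                panel=patient_therapies,
                pds=reference_pharmacodynamics(patient_graph, patient_therapies),
            )
        )

    # In-vitro cell-line mixtures: MET activation is environmental (HGF),
    # so the lattice spans only the V600E / T790M alterations.
    invitro_graph = egfr_lattice(("V600E", "T790M"))
    panel = paper_panel()
    invitro_pds = reference_pharmacodynamics(invitro_graph, panel)
    scenarios.append(
        Scenario(
            name="invitro_heterogeneous_hgf",
            graph=invitro_graph,
            environment=Environment(hgf=True),
            composition={
                genotype("L858R"): 0.89,
                genotype("L858R", "V600E"): 0.10,
                genotype("L858R", "T790M"): 0.01,
            },
            panel=panel,
            pds=invitro_pds,
        )
    )
    scenarios.append(
        Scenario(
            name="invitro_simple",
            graph=invitro_graph,
            environment=Environment(hgf=True),
            composition={
                genotype("L858R"): 0.90,
                genotype("L858R", "T790M"): 0.10,
            },
            panel=panel,
            pds=invitro_pds,
        )
    )
    return scenarios


def get_scenario(name: str) -> Scenario:
    for sc in load_paper_scenarios():
        if sc.name == name:
            return sc
    raise KeyError(f"unknown built-in scenario {name!r}")


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

#: Resistance motif: alteration -> predicate(therapy drugs, tki) that is True
#: when the therapy fails to address the alteration.
def _motif_insensitive(g: Genotype, therapy: Therapy) -> bool:
    drugs = dict(therapy.concentrations)
    if "T790M" in g.alterations and therapy.tki_drug == "erlotinib":
        return True
    if "V600E" in g.alterations and not (
        "vemurafenib" in drugs or "trametinib" in drugs
    ):
        return True
    if "METamp" in g.alterations and "crizotinib" not in drugs:
        return True
    return False


def generate_synthetic_pharmacodynamics(
    seed: int,
    graph: MutationGraph,
    panel: Iterable[Therapy],
    environments: Sequence[Environment] = (Environment(False), Environment(True)),
    resistance_motif: bool = False,
) -> PharmacodynamicsTable:
    """Random but reproducible dose-response parameters per condition.

    Draws, per (genotype, environment, therapy): g0 ~ U[0.05, 0.3]/day,
    gmin ~ U[-0.3, min(0.1, g0)]/day, ec50 ~ U[0.05, 2] uM, hill ~
    U[0.5, 3].  With ``resistance_motif=True`` each alteration confers
    insensitivity to a designated therapy class (T790M to erlotinib-based
    combos, V600E unless a BRAF/MEK inhibitor is present, METamp unless
    crizotinib is present): for such pairs gmin is clamped to be
    nonnegative, so the clone cannot be killed by that therapy.
    """
    rng = np.random.default_rng(seed)
    table = PharmacodynamicsTable()
    for env in environments:
        for g in graph.nodes:
            for t in panel:
                g0 = rng.uniform(0.05, 0.3)
                gmin = rng.uniform(-0.3, min(0.1, g0))
                ec50 = rng.uniform(0.05, 2.0)
                hill = rng.uniform(0.5, 3.0)
                if resistance_motif and _motif_insensitive(g, t):
                    gmin = max(gmin, 0.0)
                    g0 = max(g0, gmin)
                table.add(
                    ClonePharmacodynamics(g, env, t.name, g0=g0, gmin=gmin,
                                          ec50=ec50, hill=hill)
                )
    return table


def generate_synthetic_assay(
    pds: PharmacodynamicsTable,
    doses: Sequence[float],
    times: Sequence[float],
    replicates: int,
    noise_sd: float,
    seed: int,
    x0: float = DEFAULT_TOTAL_CELLS,
) -> list[GrowthAssayRecord]:
    """Exponential-growth assay readouts under Hill-type drug inhibition.

    For every pharmacodynamics entry, dose and time point, the noiseless
    count is x0 * exp(g(dose) * t); each replicate is multiplied by
    lognormal noise exp(noise_sd * z), z ~ N(0, 1).  ``noise_sd = 0`` gives
    exact model data; a fixed seed reproduces the records exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    records = []
    for entry in pds:
        for dose in doses:
            rate = evaluate_growth_rate(entry, dose)
            for t in times:
                mean = x0 * np.exp(rate * t)
                for rep in range(replicates):
                    noise = np.exp(noise_sd * rng.standard_normal()) if noise_sd else 1.0
                    records.append(
                        GrowthAssayRecord(
                            genotype=entry.genotype,
                            environment=entry.environment,
                            therapy_name=entry.therapy_name,
                            tki_concentration=float(dose),
                            time=float(t),
                            replicate=rep,
                            cell_count=float(mean * noise),
                        )
                    )
    return records


def assay_records_to_dataframe(records: Iterable[GrowthAssayRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genotype": r.genotype.name,
                "environment": r.environment.label,
                "therapy": r.therapy_name,
                "tki_concentration_uM": r.tki_concentration,
                "time_days": r.time,
                "replicate": r.replicate,
                "cell_count": r.cell_count,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Config serialization (YAML primary, JSON accepted)
# ---------------------------------------------------------------------------

def _genotype_to_str(g: Genotype) -> str:
    ordered = [a for a in ALTERATIONS if a in g.alterations]
    ordered += sorted(g.alterations.difference(ALTERATIONS))
    return "+".join(ordered)


def _genotype_from_str(s: str) -> Genotype:
    return Genotype(frozenset(p for p in s.split("+") if p))


def scenario_to_dict(sc: Scenario) -> dict:
    return {
        "name": sc.name,
        "environment": {"hgf": sc.environment.hgf},
        "total_cells": sc.total_cells,
        "genotypes": [_genotype_to_str(g) for g in sc.graph.nodes],
        "edges": [
            {"parent": _genotype_to_str(p), "child": _genotype_to_str(c),
             "rate_per_day": mu}
            for p, c, mu in sc.graph.edges
        ],
        "composition": {
            _genotype_to_str(g): f for g, f in sc.composition.items()
        },
        "panel": [
            {
                "name": t.name,
                "concentrations_uM": dict(t.concentrations),
                "tki_drug": t.tki_drug,
            }
            for t in sc.panel
        ],
        "pharmacodynamics": [
            {
                "genotype": _genotype_to_str(e.genotype),
                "hgf": e.environment.hgf,
                "therapy": e.therapy_name,
                "g0_per_day": e.g0,
                "gmin_per_day": e.gmin,
                "ec50_uM": e.ec50,
                "hill": e.hill,
            }
            for e in (sc.pds or ())
        ],
    }


def scenario_from_dict(d: dict) -> Scenario:
    nodes = [_genotype_from_str(s) for s in d["genotypes"]]
    edges = [
        (_genotype_from_str(e["parent"]), _genotype_from_str(e["child"]),
         float(e["rate_per_day"]))
        for e in d.get("edges", [])
    ]
    graph = MutationGraph(nodes, edges)
    env = Environment(hgf=bool(d.get("environment", {}).get("hgf", False)))
    panel = tuple(
        Therapy(
            name=t["name"],
            concentrations=tuple(t["concentrations_uM"].items()),
            tki_drug=t["tki_drug"],
        )
        for t in d.get("panel", [])
    )
    pds = PharmacodynamicsTable(
        ClonePharmacodynamics(
            _genotype_from_str(e["genotype"]),
            Environment(hgf=bool(e["hgf"])),
            e["therapy"],
            g0=float(e["g0_per_day"]),
            gmin=float(e["gmin_per_day"]),
            ec50=float(e["ec50_uM"]),
            hill=float(e["hill"]),
        )
        for e in d.get("pharmacodynamics", [])
    )
    return Scenario(
        name=d["name"],
        graph=graph,
        environment=env,
        composition={
            _genotype_from_str(g): float(f) for g, f in d["composition"].items()
        },
        total_cells=float(d.get("total_cells", DEFAULT_TOTAL_CELLS)),
        panel=panel,
        pds=pds if len(pds) else None,
    )


def save_scenario(sc: Scenario, path) -> None:
    d = scenario_to_dict(sc)
    path = str(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(d, fh, sort_keys=True)


def load_scenario(path) -> Scenario:
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        if path.endswith(".json"):
            d = json.load(fh)
        else:
            d = yaml.safe_load(fh)
    return scenario_from_dict(d)
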