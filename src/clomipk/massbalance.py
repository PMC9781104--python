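"""Pathway-contribution accounting from extended-horizon simulations.

Route fractions are ratios of cumulative reaction fluxes (plus renal
excretion) to the total amount of a compound eliminated; cumulative
metabolite yields multiply route fractions along all directed paths of the
network.  Bioavailability is read from the engine's first-pass tracer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .engine import SimulationResult
from .network import UNDEFINED_METABOLITE

__all__ = [
    "PathwayReport",
    "InsufficientEliminationError",
    "pathway_fractions",
    "cumulative_yield",
    "yield_decomposition",
    "bioavailability",
    "urinary_fraction",
]

log = logging.getLogger(__name__)

RENAL_ROUTE = "renal"


class InsufficientEliminationError(RuntimeError):
    pass


@dataclass
class PathwayReport:
    """Elimination-route shares per compound plus dose-level fractions."""

    dosed_compound: str
    dose_umol: float
    fraction_absorbed: float
    route_fractions: dict[str, dict[str, float]]  # compound -> route -> share
    enzyme_fractions: dict[str, dict[str, float]]  # compound -> catalyst -> share
    #: route id -> (substrate, product, catalyst); RENAL_ROUTE omitted
    route_topology: dict[str, tuple[str, str, str]]
    bioavailability: dict[str, float] = field(default_factory=dict)
    urinary_permille: dict[str, float] = field(default_factory=dict)
    metabolite_yield: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dosed_compound": self.dosed_compound,
            "dose_umol": self.dose_umol,
            "fraction_absorbed": self.fraction_absorbed,
            "route_fractions": self.route_fractions,
            "enzyme_fractions": self.enzyme_fractions,
            "bioavailability": self.bioavailability,
            "urinary_permille": self.urinary_permille,
            "metabolite_yield": self.metabolite_yield,
        }


def _dosed_victim(result: SimulationResult) -> str:
    victims = [
        cid
        for cid in result.dosed_umol
        if not result.network.compound(cid).is_perpetrator
    ]
    if len(victims) != 1:
        raise ValueError(
            f"expected exactly one dosed victim compound, got {victims!r}"
        )
    return victims[0]


def pathway_fractions(
    result: SimulationResult,
    min_eliminated: float = 0.999,
) -> PathwayReport:
    """Elimination-route fractions at the end of the simulation.

    Requires the dose to be >= ``min_eliminated`` eliminated (otherwise the
    cumulative fluxes are biased towards fast routes); run the simulation on
    an extended horizon (default scenarios use 2000 h).
    """
    victim = _dosed_victim(result)
    dose = result.dosed_umol[victim]
    body_slots = ("gut_lumen", "gut_wall", "liver", "kidney", "rest", "arterial", "venous")
    remaining = 0.0
    for cid in result.compounds:
        if result.network.compound(cid).is_perpetrator:
            continue
        for slot in body_slots:
            remaining += result.amounts[cid][slot][-1]
    absorbed = dose - result.amounts[victim]["unabsorbed"][-1]
    if absorbed > 0 and remaining > (1.0 - min_eliminated) * absorbed:
        raise InsufficientEliminationError(
            f"only {(1 - remaining / absorbed) * 100:.2f}% of the absorbed dose "
            f"eliminated; extend the simulation horizon"
        )

    route_fractions: dict[str, dict[str, float]] = {}
    enzyme_fractions: dict[str, dict[str, float]] = {}
    topology: dict[str, tuple[str, str, str]] = {}
    for cid in result.compounds:
        spec = result.network.compound(cid)
        if spec.is_perpetrator:
            continue
        routes: dict[str, float] = {}
        for rxn in result.network.reactions_of(cid):
            routes[rxn.id] = float(result.reaction_flux[rxn.id][-1])
            topology[rxn.id] = (rxn.substrate, rxn.product, rxn.catalyst)
        if spec.renal_excretion:
            routes[RENAL_ROUTE] = float(result.amounts[cid]["urine"][-1])
        eliminated = sum(routes.values())
        if eliminated <= 0:
            route_fractions[cid] = {}
            enzyme_fractions[cid] = {}
            continue
        fractions = {rid: flux / eliminated for rid, flux in routes.items()}
        route_fractions[cid] = fractions
        agg: dict[str, float] = {}
        for rid, frac in fractions.items():
            catalyst = RENAL_ROUTE if rid == RENAL_ROUTE else topology[rid][2]
            agg[catalyst] = agg.get(catalyst, 0.0) + frac
        enzyme_fractions[cid] = agg

    report = PathwayReport(
        dosed_compound=victim,
        dose_umol=dose,
        fraction_absorbed=absorbed / dose if dose > 0 else 0.0,
        route_fractions=route_fractions,
        enzyme_fractions=enzyme_fractions,
        route_topology=topology,
    )
    for cid in result.compounds:
        spec = result.network.compound(cid)
        if spec.is_perpetrator:
            continue
        if cid in result.first_pass and cid in result.dosed_umol:
            report.bioavailability[cid] = bioavailability(result, cid)
        report.urinary_permille[cid] = urinary_fraction(result, cid)
        if cid != victim:
            report.metabolite_yield[cid] = cumulative_yield(report, victim, cid)
    return report


def yield_decomposition(
    report: PathwayReport, source: str, target: str
) -> list[tuple[tuple[str, ...], float]]:
    """All directed paths source -> target with their dose-fraction
    contributions (products of route fractions along the path, times the
    fraction absorbed)."""
    paths: list[tuple[tuple[str, ...], float]] = []

    def walk(compound: str, fraction: float, visited: tuple[str, ...]) -> None:
        for rid, share in report.route_fractions.get(compound, {}).items():
            if rid == RENAL_ROUTE or share == 0.0:
                continue
            _, product, _ = report.route_topology[rid]
            if product == UNDEFINED_METABOLITE:
                continue
            contribution = fraction * share
            path = visited + (product,)
            if product == target:
                paths.append((path, contribution))
            elif product not in visited:  # the network is a DAG; guard anyway
                walk(product, contribution, path)

    walk(source, report.fraction_absorbed, (source,))
    return paths


def cumulative_yield(report: PathwayReport, source: str, target: str) -> float:
    """Fraction of the dose of ``source`` eventually converted to ``target``,
    summed over all directed paths.  Returns 0 (with a log note) when the
    target is unreachable."""
    paths = yield_decomposition(report, source, target)
    if not paths:
        log.info("no path from %s to %s in the network", source, target)
        return 0.0
    return sum(f for _, f in paths)


def bioavailability(result: SimulationResult, compound: str | None = None) -> float:
    """Fraction of the dosed moles reaching venous blood unmetabolized
    (Fa × gut-wall escape × hepatic first-pass escape), read from the
    engine's absorbing-boundary first-pass tracer."""
    cid = compound if compound is not None else _dosed_victim(result)
    dose = result.dosed_umol.get(cid, 0.0)
    if dose == 0.0:
        return 0.0
    return float(result.first_pass[cid][-1] / dose)


def urinary_fraction(result: SimulationResult, compound: str | None = None) -> float:
    """Cumulative urinary amount of ``compound`` as ‰ of the victim dose."""
    victim = _dosed_victim(result)
    dose = result.dosed_umol[victim]
    cid = compound if compound is not None else victim
    if dose == 0.0:
        return 0.0
    return float(result.amounts[cid]["urine"][-1] / dose * 1000.0)
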