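"""Panel-study regimens, non-compartmental metrics and population scenarios."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import DoseEvent, SimulationResult, SolverOptions, simulate
from .interactions import InteractionSpec
from .network import NetworkSpec
from .physiology import (
    ActivityScore,
    IvsfTable,
    PhysiologySpec,
    PopulationSpec,
    sample_population,
)

__all__ = [
    "Regimen",
    "ScenarioSpec",
    "PKMetrics",
    "ScenarioResult",
    "build_regimen",
    "nca_auc_last",
    "nca_cmax",
    "run_scenario",
]

VICTIM = "e_clomiphene"
E_ISOMER_FRACTION = 0.62  # (E):(Z) mass ratio in the citrate tablets
VICTIM_DOSE_MG = 100.0  # clomiphene citrate, single oral dose

REGIMEN_LABELS = ("control", "clarithromycin", "paroxetine")


@dataclass(frozen=True)
class Regimen:
    label: str
    doses: tuple[DoseEvent, ...]
    sampling_times: np.ndarray  # absolute times (h)
    victim_dose_time: float

    def __post_init__(self) -> None:
        if self.label == "control" and any(
            d.compound != VICTIM for d in self.doses
        ):
            raise ValueError("control regimen must contain victim doses only")

    @property
    def victim_doses(self) -> list[DoseEvent]:
        return [d for d in self.doses if d.compound == VICTIM]

    @property
    def perpetrator_doses(self) -> list[DoseEvent]:
        return [d for d in self.doses if d.compound != VICTIM]


def build_regimen(
    label: str,
    victim_dose_mg: float = VICTIM_DOSE_MG,
    sampling_step: float = 0.25,
    sampling_duration: float = 96.0,
) -> Regimen:
    """Compose one study period.

    control: one victim dose at t=0.
    clarithromycin: 500 mg twice daily on days 1-4 (t=0..84 h, 12-h spacing)
    plus a 500 mg co-dose with the victim on day 5 (t=96 h) — 9 events.
    paroxetine: 40 mg once daily on days 1-2 (t=0, 24 h) plus a 40 mg
    co-dose with the victim on day 3 (t=48 h) — 3 events.
    """
    if label not in REGIMEN_LABELS:
        raise ValueError(f"unknown regimen label {label!r}")
    doses: list[DoseEvent] = []
    if label == "control":
        t_victim = 0.0
    elif label == "clarithromycin":
        t_victim = 96.0
        for i in range(8):  # bid on days 1-4
            doses.append(DoseEvent("clarithromycin", 500.0, 12.0 * i))
        doses.append(DoseEvent("clarithromycin", 500.0, t_victim))
    else:  # paroxetine
        t_victim = 48.0
        doses.append(DoseEvent("paroxetine", 40.0, 0.0))
        doses.append(DoseEvent("paroxetine", 40.0, 24.0))
        doses.append(DoseEvent("paroxetine", 40.0, t_victim))
    doses.append(
        DoseEvent(VICTIM, victim_dose_mg, t_victim, isomer_fraction=E_ISOMER_FRACTION)
    )
    sampling = t_victim + np.arange(0.0, sampling_duration + 1e-9, sampling_step)
    return Regimen(
        label=label,
        doses=tuple(sorted(doses, key=lambda d: d.time)),
        sampling_times=sampling,
        victim_dose_time=t_victim,
    )


def nca_auc_last(times, concentrations) -> float:
    """AUC from the first to the last sample, linear trapezoidal rule."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one sample")
    if t.size == 1:
        import warnings

        warnings.warn("single sample: AUC_last is 0", stacklevel=2)
        return 0.0
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(c, t))


def nca_cmax(times, concentrations) -> tuple[float, float]:
    """Maximum observed concentration and its earliest time."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one sample")
    i = int(np.argmax(c))  # argmax returns the first maximum -> earliest
    return float(c[i]), float(t[i])


@dataclass(frozen=True)
class PKMetrics:
    analyte: str
    auc_last: float
    cmax: float
    tmax: float

    def __post_init__(self) -> None:
        if min(self.auc_last, self.cmax, self.tmax) < 0:
            raise ValueError("PK metrics must be >= 0")


@dataclass
class ScenarioSpec:
    activity_score: ActivityScore
    regimen: Regimen
    population: PopulationSpec
    network: NetworkSpec
    reference: PhysiologySpec
    ivsf: IvsfTable
    interaction: InteractionSpec | None = None
    analytes: tuple[str, ...] = ()
    solver: SolverOptions = field(default_factory=SolverOptions)


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    times: np.ndarray  # relative to the victim dose
    profiles: dict[str, np.ndarray]  # analyte -> (n, t) plasma µmol/L
    metrics: dict[str, list[PKMetrics]]
    geomean: dict[str, np.ndarray]
    gsd: dict[str, np.ndarray]
    results: list[SimulationResult] = field(default_factory=list)

    def geometric_mean_metric(self, analyte: str, name: str) -> float:
        vals = np.array([getattr(m, name) for m in self.metrics[analyte]])
        vals = vals[vals > 0]
        if vals.size == 0:
            return 0.0
        return float(np.exp(np.mean(np.log(vals))))


def _geo_stats(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geometric mean and GSD per column, ignoring nonpositive values by
    flooring them at a tiny constant (profiles are positive post-dose)."""
    floored = np.maximum(matrix, 1e-300)
    logs = np.log(floored)
    gm = np.exp(logs.mean(axis=0))
    if matrix.shape[0] > 1:
        gsd = np.exp(logs.std(axis=0, ddof=1))
    else:
        gsd = np.ones(matrix.shape[1])
    return gm, gsd


def run_scenario(spec: ScenarioSpec, keep_results: bool = False) -> ScenarioResult:
    """Simulate every individual of the population under the regimen.

    CYP2D6 reactions are rescaled to the scenario's activity score; outputs
    are per-analyte plasma profiles (times relative to the victim dose),
    per-individual NCA metrics and geometric mean / GSD summaries.
    Deterministic for a fixed population seed.
    """
    analytes = spec.analytes or tuple(
        c.id for c in spec.network.compounds if not c.is_perpetrator
    )
    individuals = sample_population(spec.reference, spec.population)
    grid = spec.regimen.sampling_times
    rel_times = grid - spec.regimen.victim_dose_time
    profiles = {a: np.zeros((len(individuals), len(grid))) for a in analytes}
    metrics: dict[str, list[PKMetrics]] = {a: [] for a in analytes}
    results = []
    for i, individual in enumerate(individuals):
        try:
            res = simulate(
                individual,
                spec.network,
                list(spec.regimen.doses),
                grid=grid,
                inhibition=spec.interaction,
                activity_score=spec.activity_score,
                ivsf=spec.ivsf,
                t_end=float(grid[-1]),
                options=spec.solver,
            )
        except Exception as exc:
            raise RuntimeError(f"simulation failed for individual {i}") from exc
        mask = np.isin(res.times, grid)
        for a in analytes:
            conc = res.plasma_concentration(a)[mask]
            profiles[a][i] = conc
            auc = nca_auc_last(rel_times, conc)
            cmax, tmax = nca_cmax(rel_times, conc)
            metrics[a].append(PKMetrics(a, auc, cmax, tmax))
        if keep_results:
            results.append(res)
    geomean, gsd = {}, {}
    for a in analytes:
        geomean[a], gsd[a] = _geo_stats(profiles[a])
    return ScenarioResult(
        spec=spec,
        times=rel_times,
        profiles=profiles,
        metrics=metrics,
        geomean=geomean,
        gsd=gsd,
        results=results,
    )
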