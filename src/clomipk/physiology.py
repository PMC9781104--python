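"""Virtual individuals, population sampling and CYP2D6 activity-score scaling.

The physiology is a reduced whole-body scheme with seven compartments
(gut lumen, gut wall, liver, kidney, rest-of-body, arterial and venous
blood).  Organ volumes, blood flows and GFR for the bundled reference
female adult live in ``data/reference_physiology.yaml``; individuals are
derived from it by allometric scaling, and populations by independent
log-normal variability per parameter class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ORGANS",
    "PERFUSED_ORGANS",
    "PhysiologySpec",
    "PopulationSpec",
    "ActivityScore",
    "IvsfTable",
    "build_reference_individual",
    "sample_population",
    "effective_kcat",
    "load_reference_table",
]

ORGANS = ("gut_lumen", "gut_wall", "liver", "kidney", "rest", "arterial", "venous")

#: organs that receive arterial blood directly (liver flow = hepatic artery)
PERFUSED_ORGANS = ("gut_wall", "liver", "kidney", "rest")

#: only these organs may carry metabolic enzyme
ENZYME_ORGANS = ("liver", "gut_wall")

_PHENOTYPE_BY_SCORE = {0.0: "PM", 0.5: "IM", 0.75: "IM", 1.0: "IM", 2.0: "NM", 3.0: "UM"}


class ConfigurationError(ValueError):
    """Raised for malformed physiology / scaling configuration."""


@dataclass
class PhysiologySpec:
    """One virtual individual.

    volumes in L, flows in L/h (blood), GFR in L/h, enzyme abundances in µmol.
    ``blood_flows`` holds the arterial inflow per perfused organ; the liver
    entry is the hepatic-artery flow (portal blood arrives via the gut wall).
    """

    volumes: dict[str, float]
    blood_flows: dict[str, float]
    cardiac_output: float
    gfr: float
    enzyme_abundance: dict[tuple[str, str], float]
    weight: float
    height: float
    age: float

    def __post_init__(self) -> None:
        for organ in ORGANS:
            if organ not in self.volumes:
                raise ConfigurationError(f"missing volume for organ {organ!r}")
        for organ in PERFUSED_ORGANS:
            if organ not in self.blood_flows:
                raise ConfigurationError(f"missing blood flow for organ {organ!r}")
        if any(v < 0 for v in self.volumes.values()):
            raise ConfigurationError("organ volumes must be >= 0")
        if any(q < 0 for q in self.blood_flows.values()):
            raise ConfigurationError("blood flows must be >= 0")
        if self.gfr < 0 or self.cardiac_output < 0:
            raise ConfigurationError("GFR and cardiac output must be >= 0")
        for (enzyme, organ), amount in self.enzyme_abundance.items():
            if organ not in ENZYME_ORGANS:
                raise ConfigurationError(
                    f"enzyme {enzyme!r} placed in {organ!r}; only {ENZYME_ORGANS} allowed"
                )
            if amount < 0:
                raise ConfigurationError("enzyme abundances must be >= 0")
        inflow = sum(self.blood_flows[o] for o in PERFUSED_ORGANS)
        if not math.isclose(inflow, self.cardiac_output, rel_tol=1e-9, abs_tol=1e-9):
            raise ConfigurationError(
                f"organ inflows ({inflow:.6g} L/h) must sum to cardiac output "
                f"({self.cardiac_output:.6g} L/h)"
            )

    @property
    def liver_total_flow(self) -> float:
        """Total hepatic outflow: hepatic artery plus portal (gut-wall) flow."""
        return self.blood_flows["liver"] + self.blood_flows["gut_wall"]

    def to_dict(self) -> dict:
        return {
            "volumes": dict(self.volumes),
            "blood_flows": dict(self.blood_flows),
            "cardiac_output": self.cardiac_output,
            "gfr": self.gfr,
            "enzyme_abundance": [
                {"enzyme": e, "organ": o, "amount": a}
                for (e, o), a in sorted(self.enzyme_abundance.items())
            ],
            "weight": self.weight,
            "height": self.height,
            "age": self.age,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhysiologySpec":
        return cls(
            volumes=dict(d["volumes"]),
            blood_flows=dict(d["blood_flows"]),
            cardiac_output=float(d["cardiac_output"]),
            gfr=float(d["gfr"]),
            enzyme_abundance={
                (row["enzyme"], row["organ"]): float(row["amount"])
                for row in d["enzyme_abundance"]
            },
            weight=float(d["weight"]),
            height=float(d["height"]),
            age=float(d["age"]),
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Population size plus log-normal CV per parameter class.

    Recognised classes: ``volume``, ``flow``, ``gfr``, ``enzyme``.
    """

    n: int
    cv: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if any(v < 0 for v in self.cv.values()):
            raise ValueError("CVs must be >= 0")


@dataclass(frozen=True)
class ActivityScore:
    """CYP2D6 activity score with its phenotype label."""

    value: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.value not in _PHENOTYPE_BY_SCORE:
            raise ValueError(
                f"activity score must be one of {sorted(_PHENOTYPE_BY_SCORE)}, "
                f"got {self.value}"
            )
        expected = _PHENOTYPE_BY_SCORE[self.value]
        if not self.label:
            object.__setattr__(self, "label", expected)
        elif self.label != expected:
            raise ValueError(
                f"phenotype label {self.label!r} inconsistent with AS={self.value} "
                f"(expected {expected!r})"
            )

    @classmethod
    def from_value(cls, value: float) -> "ActivityScore":
        return cls(float(value))


class IvsfTable:
    """Per-reaction scaling factors turning the NM catalytic rate into the
    rate at another activity score.

    Keys are ``(reaction_id, activity_score)``; a reaction id of ``"*"``
    provides a shared fallback for all CYP2D6-dependent reactions.
    """

    def __init__(self, entries: dict[tuple[str, float], float]):
        self.entries = {(rid, float(s)): float(v) for (rid, s), v in entries.items()}
        for (rid, score), value in self.entries.items():
            if value < 0:
                raise ValueError(f"IVSF for ({rid}, AS={score}) must be >= 0")
            if score == 2.0 and not math.isclose(value, 1.0, rel_tol=1e-9):
                raise ValueError(f"IVSF at AS=2 must equal 1 (reaction {rid!r})")
            if score == 0.0 and value != 0.0:
                raise ValueError(f"IVSF at AS=0 must equal 0 (reaction {rid!r})")

    def get(self, reaction_id: str, score: float) -> float:
        key = (reaction_id, float(score))
        if key in self.entries:
            return self.entries[key]
        wildcard = ("*", float(score))
        if wildcard in self.entries:
            return self.entries[wildcard]
        raise KeyError(
            f"no IVSF entry for reaction {reaction_id!r} at activity score {score}"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction_id": rid, "activity_score": s, "ivsf": v}
            for (rid, s), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["reaction_id", "activity_score", "ivsf"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IvsfTable":
        df = pd.read_csv(path)
        required = {"reaction_id", "activity_score", "ivsf"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"IVSF table needs columns {sorted(required)}")
        return cls(
            {
                (str(r.reaction_id), float(r.activity_score)): float(r.ivsf)
                for r in df.itertuples()
            }
        )


def load_reference_table(path=None) -> dict:
    """Load the bundled (or a user-provided) reference physiology table."""
    if path is None:
        from importlib.resources import files

        path = files("clomipk.data") / "reference_physiology.yaml"
        text = path.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def build_reference_individual(
    age: float,
    weight: float,
    height: float,
    reference: dict | None = None,
    volume_exponent: float = 1.0,
    flow_exponent: float = 0.75,
) -> PhysiologySpec:
    """Scale the bundled reference female adult to the given demographics.

    Volumes (and enzyme amounts, which track liver size) scale with
    ``(weight/ref_weight)**volume_exponent``; flows and GFR with
    ``flow_exponent``.  Deterministic.
    """
    if min(age, weight, height) <= 0:
        raise ValueError("age, weight and height must be positive")
    ref = reference if reference is not None else load_reference_table()
    try:
        ref_weight = float(ref["weight"])
        volumes = {o: float(ref["volumes"][o]) for o in ORGANS}
        flows = {o: float(ref["blood_flows"][o]) for o in PERFUSED_ORGANS}
        gfr = float(ref["gfr"])
        abundance = {
            (row["enzyme"], row["organ"]): float(row["amount"])
            for row in ref["enzyme_abundance"]
        }
    except KeyError as exc:  # pragma: no cover - exercised via error test
        raise ConfigurationError(f"reference table is missing entry: {exc}") from exc

    fv = (weight / ref_weight) ** volume_exponent
    ff = (weight / ref_weight) ** flow_exponent
    volumes = {o: v * fv for o, v in volumes.items()}
    flows = {o: q * ff for o, q in flows.items()}
    return PhysiologySpec(
        volumes=volumes,
        blood_flows=flows,
        cardiac_output=sum(flows.values()),
        gfr=gfr * ff,
        enzyme_abundance={k: a * fv for k, a in abundance.items()},
        weight=weight,
        height=height,
        age=age,
    )


def _lognormal(rng: np.random.Generator, median: float, cv: float) -> float:
    if cv <= 0 or median <= 0:
        return median
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return median * math.exp(sigma * rng.standard_normal())


def sample_population(ref: PhysiologySpec, pop: PopulationSpec) -> list[PhysiologySpec]:
    """Draw ``pop.n`` individuals around ``ref``.

    Each parameter is log-normal with the class CV (median at the reference
    value); after sampling, organ flows are renormalized so their sum equals
    the sampled cardiac output.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(pop.seed)
    cv_vol = pop.cv.get("volume", 0.0)
    cv_flow = pop.cv.get("flow", 0.0)
    cv_gfr = pop.cv.get("gfr", 0.0)
    cv_enz = pop.cv.get("enzyme", 0.0)

    out = []
    for _ in range(pop.n):
        volumes = {o: _lognormal(rng, v, cv_vol) for o, v in ref.volumes.items()}
        co = _lognormal(rng, ref.cardiac_output, cv_flow)
        flows = {o: _lognormal(rng, q, cv_flow) for o, q in ref.blood_flows.items()}
        total = sum(flows.values())
        if total > 0:
            flows = {o: q * co / total for o, q in flows.items()}
        gfr = _lognormal(rng, ref.gfr, cv_gfr)
        abundance = {
            k: _lognormal(rng, a, cv_enz) for k, a in ref.enzyme_abundance.items()
        }
        out.append(
            replace(
                ref,
                volumes=volumes,
                blood_flows=flows,
                cardiac_output=co,
                gfr=gfr,
                enzyme_abundance=abundance,
            )
        )
    return out


def effective_kcat(
    kcat_nm: float, score: ActivityScore, table: IvsfTable, reaction: str
) -> float:
    """NM catalytic rate rescaled to the given activity score.

    Returns ``kcat_nm * IVSF(reaction, score)``; raises ``KeyError`` when the
    table holds no entry (no silent default).
    """
    if kcat_nm < 0:
        raise ValueError("kcat must be >= 0")
    return kcat_nm * table.get(reaction, score.value)
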