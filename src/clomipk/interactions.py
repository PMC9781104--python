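"""Competitive and mechanism-based CYP inhibition.

Unbound inhibitor concentration at the enzyme site uses the same
convention as victim metabolism: Cu = fu * C_organ / Kp_organ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import CompoundSpec

__all__ = [
    "InhibitionSpec",
    "InteractionSpec",
    "apparent_km",
    "inactivation_rate",
    "enzyme_turnover_rhs",
    "DEFAULT_KDEG",
]

#: default enzyme degradation rates (1/h) per (enzyme, organ).  Liver CYP3A4
#: and gut CYP3A4 turnover half-lives of ~36 h / ~23 h and liver CYP2D6 of
#: ~51 h are widely used literature defaults; override via InhibitionSpec.
DEFAULT_KDEG: dict[tuple[str, str], float] = {
    ("CYP3A4", "liver"): 0.0193,
    ("CYP3A4", "gut_wall"): 0.0301,
    ("CYP2D6", "liver"): 0.0136,
    ("CYP2D6", "gut_wall"): 0.0301,
    ("CYP2B6", "liver"): 0.0217,
    ("CYP2B6", "gut_wall"): 0.0301,
}


@dataclass(frozen=True)
class InhibitionSpec:
    """One perpetrator-enzyme interaction (competitive and/or MBI)."""

    perpetrator: str
    enzyme: str
    ki: float | None = None  # µmol/L, competitive
    k_inact: float | None = None  # 1/h
    k_i: float | None = None  # µmol/L, half-maximal inactivation
    k_deg: dict[tuple[str, str], float] | None = None  # overrides per (enzyme, organ)

    def __post_init__(self) -> None:
        mbi = self.k_inact is not None or self.k_i is not None
        if mbi and (self.k_inact is None or self.k_i is None):
            raise ValueError("mechanism-based inhibition needs both k_inact and K_I")
        if self.ki is None and not mbi:
            raise ValueError("inhibition spec needs a competitive Ki or MBI constants")
        for v in (self.ki, self.k_inact, self.k_i):
            if v is not None and v <= 0:
                raise ValueError("inhibition constants must be > 0")

    @property
    def is_mbi(self) -> bool:
        return self.k_inact is not None

    def kdeg(self, enzyme: str, organ: str) -> float:
        if self.k_deg and (enzyme, organ) in self.k_deg:
            return self.k_deg[(enzyme, organ)]
        return DEFAULT_KDEG[(enzyme, organ)]


@dataclass
class InteractionSpec:
    """Perpetrator compounds plus their inhibition mechanisms."""

    inhibitions: list[InhibitionSpec]
    perpetrators: list[CompoundSpec] = field(default_factory=list)
    #: first-order unspecific hepatic clearance per perpetrator (L/h on Cu)
    perpetrator_clearance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {c.id for c in self.perpetrators}
        for inh in self.inhibitions:
            if inh.perpetrator not in ids:
                raise ValueError(
                    f"inhibition references unknown perpetrator {inh.perpetrator!r}"
                )


def apparent_km(km: float, iu: float, ki: float) -> float:
    """Competitive inhibition: KM inflated by (1 + Iu/Ki)."""
    if km <= 0 or ki <= 0:
        raise ValueError("KM and Ki must be > 0")
    if iu < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    return km * (1.0 + iu / ki)


def inactivation_rate(e: float, iu: float, k_inact: float, k_i: float) -> float:
    """Mechanism-based inactivation flux [µmol/h]: k_inact·Iu/(K_I+Iu)·E."""
    if k_inact <= 0 or k_i <= 0:
        raise ValueError("k_inact and K_I must be > 0")
    if e < 0 or iu < 0:
        raise ValueError("enzyme amount and Iu must be >= 0")
    return k_inact * iu / (k_i + iu) * e


def enzyme_turnover_rhs(e: float, e0: float, k_deg: float, inact_rate: float) -> float:
    """dE/dt under zero-order synthesis, first-order degradation and MBI."""
    if e0 <= 0:
        raise ValueError("baseline enzyme amount must be > 0")
    return k_deg * e0 - k_deg * e - inact_rate
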