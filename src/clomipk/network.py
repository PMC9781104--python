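"""Compounds and the metabolic reaction network.

The default network covers (E)-clomiphene and its three measured
metabolites, with hydroxylation / N-desethylation routes catalysed by
CYP2D6, CYP3A4 and CYP2B6 plus unspecific hepatic clearances; products
without PK of their own ("undefined metabolites") are terminal sinks
tracked for mass balance only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "UNDEFINED_METABOLITE",
    "ENZYMES",
    "CompoundSpec",
    "ReactionSpec",
    "NetworkSpec",
    "validate_network",
    "dose_to_moles",
    "load_default_network",
]

UNDEFINED_METABOLITE = "undefined_metabolite"
ENZYMES = ("CYP2D6", "CYP3A4", "CYP2B6")
UNSPECIFIC = "unspecific_hepatic"


@dataclass(frozen=True)
class CompoundSpec:
    """Physicochemistry and disposition parameters of one compound."""

    id: str
    molecular_weight: float
    fu: float
    kp: dict[str, float]
    salt_factor: float = 1.0
    blood_plasma_ratio: float = 1.0
    ka: float = 0.0  # 1/h, parent and perpetrators only
    fa: float = 1.0
    renal_excretion: bool = False
    filtration_scaling: float = 1.0
    is_perpetrator: bool = False

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.id}: molecular weight must be > 0")
        if not 0 < self.fu <= 1:
            raise ValueError(f"{self.id}: fu must be in (0, 1]")
        if not 0 < self.fa <= 1:
            raise ValueError(f"{self.id}: Fa must be in (0, 1]")
        if not 0 < self.salt_factor <= 1:
            raise ValueError(f"{self.id}: salt-to-base factor must be in (0, 1]")
        if any(v <= 0 for v in self.kp.values()):
            raise ValueError(f"{self.id}: all Kp must be > 0")
        if self.blood_plasma_ratio <= 0:
            raise ValueError(f"{self.id}: blood:plasma ratio must be > 0")
        if self.ka < 0 or self.filtration_scaling < 0:
            raise ValueError(f"{self.id}: ka and filtration scaling must be >= 0")


@dataclass(frozen=True)
class ReactionSpec:
    """One metabolic conversion.

    Exactly one kinetic mode: saturable (``kcat`` [1/min] + ``km`` [µmol/L])
    or first-order (``clint`` [L/h], flux = clint · Cu).
    """

    id: str
    substrate: str
    product: str  # compound id or UNDEFINED_METABOLITE
    catalyst: str  # enzyme id or "unspecific_hepatic"
    kcat: float | None = None
    km: float | None = None
    clint: float | None = None
    cyp2d6_dependent: bool = False
    organs: tuple[str, ...] = ("liver",)

    def __post_init__(self) -> None:
        saturable = self.kcat is not None and self.km is not None
        first_order = self.clint is not None
        if saturable == first_order:
            raise ValueError(
                f"reaction {self.id!r}: exactly one kinetic mode required "
                "(kcat+km or clint)"
            )
        for value in (self.kcat, self.km, self.clint):
            if value is not None and value < 0:
                raise ValueError(f"reaction {self.id!r}: kinetic constants must be >= 0")
        if self.catalyst not in ENZYMES and self.catalyst != UNSPECIFIC:
            raise ValueError(
                f"reaction {self.id!r}: unknown catalyst {self.catalyst!r}"
            )

    @property
    def first_order(self) -> bool:
        return self.clint is not None


@dataclass
class NetworkSpec:
    """Compound list plus directed reaction graph."""

    compounds: list[CompoundSpec]
    reactions: list[ReactionSpec]

    def compound(self, cid: str) -> CompoundSpec:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(f"unknown compound id {cid!r}")

    def reactions_of(self, substrate: str) -> list[ReactionSpec]:
        return [r for r in self.reactions if r.substrate == substrate]

    def to_dict(self) -> dict:
        def cdict(c: CompoundSpec) -> dict:
            return {
                "id": c.id,
                "molecular_weight": c.molecular_weight,
                "fu": c.fu,
                "kp": dict(c.kp),
                "salt_factor": c.salt_factor,
                "blood_plasma_ratio": c.blood_plasma_ratio,
                "ka": c.ka,
                "fa": c.fa,
                "renal_excretion": c.renal_excretion,
                "filtration_scaling": c.filtration_scaling,
                "is_perpetrator": c.is_perpetrator,
            }

        def rdict(r: ReactionSpec) -> dict:
            return {
                "id": r.id,
                "substrate": r.substrate,
                "product": r.product,
                "catalyst": r.catalyst,
                "kcat": r.kcat,
                "km": r.km,
                "clint": r.clint,
                "cyp2d6_dependent": r.cyp2d6_dependent,
                "organs": list(r.organs),
            }

        return {
            "compounds": [cdict(c) for c in self.compounds],
            "reactions": [rdict(r) for r in self.reactions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        compounds = [CompoundSpec(**c) for c in d["compounds"]]
        reactions = []
        for r in d["reactions"]:
            r = dict(r)
            r["organs"] = tuple(r.get("organs", ("liver",)))
            reactions.append(ReactionSpec(**r))
        return cls(compounds=compounds, reactions=reactions)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_network(net: NetworkSpec) -> list[str]:
    """Structural validation; returns a list of human-readable violations
    (empty for the bundled default network)."""
    issues: list[str] = []
    ids = [c.id for c in net.compounds]
    if len(set(ids)) != len(ids):
        issues.append("duplicate compound ids")
    known = set(ids)
    rids = [r.id for r in net.reactions]
    if len(set(rids)) != len(rids):
        issues.append("duplicate reaction ids")
    for r in net.reactions:
        if r.substrate not in known:
            issues.append(f"reaction {r.id!r}: unknown substrate {r.substrate!r}")
        if r.product != UNDEFINED_METABOLITE and r.product not in known:
            issues.append(f"reaction {r.id!r}: unknown product {r.product!r}")
        if r.product == r.substrate:
            issues.append(f"reaction {r.id!r}: substrate equals product")
        for organ in r.organs:
            if organ not in ("liver", "gut_wall"):
                issues.append(f"reaction {r.id!r}: invalid reaction organ {organ!r}")
    for c in net.compounds:
        if c.is_perpetrator:
            continue
        has_route = c.renal_excretion or any(
            r.substrate == c.id for r in net.reactions
        )
        if not has_route:
            issues.append(f"compound {c.id!r} has no elimination route")
    return issues


def dose_to_moles(
    dose_mg: float, compound: CompoundSpec, isomer_fraction: float = 1.0
) -> float:
    """Convert a salt dose [mg] to base moles [µmol].

    ``dose_mg * isomer_fraction`` is the salt mass of the modeled isomer;
    the salt-to-base factor and molecular weight of the base convert it to
    µmol.
    """
    if dose_mg < 0:
        raise ValueError("dose must be >= 0")
    if not 0 < isomer_fraction <= 1:
        raise ValueError("isomer fraction must be in (0, 1]")
    return dose_mg * isomer_fraction * compound.salt_factor / compound.molecular_weight * 1000.0


def load_default_network(path=None) -> NetworkSpec:
    """The bundled default victim network (parent plus three metabolites)."""
    if path is not None:
        return NetworkSpec.from_yaml(path)
    from importlib.resources import files

    text = (files("clomipk.data") / "default_network.yaml").read_text()
    return NetworkSpec.from_dict(yaml.safe_load(text))
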