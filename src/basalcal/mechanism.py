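"""Mass-action reaction networks: in-memory model, file dialect, validation.

A :class:`Mechanism` is an ordered list of species and an ordered list of
uni-/bimolecular mass-action reactions, each carrying a rate coefficient on
the log10 scale together with a prior uncertainty half-width ``f_prior``
(in orders of magnitude).  Rate coefficients use the Arrhenius
parameterization ``k = A * T^n * exp(-E/RT)`` with the temperature exponent
and activation energy pinned to zero, so a single number ``log10_k``
(= log10 A) characterizes each reaction.

Units: first-order k in 1/s, second-order k in cm^3/(mol s); concentrations
in mol/cm^3 (see :mod:`basalcal.units`).

The on-disk format is a small YAML dialect documented in
``docs/mechanism_format.md``; :func:`parse_mechanism` / :func:`write_mechanism`
round-trip it losslessly.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "SpeciesDef",
    "RateCoefficient",
    "Reaction",
    "Mechanism",
    "MechanismError",
    "parse_mechanism",
    "write_mechanism",
    "parse_equation",
    "format_equation",
    "set_log_parameters",
]

#: tokens accepted for an empty reaction side (pure degradation / source)
EMPTY_TOKENS = {"0", "∅", "⌀", "null", "none"}


class MechanismError(ValueError):
    """Raised when a mechanism file or object violates the format rules."""


@dataclass
class SpeciesDef:
    """A chemical species of the network.

    ``role`` is ``"dynamic"`` (has an ODE) or ``"buffered"`` (held at a fixed
    activity, no ODE — used for the REF bookkeeping species that expresses
    protein synthesis and degradation).  ``is_complex`` species start every
    simulation at zero concentration.  ``monitored`` species are the ones
    whose basal ranges enter the error function.
    """

    id: str
    name: str = ""
    role: str = "dynamic"
    is_complex: bool = False
    monitored: bool = False
    activity: float = 1.0  # mol/cm^3, buffered species only

    def __post_init__(self) -> None:
        if self.role not in ("dynamic", "buffered"):
            raise MechanismError(f"species {self.id!r}: unknown role {self.role!r}")
        if self.is_complex and self.role == "buffered":
            raise MechanismError(f"species {self.id!r}: a complex cannot be buffered")

    @property
    def buffered(self) -> bool:
        return self.role == "buffered"


@dataclass
class RateCoefficient:
    """log10 rate coefficient with its prior uncertainty band.

    ``log10_k0`` is the nominal (starting) value; the admissible band is
    ``log10_k0 ± f_prior``.  ``n_exp`` and ``E_act`` exist for interface
    completeness and are always zero (temperature-independent kinetics).
    ``pinned`` flags a value that was clamped to a bound of the band.
    """

    log10_k: float
    f_prior: float = 4.0
    log10_k0: float | None = None
    n_exp: float = 0.0
    E_act: float = 0.0
    pinned: bool = False

    def __post_init__(self) -> None:
        if self.log10_k0 is None:
            self.log10_k0 = self.log10_k
        if self.n_exp != 0.0 or self.E_act != 0.0:
            raise MechanismError("temperature dependence is not supported: n_exp and E_act must be 0")
        if self.f_prior < 0:
            raise MechanismError("f_prior must be nonnegative")

    @property
    def k(self) -> float:
        """Linear-scale rate coefficient (1/s or cm^3/(mol s))."""
        return 10.0 ** self.log10_k

    @property
    def A(self) -> float:
        """Arrhenius pre-exponential; equals k since n=E=0."""
        return self.k

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.log10_k0 - self.f_prior, self.log10_k0 + self.f_prior)


@dataclass
class Reaction:
    """A mass-action reaction with stoichiometric reactant/product multisets."""

    index: int
    reactants: dict[str, int]
    products: dict[str, int]
    rate: RateCoefficient
    reverse_of: int | None = None

    @property
    def molecularity(self) -> int:
        return sum(self.reactants.values())

    @property
    def equation(self) -> str:
        return format_equation(self.reactants, self.products)


@dataclass
class Mechanism:
    """An ordered species list plus an ordered reaction list."""

    species: list[SpeciesDef] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    name: str = "mechanism"
    notes: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def dynamic_species(self) -> list[SpeciesDef]:
        return [s for s in self.species if not s.buffered]

    @property
    def monitored_species(self) -> list[SpeciesDef]:
        return [s for s in self.species if s.monitored]

    def species_by_id(self, sid: str) -> SpeciesDef:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_index(self, idx: int) -> Reaction:
        for r in self.reactions:
            if r.index == idx:
                return r
        raise KeyError(idx)

    @property
    def reversible_pair_count(self) -> int:
        """Number of reversible pairs (each pair counted once)."""
        n = 0
        for r in self.reactions:
            if r.reverse_of is not None and r.index < r.reverse_of:
                n += 1
        return n

    def log10_k_vector(self, indices: Sequence[int]) -> "list[float]":
        return [self.reaction_by_index(i).rate.log10_k for i in indices]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise MechanismError(f"duplicate species ids: {dup}")
        idset = set(ids)
        seen_idx: set[int] = set()
        by_index: dict[int, Reaction] = {}
        for r in self.reactions:
            if r.index in seen_idx:
                raise MechanismError(f"duplicate reaction index {r.index}")
            seen_idx.add(r.index)
            by_index[r.index] = r
            for sid in list(r.reactants) + list(r.products):
                if sid not in idset:
                    raise MechanismError(
                        f"reaction {r.index}: undeclared species {sid!r}"
                    )
            if not r.reactants:
                raise MechanismError(f"reaction {r.index}: no reactants")
            if r.molecularity > 2:
                raise MechanismError(
                    f"reaction {r.index}: molecularity {r.molecularity} unsupported (max 2)"
                )
            if any(v <= 0 for v in list(r.reactants.values()) + list(r.products.values())):
                raise MechanismError(f"reaction {r.index}: nonpositive stoichiometry")
        for r in self.reactions:
            if r.reverse_of is not None:
                partner = by_index.get(r.reverse_of)
                if partner is None:
                    raise MechanismError(
                        f"reaction {r.index}: reverse_of {r.reverse_of} does not exist"
                    )
                if partner.reverse_of != r.index:
                    raise MechanismError(
                        f"reaction {r.index}: reverse pairing with {r.reverse_of} is not symmetric"
                    )

    def copy(self) -> "Mechanism":
        return copy.deepcopy(self)

    # -- JSON interop ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "notes": self.notes,
            "species": [
                {
                    "id": s.id,
                    "name": s.name,
                    "role": s.role,
                    "complex": s.is_complex,
                    "monitored": s.monitored,
                    **({"activity": s.activity} if s.buffered else {}),
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "index": r.index,
                    "equation": r.equation,
                    "log10_k": r.rate.log10_k,
                    "f_prior": r.rate.f_prior,
                    "log10_k0": r.rate.log10_k0,
                    **({"reverse_of": r.reverse_of} if r.reverse_of is not None else {}),
                }
                for r in self.reactions
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# equation strings


def parse_equation(text: str) -> tuple[dict[str, int], dict[str, int]]:
    """Parse ``"A + B -> C"`` into reactant/product stoichiometric multisets.

    ``"2 A"`` denotes stoichiometry 2; an empty side is written ``0`` (also
    accepted: the empty-set glyphs).
    """
    if "->" not in text:
        raise MechanismError(f"missing '->' in equation {text!r}")
    lhs, rhs = text.split("->", 1)

    def side(chunk: str) -> dict[str, int]:
        chunk = chunk.strip()
        if not chunk or chunk.lower() in EMPTY_TOKENS:
            return {}
        out: dict[str, int] = {}
        for term in chunk.split("+"):
            term = term.strip()
            if not term:
                raise MechanismError(f"empty term in equation {text!r}")
            m = re.match(r"^(\d+)\s+(\S+)$", term)
            if m:
                coef, sid = int(m.group(1)), m.group(2)
            else:
                coef, sid = 1, term
            out[sid] = out.get(sid, 0) + coef
        return out

    return side(lhs), side(rhs)


def format_equation(reactants: Mapping[str, int], products: Mapping[str, int]) -> str:
    def side(d: Mapping[str, int]) -> str:
        if not d:
            return "0"
        return " + ".join(
            (f"{v} {k}" if v != 1 else k) for k, v in d.items()
        )

    return f"{side(reactants)} -> {side(products)}"


# ---------------------------------------------------------------------------
# file dialect


def parse_mechanism(path: str | Path) -> Mechanism:
    """Read a mechanism file (YAML dialect, see docs/mechanism_format.md)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise MechanismError(f"{path}: not a mechanism document")
    return mechanism_from_dict(doc)


def mechanism_from_dict(doc: Mapping) -> Mechanism:
    species = []
    for entry in doc.get("species", []):
        if isinstance(entry, str):
            entry = {"id": entry}
        species.append(
            SpeciesDef(
                id=str(entry["id"]),
                name=str(entry.get("name", "")),
                role=str(entry.get("role", "dynamic")),
                is_complex=bool(entry.get("complex", False)),
                monitored=bool(entry.get("monitored", False)),
                activity=float(entry.get("activity", 1.0)),
            )
        )
    reactions = []
    for entry in doc.get("reactions", []):
        reactants, products = parse_equation(str(entry["equation"]))
        rate = RateCoefficient(
            log10_k=float(entry["log10_k"]),
            f_prior=float(entry.get("f_prior", 4.0)),
            log10_k0=(float(entry["log10_k0"]) if "log10_k0" in entry else None),
        )
        reactions.append(
            Reaction(
                index=int(entry["index"]),
                reactants=reactants,
                products=products,
                rate=rate,
                reverse_of=(int(entry["reverse_of"]) if entry.get("reverse_of") is not None else None),
            )
        )
    return Mechanism(
        species=species,
        reactions=reactions,
        name=str(doc.get("name", "mechanism")),
        notes=str(doc.get("notes", "")),
    )


def write_mechanism(mech: Mechanism, path: str | Path) -> None:
    """Write a mechanism file; ``parse_mechanism(write_mechanism(m))`` is lossless."""
    doc = mech.to_dict()
    # plain float repr keeps full precision through YAML round-trips
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=False, width=100)
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# parameter updates


def set_log_parameters(
    mech: Mechanism,
    values: Mapping[int, float],
    clip: bool = False,
) -> Mechanism:
    """Return a copy of ``mech`` with updated ``log10_k`` for the given reactions.

    ``values`` maps reaction index -> new log10_k.  With ``clip=True`` a value
    outside ``log10_k0 ± f_prior`` is clamped to the violated bound and the
    coefficient's ``pinned`` flag is raised; with ``clip=False`` an
    out-of-band value raises.
    """
    out = mech.copy()
    known = {r.index for r in out.reactions}
    for idx in values:
        if idx not in known:
            raise MechanismError(f"unknown reaction index {idx}")
    for r in out.reactions:
        if r.index not in values:
            continue
        v = float(values[r.index])
        lo, hi = r.rate.bounds
        pinned = False
        if v < lo or v > hi:
            if not clip:
                raise MechanismError(
                    f"reaction {r.index}: log10_k={v} outside prior band [{lo}, {hi}]"
                )
            v = min(max(v, lo), hi)
            pinned = True
        r.rate = replace(r.rate, log10_k=v, pinned=pinned)
    return out
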