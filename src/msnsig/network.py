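"""Species, mass-action reactions and structural checks.

A signaling network is represented as a :class:`NetworkModel`: a list of
species (with initial concentrations in uM), a list of uni/bimolecular
mass-action reactions, and a list of conserved moieties (protein totals that
mass action must preserve).  The two externally driven species -- free
intracellular calcium and extracellular dopamine -- are *clamped inputs*:
reactions may read their concentration but never change it; their trajectory
is imposed by the stimulus.

All concentrations are in uM and all times in seconds throughout the package.
First-order rate constants carry units of 1/s, second-order constants
uM^-1 s^-1 (and uM^-2 s^-1 for the few reactions with a stoichiometry-two
reactant).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

COMPARTMENT_TAGS = ("cytosol", "PSD", "input")

__all__ = [
    "SpeciesDef",
    "MassActionReaction",
    "ConservedMoiety",
    "NetworkModel",
    "rate_vector",
    "conservation_check",
    "detailed_balance_check",
    "apply_scaling",
]


@dataclass
class SpeciesDef:
    """A chemical species.

    The compartment tag is bookkeeping only: the model is a single well-mixed
    volume and tags merely record whether a species conceptually lives in the
    F-actin-rich cytosol, the postsynaptic density, or is an external input.
    """

    name: str
    compartment_tag: str = "cytosol"
    initial_concentration: float = 0.0
    is_clamped_input: bool = False

    def __post_init__(self) -> None:
        if self.compartment_tag not in COMPARTMENT_TAGS:
            raise ValueError(
                f"compartment_tag must be one of {COMPARTMENT_TAGS}, "
                f"got {self.compartment_tag!r} for species {self.name!r}"
            )
        if not self.name or not isinstance(self.name, str):
            raise ValueError("species name must be a non-empty string")
        if self.initial_concentration < 0:
            raise ValueError(
                f"initial concentration of {self.name!r} must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass
class MassActionReaction:
    """One elementary mass-action reaction, reversible iff kr > 0.

    ``reactants`` and ``products`` are sequences of ``(species name, stoich)``
    with stoichiometry restricted to 1 or 2; every reaction in the striatal
    network is uni- or bimolecular.  The net flux is

        v = kf * prod_i [R_i]^s_i  -  kr * prod_j [P_j]^s_j

    and an irreversible reaction simply has kr = 0.
    """

    id: str
    reactants: Sequence[tuple[str, int]]
    products: Sequence[tuple[str, int]]
    kf: float
    kr: float = 0.0

    def __post_init__(self) -> None:
        if self.kf < 0 or self.kr < 0:
            raise ValueError(f"reaction {self.id!r}: rate constants must be >= 0")
        for name, stoich in list(self.reactants) + list(self.products):
            if stoich not in (1, 2):
                raise ValueError(
                    f"reaction {self.id!r}: stoichiometry must be 1 or 2, "
                    f"got {stoich} for {name!r}"
                )
        r_order = sum(s for _, s in self.reactants)
        if r_order > 2:
            raise ValueError(
                f"reaction {self.id!r}: total reactant order {r_order} > 2"
            )

    @property
    def reversible(self) -> bool:
        return self.kr > 0

    def flux(self, state: Mapping[str, float]) -> float:
        fwd = self.kf
        for name, stoich in self.reactants:
            fwd *= state[name] ** stoich
        bwd = self.kr
        if self.kr > 0:
            for name, stoich in self.products:
                bwd *= state[name] ** stoich
        else:
            bwd = 0.0
        return fwd - bwd

    @property
    def keq(self) -> float:
        """Equilibrium constant kf/kr; only defined for reversible reactions."""
        if not self.reversible:
            raise ValueError(f"reaction {self.id!r} is irreversible; Keq undefined")
        return self.kf / self.kr


@dataclass
class ConservedMoiety:
    """A set of species whose summed concentration is invariant in time."""

    name: str
    members: Sequence[str]
    total: float


@dataclass
class NetworkModel:
    """A complete mass-action network with conservation bookkeeping."""

    species: list[SpeciesDef] = field(default_factory=list)
    reactions: list[MassActionReaction] = field(default_factory=list)
    conserved_moieties: list[ConservedMoiety] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)
    name: str = "model"

    # -- lookups -------------------------------------------------------------
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def get_species(self, name: str) -> SpeciesDef:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"unknown species {name!r}")

    def get_reaction(self, rid: str) -> MassActionReaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    def clamped_names(self) -> list[str]:
        return [s.name for s in self.species if s.is_clamped_input]

    def initial_state(self) -> dict[str, float]:
        return {s.name: s.initial_concentration for s in self.species}

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        names = self.species_names()
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate species names: {dupes}")
        declared = set(names)
        clamped = set(self.clamped_names())
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise ValueError(f"duplicate reaction ids: {dupes}")
        for r in self.reactions:
            for name, _ in list(r.reactants) + list(r.products):
                if name not in declared:
                    raise ValueError(
                        f"reaction {r.id!r} references undeclared species {name!r}"
                    )
            # clamped inputs are forcing functions: they may appear as
            # reactants (their consumption is simply not applied) but must
            # never be produced, which would be meaningless under clamping
            for name, _ in r.products:
                if name in clamped:
                    raise ValueError(
                        f"reaction {r.id!r} produces clamped input {name!r}"
                    )
        for m in self.conserved_moieties:
            for name in m.members:
                if name not in declared:
                    raise ValueError(
                        f"moiety {m.name!r} references undeclared species {name!r}"
                    )
            init = sum(self.get_species(n).initial_concentration for n in m.members)
            if not math.isclose(init, m.total, rel_tol=1e-6, abs_tol=1e-12):
                raise ValueError(
                    f"moiety {m.name!r}: declared total {m.total} uM does not "
                    f"match summed initial concentrations {init} uM"
                )

    # -- parameter addressing ------------------------------------------------
    def parameter_names(self) -> list[str]:
        """Addressable parameters: rate constants plus moiety totals.

        ``kf:<rid>`` / ``kr:<rid>`` address rate constants (kr only for
        reversible reactions); ``total:<moiety>`` addresses a conserved total.
        """
        out = []
        for r in self.reactions:
            out.append(f"kf:{r.id}")
            if r.reversible:
                out.append(f"kr:{r.id}")
        for m in self.conserved_moieties:
            out.append(f"total:{m.name}")
        return out

    def copy(self) -> "NetworkModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------


def rate_vector(
    model: NetworkModel, state: Mapping[str, float]
) -> dict[str, float]:
    """Time-derivative of every species at the given state (uM/s).

    Small negative concentrations (within solver tolerance) are clamped to
    zero before evaluating fluxes.  Clamped-input species always have zero
    derivative.  This is the reference (dictionary-based) implementation; the
    ODE engine uses an array-compiled equivalent.
    """
    names = model.species_names()
    for n in state:
        if n not in set(names):
            raise KeyError(f"unknown species in state: {n!r}")
    clean = {n: max(float(state[n]), 0.0) for n in names}
    deriv = {n: 0.0 for n in names}
    clamped = set(model.clamped_names())
    for r in model.reactions:
        v = r.flux(clean)
        for name, stoich in r.reactants:
            deriv[name] -= stoich * v
        for name, stoich in r.products:
            deriv[name] += stoich * v
    for n in clamped:
        deriv[n] = 0.0
    return deriv


def conservation_check(model: NetworkModel, trajectory) -> dict[str, float]:
    """Maximum relative drift of every conserved moiety along a trajectory.

    ``trajectory`` is a :class:`msnsig.engine.SimulationResult` (anything with
    a ``concentrations`` DataFrame keyed by species name works).  Returns
    ``{moiety name: max_t |sum(members)(t) - total| / total}``.
    """
    conc = trajectory.concentrations
    out: dict[str, float] = {}
    for m in model.conserved_moieties:
        for name in m.members:
            if name not in conc.columns:
                raise KeyError(
                    f"moiety {m.name!r} references species {name!r} "
                    "absent from the trajectory"
                )
        total_t = conc[list(m.members)].sum(axis=1).to_numpy()
        out[m.name] = float(np.max(np.abs(total_t - m.total)) / m.total)
    return out


def detailed_balance_check(
    model: NetworkModel,
    cycle: Sequence[str | tuple[str, int]],
) -> float:
    """Product of equilibrium constants around a closed reaction loop.

    ``cycle`` lists reversible reactions in loop order, each either a reaction
    id (traversed forward) or ``(id, -1)`` to traverse it in reverse.  A
    thermodynamically consistent cycle returns 1 (within numerical tolerance).
    The function verifies the loop actually closes: the orientation-signed
    stoichiometries must cancel for every species.
    """
    entries: list[tuple[MassActionReaction, int]] = []
    for item in cycle:
        rid, direction = (item, 1) if isinstance(item, str) else item
        if direction not in (1, -1):
            raise ValueError(f"cycle direction must be +1 or -1, got {direction}")
        r = model.get_reaction(rid)
        if not r.reversible:
            raise ValueError(
                f"reaction {rid!r} is irreversible and cannot be part of a "
                "detailed-balance cycle"
            )
        entries.append((r, direction))
    net: dict[str, int] = {}
    for r, direction in entries:
        for name, stoich in r.reactants:
            net[name] = net.get(name, 0) - direction * stoich
        for name, stoich in r.products:
            net[name] = net.get(name, 0) + direction * stoich
    imbalance = {n: v for n, v in net.items() if v != 0}
    if imbalance:
        raise ValueError(
            f"cycle does not close; net stoichiometric change: {imbalance}"
        )
    ratio = 1.0
    for r, direction in entries:
        ratio *= r.keq**direction
    return ratio


def apply_scaling(
    model: NetworkModel, scale_factors: Mapping[str, float]
) -> NetworkModel:
    """Return a copy of the model with addressed parameters multiplied.

    Rate constants are addressed ``kf:<reaction id>`` / ``kr:<reaction id>``;
    conserved totals ``total:<moiety name>``.  Scaling a total rescales the
    initial concentration of every member species proportionally, so the
    moiety stays internally consistent.
    """
    for p, f in scale_factors.items():
        if f <= 0:
            raise ValueError(f"multiplier for {p!r} must be > 0, got {f}")
    known = set(model.parameter_names())
    unknown = sorted(set(scale_factors) - known)
    if unknown:
        raise KeyError(f"unknown parameters: {unknown}")
    out = model.copy()
    for p, f in scale_factors.items():
        kind, _, target = p.partition(":")
        if kind in ("kf", "kr"):
            r = out.get_reaction(target)
            setattr(r, kind, getattr(r, kind) * f)
        else:
            for m in out.conserved_moieties:
                if m.name == target:
                    for name in m.members:
                        sp = out.get_species(name)
                        sp.initial_concentration *= f
    # moieties may share species (e.g. a holoenzyme counted in two subunit
    # totals): refresh every declared total from the scaled initials
    if any(p.startswith("total:") for p in scale_factors):
        for m in out.conserved_moieties:
            m.total = sum(
                out.get_species(n).initial_concentration for n in m.members
            )
    return out
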