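"""Declarative description of a normalized multi-tissue metabolic network.

A :class:`ModelDocument` lists species, reactions, branch points, regulatory
edges, flux sources, hormone profiles and receptor pairs.  Concentrations are
dimensionless: by construction the nominal steady-state value of every
non-boundary species is exactly 1, so the only free dynamical parameters are
the flux-distribution fractions at branch points, the regulation weights and
the source strengths.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Optional

from .errors import ModelValidationError

COMPARTMENTS = frozenset(
    {"liver", "blood", "adipose", "pancreas", "macrophage", "other_tissue"}
)
ROLES = frozenset(
    {
        "metabolite",
        "mrna",
        "protein",
        "regulator",
        "hormone",
        "receptor_inactive",
        "receptor_active",
    }
)
HORMONE_KINDS = ("growth_hormone", "androgen", "estrogen")
PROFILE_KINDS = frozenset({"constant", "daily_oscillation", "monthly_cycle"})

#: branches must close to 1 within this tolerance
FRACTION_SUM_TOL = 1e-12
#: fractions at or below this are rejected (the control-coefficient quotient
#: divides by fraction differences)
MIN_FRACTION = 1e-9


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = "liver"
    role: str = "metabolite"
    is_boundary: bool = False


@dataclass
class Reaction:
    """A reaction with normalized mass-action kinetics.

    ``substrates``/``products`` are ``(species_id, stoichiometry)`` pairs.
    ``modifiers`` (edge ids acting on this rate) is derived from the document's
    regulatory edges during validation.  ``nominal_flux`` is filled in when the
    document is compiled.
    """

    id: str
    substrates: list = field(default_factory=list)
    products: list = field(default_factory=list)
    branch_point: Optional[str] = None
    modifiers: list = field(default_factory=list)
    nominal_flux: Optional[float] = None


@dataclass
class BranchPoint:
    """A species whose outflow splits among member reactions with fractions f."""

    id: str
    source_species: str
    fractions: dict = field(default_factory=dict)

    @property
    def member_reactions(self):
        return list(self.fractions)


@dataclass
class RegulatoryEdge:
    """Multiplicative regulation of a reaction rate or a flux source.

    ``target`` may name a reaction, a flux source, or an mrna/regulator species
    (in which case the edge acts on every reaction synthesizing that species).
    The multiplier is 1 at the all-ones state, so regulation is neutral at the
    nominal steady state.
    """

    id: str
    regulator: str
    target: str
    sign: int = 1
    weight: float = 1.0


@dataclass
class FluxSource:
    id: str
    target_species: str
    basal_rate: float = 1.0
    multiplier: float = 1.0

    @property
    def effective_rate(self):
        return self.basal_rate * self.multiplier


@dataclass
class HormoneProfile:
    """Waveform of a hormone source (dimensionless level against hours)."""

    hormone: str
    kind: str = "constant"
    mean_level: float = 1.0
    amplitude: float = 0.0
    period_hours: float = 24.0
    phase_hours: float = 0.0


@dataclass
class ReceptorPair:
    """Active/inactive receptor forms bound to a hormone (quasi-steady-state).

    ``active + inactive = total`` holds at all times; ``half_saturation`` is
    the hormone level at which half of the receptor pool is active.
    """

    hormone: str
    inactive_species: str
    active_species: str
    half_saturation: float = 1.0
    total: float = 1.0


@dataclass
class ModelDocument:
    species: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    branch_points: list = field(default_factory=list)
    regulatory_edges: list = field(default_factory=list)
    flux_sources: list = field(default_factory=list)
    hormone_profiles: list = field(default_factory=list)
    receptor_pairs: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- lookup helpers ---------------------------------------------------
    def species_by_id(self):
        return {s.id: s for s in self.species}

    def reactions_by_id(self):
        return {r.id: r for r in self.reactions}

    def branch_by_id(self):
        return {b.id: b for b in self.branch_points}

    def edges_by_id(self):
        return {e.id: e for e in self.regulatory_edges}

    def sources_by_id(self):
        return {s.id: s for s in self.flux_sources}

    def find_species(self, sid):
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def copy(self):
        return copy.deepcopy(self)

    # -- validation -------------------------------------------------------
    def validate(self):
        """Check every invariant the document must satisfy; raise on failure."""
        sp = {}
        for s in self.species:
            if s.id in sp:
                raise ModelValidationError(f"duplicate species id {s.id!r}")
            if s.compartment not in COMPARTMENTS:
                raise ModelValidationError(
                    f"species {s.id!r}: unknown compartment {s.compartment!r}"
                )
            if s.role not in ROLES:
                raise ModelValidationError(f"species {s.id!r}: unknown role {s.role!r}")
            sp[s.id] = s

        rx = {}
        for r in self.reactions:
            if r.id in rx:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            for sid, st in list(r.substrates) + list(r.products):
                if sid not in sp:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )
                if st <= 0:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: non-positive stoichiometry for {sid!r}"
                    )
            rx[r.id] = r

        branches = {}
        for b in self.branch_points:
            if b.id in branches:
                raise ModelValidationError(f"duplicate branch id {b.id!r}")
            if b.source_species not in sp:
                raise ModelValidationError(
                    f"branch {b.id!r} references unknown species {b.source_species!r}"
                )
            if len(b.fractions) < 2:
                raise ModelValidationError(f"branch {b.id!r} needs >=2 member reactions")
            total = 0.0
            for rid, f in b.fractions.items():
                if rid not in rx:
                    raise ModelValidationError(
                        f"branch {b.id!r} references unknown reaction {rid!r}"
                    )
                if not (f > MIN_FRACTION and f < 1.0):
                    raise ModelValidationError(
                        f"branch {b.id!r}: fraction {f!r} of {rid!r} outside "
                        f"({MIN_FRACTION}, 1)"
                    )
                consumed = {s for s, _ in rx[rid].substrates}
                if b.source_species not in consumed:
                    raise ModelValidationError(
                        f"branch {b.id!r}: member {rid!r} does not consume "
                        f"{b.source_species!r}"
                    )
                total += f
            if abs(total - 1.0) > FRACTION_SUM_TOL:
                raise ModelValidationError(
                    f"branch {b.id!r}: fractions sum to {total!r}, not 1"
                )
            branches[b.id] = b

        # reaction -> branch back references must agree
        membership = {}
        for b in self.branch_points:
            for rid in b.fractions:
                if rid in membership:
                    raise ModelValidationError(
                        f"reaction {rid!r} is a member of two branches "
                        f"({membership[rid]!r} and {b.id!r})"
                    )
                membership[rid] = b.id
        for r in self.reactions:
            r.branch_point = membership.get(r.id)

        edge_ids = set()
        src = {}
        for s in self.flux_sources:
            if s.id in src:
                raise ModelValidationError(f"duplicate flux source id {s.id!r}")
            if s.target_species not in sp:
                raise ModelValidationError(
                    f"flux source {s.id!r} targets unknown species {s.target_species!r}"
                )
            if s.effective_rate <= 0:
                raise ModelValidationError(
                    f"flux source {s.id!r}: effective influx must be positive"
                )
            src[s.id] = s

        for e in self.regulatory_edges:
            if e.id in edge_ids:
                raise ModelValidationError(f"duplicate edge id {e.id!r}")
            edge_ids.add(e.id)
            if e.regulator not in sp:
                raise ModelValidationError(
                    f"edge {e.id!r}: unknown regulator species {e.regulator!r}"
                )
            if e.sign not in (1, -1):
                raise ModelValidationError(f"edge {e.id!r}: sign must be +1 or -1")
            if e.weight < 0:
                raise ModelValidationError(f"edge {e.id!r}: weight must be >= 0")
            if e.target not in rx and e.target not in src and e.target not in sp:
                raise ModelValidationError(
                    f"edge {e.id!r} targets unknown id {e.target!r}"
                )
            if e.target in sp and e.target not in rx and e.target not in src:
                role = sp[e.target].role
                if role not in ("mrna", "regulator"):
                    raise ModelValidationError(
                        f"edge {e.id!r}: species target {e.target!r} must be an "
                        f"mrna or regulator species (got role {role!r})"
                    )

        # derived modifier lists on reactions (species targets resolve to the
        # reactions that synthesize the species)
        producers = {}
        for r in self.reactions:
            for sid, _ in r.products:
                producers.setdefault(sid, []).append(r.id)
        for r in self.reactions:
            r.modifiers = []
        for e in self.regulatory_edges:
            if e.target in rx:
                rx[e.target].modifiers.append(e.id)
            elif e.target in sp and e.target not in src:
                for rid in producers.get(e.target, []):
                    rx[rid].modifiers.append(e.id)

        for p in self.hormone_profiles:
            if p.hormone not in HORMONE_KINDS:
                raise ModelValidationError(f"unknown hormone {p.hormone!r} in profile")
            if p.kind not in PROFILE_KINDS:
                raise ModelValidationError(f"unknown profile kind {p.kind!r}")
            if p.mean_level <= 0:
                raise ModelValidationError("profile mean_level must be positive")
            if not (0.0 <= p.amplitude <= p.mean_level):
                raise ModelValidationError(
                    f"profile for {p.hormone!r}: amplitude must lie in "
                    f"[0, mean_level] so the signal stays non-negative"
                )
            if p.period_hours <= 0:
                raise ModelValidationError("profile period_hours must be positive")

        for pair in self.receptor_pairs:
            if pair.hormone not in HORMONE_KINDS:
                raise ModelValidationError(
                    f"receptor pair: unknown hormone {pair.hormone!r}"
                )
            for sid in (pair.inactive_species, pair.active_species):
                if sid not in sp:
                    raise ModelValidationError(
                        f"receptor pair for {pair.hormone!r}: unknown species {sid!r}"
                    )
            if pair.half_saturation <= 0 or pair.total <= 0:
                raise ModelValidationError(
                    f"receptor pair for {pair.hormone!r}: half_saturation and "
                    f"total must be positive"
                )
        return self

    # -- serialization ----------------------------------------------------
    def to_dict(self):
        return {
            "species": [asdict(s) for s in self.species],
            "reactions": [asdict(r) for r in self.reactions],
            "branch_points": [
                {
                    "id": b.id,
                    "source_species": b.source_species,
                    "fractions": dict(b.fractions),
                }
                for b in self.branch_points
            ],
            "regulatory_edges": [asdict(e) for e in self.regulatory_edges],
            "flux_sources": [asdict(s) for s in self.flux_sources],
            "hormone_profiles": [asdict(p) for p in self.hormone_profiles],
            "receptor_pairs": [asdict(p) for p in self.receptor_pairs],
            "metadata": copy.deepcopy(self.metadata),
        }

    @classmethod
    def from_dict(cls, data):
        def build(klass, items):
            return [klass(**item) for item in items]

        doc = cls(
            species=build(Species, data.get("species", [])),
            reactions=[
                Reaction(
                    id=r["id"],
                    substrates=[tuple(p) for p in r.get("substrates", [])],
                    products=[tuple(p) for p in r.get("products", [])],
                    branch_point=r.get("branch_point"),
                    modifiers=list(r.get("modifiers", [])),
                    nominal_flux=r.get("nominal_flux"),
                )
                for r in data.get("reactions", [])
            ],
            branch_points=[
                BranchPoint(
                    id=b["id"],
                    source_species=b["source_species"],
                    fractions=dict(b["fractions"]),
                )
                for b in data.get("branch_points", [])
            ],
            regulatory_edges=build(RegulatoryEdge, data.get("regulatory_edges", [])),
            flux_sources=build(FluxSource, data.get("flux_sources", [])),
            hormone_profiles=build(HormoneProfile, data.get("hormone_profiles", [])),
            receptor_pairs=build(ReceptorPair, data.get("receptor_pairs", [])),
            metadata=data.get("metadata", {}),
        )
        return doc
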