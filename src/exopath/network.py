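"""Constraint-based metabolic network containers and model I/O.

A metabolic network is a stoichiometric matrix ``S`` (metabolites x
reactions, exact rationals) with per-reaction flux bounds.  Boundary
reactions touch exactly one metabolite and represent exchange with the
environment; by convention a boundary reaction written ``met ->`` carries
positive flux when the metabolite is exported (secreted) and negative flux
when it is imported (taken up).

The :class:`StandardizedNetwork` re-encodes a network so that every
reaction is irreversible with nonnegative flux: irreversible reactions
that only allow negative flux are flipped, and reversible reactions are
split into a forward and a backward part.  The split boundary reactions
(plus, optionally, intermicrobial transfer reactions of a community
model) form the analysis *subnetwork* on which pathway definitions are
compared.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._lp import InfeasibleProblem, solve_lp

__all__ = [
    "MetabolicNetwork",
    "StandardizedNetwork",
    "CommunitySpec",
    "ValidationError",
    "load_model",
    "standardize",
    "merge_community",
    "flux_variability",
]

_INF = math.inf


class ValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


def _to_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    # repr() of a float is its shortest decimal form, so common model
    # coefficients like 1.496 or 0.0709 convert exactly.
    return Fraction(repr(float(x)))


@dataclass
class MetabolicNetwork:
    """A constraint-based metabolic model.

    Stoichiometry is stored exactly (``fractions.Fraction``) because
    pathway enumeration relies on exact sign patterns; flux bounds stay
    floats because they only enter linear programs.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: list[list[Fraction]]  # m x n
    lower_bounds: list[float]
    upper_bounds: list[float]
    biomass_id: str | None = None
    compartment_of: dict[str, str] = field(default_factory=dict)
    # Reactions (by id) that transfer metabolites between a community member
    # and the shared compartment; empty for single-species models.
    intermicrobial: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.S = [[_to_fraction(v) for v in row] for row in self.S]
        self.validate()

    # -- structural queries -------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def column(self, j: int) -> list[Fraction]:
        return [self.S[i][j] for i in range(self.m)]

    @property
    def reversible(self) -> list[bool]:
        return [
            lb < 0 < ub for lb, ub in zip(self.lower_bounds, self.upper_bounds)
        ]

    @property
    def boundary(self) -> list[int]:
        """Indices of reactions touching exactly one metabolite."""
        out = []
        for j in range(self.n):
            nz = sum(1 for i in range(self.m) if self.S[i][j] != 0)
            if nz == 1:
                out.append(j)
        return out

    def boundary_metabolite(self, j: int) -> tuple[int, Fraction]:
        """(metabolite index, coefficient) of boundary reaction ``j``."""
        for i in range(self.m):
            if self.S[i][j] != 0:
                return i, self.S[i][j]
        raise ValueError(f"reaction {self.reaction_ids[j]} has no metabolites")

    def validate(self) -> None:
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ValidationError("duplicate metabolite identifiers")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise ValidationError("duplicate reaction identifiers")
        if len(self.S) != self.m:
            raise ValidationError("stoichiometric matrix has wrong row count")
        for row in self.S:
            if len(row) != self.n:
                raise ValidationError("stoichiometric matrix has ragged rows")
        if not (len(self.lower_bounds) == len(self.upper_bounds) == self.n):
            raise ValidationError("bounds length mismatch")
        for rid, lb, ub in zip(self.reaction_ids, self.lower_bounds, self.upper_bounds):
            if lb > ub:
                raise ValidationError(f"reaction {rid} has lb > ub")
        if self.biomass_id is not None and self.biomass_id not in self.reaction_ids:
            raise ValidationError(f"biomass reaction {self.biomass_id!r} not in model")

    # -- numeric views ------------------------------------------------------

    def S_float(self) -> np.ndarray:
        return np.array([[float(v) for v in row] for row in self.S], dtype=float)

    def to_json(self) -> dict:
        """Serialize in the common JSON CBM dialect."""
        mets = [
            {"id": mid, "compartment": self.compartment_of.get(mid, "")}
            for mid in self.metabolite_ids
        ]
        rxns = []
        for j, rid in enumerate(self.reaction_ids):
            stoich = {
                self.metabolite_ids[i]: float(self.S[i][j])
                for i in range(self.m)
                if self.S[i][j] != 0
            }
            rxns.append(
                {
                    "id": rid,
                    "metabolites": stoich,
                    "lower_bound": self.lower_bounds[j],
                    "upper_bound": self.upper_bounds[j],
                }
            )
        out = {"metabolites": mets, "reactions": rxns}
        if self.biomass_id is not None:
            out["biomass"] = self.biomass_id
        if self.intermicrobial:
            out["intermicrobial"] = sorted(self.intermicrobial)
        return out

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)


@dataclass
class StandardizedNetwork:
    """All-irreversible, nonnegative-flux re-encoding of a network.

    ``origin[k] = (j, direction)`` maps standardized reaction ``k`` back to
    original reaction ``j``; ``direction`` is ``"forward"`` or
    ``"backward"`` (the backward part of a split reversible reaction).
    ``subnetwork`` lists the standardized indices under comparison and
    ``items`` their human-readable (entity, direction) labels.
    """

    base: MetabolicNetwork
    S_std: list[list[Fraction]]
    lower_bounds: list[float]
    upper_bounds: list[float]
    origin: list[tuple[int, str]]
    subnetwork: list[int]
    biomass_index: int
    items: list[tuple[str, str]]  # parallel to subnetwork: (entity, direction)

    @property
    def n(self) -> int:
        return len(self.origin)

    @property
    def m(self) -> int:
        return len(self.S_std)

    def S_float(self) -> np.ndarray:
        return np.array([[float(v) for v in row] for row in self.S_std], dtype=float)

    def item_of(self, k: int) -> tuple[str, str]:
        return self.items[self.subnetwork.index(k)]

    def collapse(self, vector: Sequence) -> list:
        """Map a standardized flux vector back to original coordinates."""
        out = [0] * self.base.n
        for k, v in enumerate(vector):
            j, direction = self.origin[k]
            out[j] = out[j] + (v if direction == "forward" else -v)
        return out


@dataclass
class CommunitySpec:
    """Specification of a multi-species community model.

    ``members`` are (label, model) pairs; ``shared_metabolites`` can move
    between members through a shared extracellular compartment;
    ``environmental_exchanges`` is the subset that can additionally enter
    or leave the community.  ``biomass_shares`` weight each member in the
    community biomass pseudo-metabolite (equal shares by default,
    enforcing balanced growth).
    """

    members: list[tuple[str, MetabolicNetwork]]
    shared_metabolites: set[str]
    environmental_exchanges: set[str]
    biomass_shares: dict[str, float] | None = None

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.members]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate member labels")
        if not self.environmental_exchanges <= self.shared_metabolites:
            raise ValidationError("environmental exchanges must be shared metabolites")
        if self.biomass_shares is None:
            self.biomass_shares = {lab: 1.0 for lab in labels}
        if set(self.biomass_shares) != set(labels):
            raise ValidationError("biomass_shares must name every member exactly once")
        if any(w <= 0 for w in self.biomass_shares.values()):
            raise ValidationError("biomass shares must be strictly positive")
        for met in self.shared_metabolites:
            touched = False
            for _, net in self.members:
                for j in net.boundary:
                    i, _ = net.boundary_metabolite(j)
                    if net.metabolite_ids[i] == met:
                        touched = True
            if not touched:
                raise ValidationError(
                    f"shared metabolite {met!r} has no member boundary reaction"
                )


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

_BIOMASS_HINTS = ("biomass", "growth")


def _detect_biomass(reaction_ids: Iterable[str]) -> str | None:
    for rid in reaction_ids:
        if any(h in rid.lower() for h in _BIOMASS_HINTS):
            return rid
    return None


def load_model(path, dialect: str = "json", biomass: str | None = None) -> MetabolicNetwork:
    """Read a model from SBML (Level 3 + flux bounds) or the JSON CBM dialect.

    The boundary set is detected automatically (single-metabolite
    reactions); the biomass reaction is detected by id pattern unless
    ``biomass`` overrides it.
    """
    if dialect == "json":
        with open(path) as fh:
            doc = json.load(fh)
        return network_from_json(doc, biomass=biomass)
    if dialect == "sbml":
        import cobra.io

        model = cobra.io.read_sbml_model(str(path))
        return network_from_cobra(model, biomass=biomass)
    raise ValueError(f"unknown dialect {dialect!r}")


def network_from_json(doc: Mapping, biomass: str | None = None) -> MetabolicNetwork:
    met_ids = [m["id"] for m in doc["metabolites"]]
    if len(set(met_ids)) != len(met_ids):
        raise ValidationError("duplicate metabolite identifiers")
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    rxn_ids, lbs, ubs = [], [], []
    cols = []
    for r in doc["reactions"]:
        rxn_ids.append(r["id"])
        lbs.append(float(r.get("lower_bound", 0.0)))
        ubs.append(float(r.get("upper_bound", _INF)))
        col = {}
        for mid, coef in r["metabolites"].items():
            if mid not in met_index:
                raise ValidationError(
                    f"reaction {r['id']} names undeclared metabolite {mid!r}"
                )
            col[met_index[mid]] = _to_fraction(coef)
        cols.append(col)
    S = [[cols[j].get(i, Fraction(0)) for j in range(len(rxn_ids))] for i in range(len(met_ids))]
    biomass_id = biomass or doc.get("biomass") or _detect_biomass(rxn_ids)
    comp = {m["id"]: m.get("compartment", "") for m in doc["metabolites"]}
    net = MetabolicNetwork(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lower_bounds=lbs,
        upper_bounds=ubs,
        biomass_id=biomass_id,
        compartment_of=comp,
        intermicrobial=set(doc.get("intermicrobial", [])),
    )
    if net.biomass_id is None:
        raise ValidationError("no biomass reaction candidate and no override given")
    return net


def network_from_cobra(model, biomass: str | None = None) -> MetabolicNetwork:
    """Convert a cobrapy model (SBML-backed) into a MetabolicNetwork."""
    met_ids = [m.id for m in model.metabolites]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    rxn_ids = [r.id for r in model.reactions]
    m, n = len(met_ids), len(rxn_ids)
    S = [[Fraction(0)] * n for _ in range(m)]
    lbs, ubs = [], []
    for j, r in enumerate(model.reactions):
        lbs.append(float(r.lower_bound))
        ubs.append(float(r.upper_bound))
        for met, coef in r.metabolites.items():
            S[met_index[met.id]][j] = _to_fraction(coef)
    biomass_id = biomass or _detect_biomass(rxn_ids)
    if biomass_id is None:
        raise ValidationError("no biomass reaction candidate and no override given")
    comp = {met.id: met.compartment or "" for met in model.metabolites}
    return MetabolicNetwork(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lower_bounds=lbs,
        upper_bounds=ubs,
        biomass_id=biomass_id,
        compartment_of=comp,
    )


def load_e_coli_core() -> MetabolicNetwork:
    """Load the BiGG e_coli_core model shipped with cobrapy ("textbook")."""
    import os

    import cobra

    path = os.path.join(os.path.dirname(cobra.__file__), "data", "textbook.xml.gz")
    return load_model(path, dialect="sbml")


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def _boundary_direction(coef: Fraction, direction: str) -> str:
    """Direction label of a split boundary reaction.

    A boundary reaction ``met ->`` (coefficient -1) exports on forward
    flux; ``-> met`` (coefficient +1) imports on forward flux.
    """
    exports = (coef < 0) == (direction == "forward")
    return "export" if exports else "import"


def standardize(
    net: MetabolicNetwork,
    subnetwork_mode: str = "boundary",
    explicit: Sequence[str] | None = None,
) -> StandardizedNetwork:
    """Re-encode ``net`` with all reactions irreversible and flux >= 0.

    ``subnetwork_mode`` selects the comparison subnetwork: ``"boundary"``
    (split boundary reactions), ``"boundary_plus_intermicrobial"``
    (boundary plus member<->shared-compartment transfer reactions of a
    community model) or ``"explicit"`` (reaction ids in ``explicit``;
    their split parts are included).
    """
    if net.biomass_id is None:
        raise ValidationError("standardization requires a biomass reaction")
    cols: list[list[Fraction]] = []
    lbs: list[float] = []
    ubs: list[float] = []
    origin: list[tuple[int, str]] = []
    for j in range(net.n):
        lb, ub = net.lower_bounds[j], net.upper_bounds[j]
        if lb > ub:
            raise ValidationError(f"reaction {net.reaction_ids[j]} has lb > ub")
        col = net.column(j)
        if lb < 0 < ub:  # reversible: split
            cols.append(col)
            lbs.append(0.0)
            ubs.append(ub)
            origin.append((j, "forward"))
            cols.append([-v for v in col])
            lbs.append(0.0)
            ubs.append(-lb)
            origin.append((j, "backward"))
        elif ub <= 0:  # written right-to-left: flip
            cols.append([-v for v in col])
            lbs.append(max(-ub, 0.0))
            ubs.append(-lb)
            origin.append((j, "backward"))
        else:
            cols.append(col)
            lbs.append(max(lb, 0.0))
            ubs.append(ub)
            origin.append((j, "forward"))
    n_std = len(cols)
    S_std = [[cols[k][i] for k in range(n_std)] for i in range(net.m)]

    boundary = set(net.boundary)
    tagged = {net.reaction_index(rid) for rid in net.intermicrobial}
    chosen: list[int] = []
    if subnetwork_mode == "boundary":
        selected = boundary
    elif subnetwork_mode == "boundary_plus_intermicrobial":
        selected = boundary | tagged
    elif subnetwork_mode == "explicit":
        if not explicit:
            raise ValidationError("explicit subnetwork mode requires reaction ids")
        selected = {net.reaction_index(rid) for rid in explicit}
    else:
        raise ValueError(f"unknown subnetwork mode {subnetwork_mode!r}")
    items: list[tuple[str, str]] = []
    for k, (j, direction) in enumerate(origin):
        if j not in selected:
            continue
        chosen.append(k)
        rid = net.reaction_ids[j]
        if j in boundary:
            i, coef = net.boundary_metabolite(j)
            entity = net.metabolite_ids[i]
            items.append((entity, _boundary_direction(coef, direction)))
        else:
            # intermicrobial transfer: member-qualified shared metabolite,
            # direction from the member's perspective (export = deposits
            # into the shared compartment)
            shared = [
                (i, net.S[i][j])
                for i in range(net.m)
                if net.S[i][j] != 0 and net.metabolite_ids[i].endswith("__shared")
            ]
            if len(shared) == 1 and "__" in rid:
                i, coef = shared[0]
                member = rid.split("__", 1)[0]
                met = net.metabolite_ids[i][: -len("__shared")]
                exports = (coef > 0) == (direction == "forward")
                items.append((f"{member}::{met}", "export" if exports else "import"))
            else:
                items.append(
                    (rid, "export" if direction == "forward" else "import")
                )
    if not chosen:
        raise ValidationError("empty subnetwork")

    bio_j = net.reaction_index(net.biomass_id)
    biomass_index = next(
        k for k, (j, d) in enumerate(origin) if j == bio_j and d == "forward"
    )
    return StandardizedNetwork(
        base=net,
        S_std=S_std,
        lower_bounds=lbs,
        upper_bounds=ubs,
        origin=origin,
        subnetwork=chosen,
        biomass_index=biomass_index,
        items=items,
    )


# ---------------------------------------------------------------------------
# community merging
# ---------------------------------------------------------------------------

def merge_community(spec: CommunitySpec) -> MetabolicNetwork:
    """Merge community members into one model with a shared compartment.

    Member reactions are id-prefixed ``<member>__<reaction>``.  Member
    boundary reactions for shared metabolites are rewired to
    ``<met>__shared`` metabolites (becoming internal transfer reactions,
    recorded in ``intermicrobial``); only ``environmental_exchanges`` get
    new boundary reactions ``EX_<met>__shared``.  A community biomass
    pseudo-metabolite is produced from the member biomasses in proportion
    ``biomass_shares`` so that no member can grow unless all do.
    """
    met_ids: list[str] = []
    comp: dict[str, str] = {}
    rxn_ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []
    cols: list[dict[int, Fraction]] = []
    met_index: dict[str, int] = {}
    intermicrobial: set[str] = set()

    def add_met(mid: str, compartment: str) -> int:
        if mid not in met_index:
            met_index[mid] = len(met_ids)
            met_ids.append(mid)
            comp[mid] = compartment
        return met_index[mid]

    for met in sorted(spec.shared_metabolites):
        add_met(f"{met}__shared", "shared")

    biomass_mets: dict[str, int] = {}
    for label, net in spec.members:
        if net.biomass_id is None:
            raise ValidationError(f"member {label} lacks a biomass reaction")
        boundary = set(net.boundary)
        for i, mid in enumerate(net.metabolite_ids):
            add_met(f"{label}__{mid}", net.compartment_of.get(mid, label))
        for j, rid in enumerate(net.reaction_ids):
            new_id = f"{label}__{rid}"
            if new_id in set(rxn_ids):
                raise ValidationError(f"duplicate prefixed id {new_id}")
            col: dict[int, Fraction] = {}
            shared_target = None
            if j in boundary:
                i, coef = net.boundary_metabolite(j)
                mid = net.metabolite_ids[i]
                if mid in spec.shared_metabolites:
                    shared_target = (i, coef, mid)
            for i in range(net.m):
                v = net.S[i][j]
                if v == 0:
                    continue
                col[met_index[f"{label}__{net.metabolite_ids[i]}"]] = v
            if shared_target is not None:
                # boundary "met ->" removed met from the member; now it
                # deposits it into the shared compartment instead.
                i, coef, mid = shared_target
                col[met_index[f"{mid}__shared"]] = -coef
                intermicrobial.add(new_id)
            rxn_ids.append(new_id)
            lbs.append(net.lower_bounds[j])
            ubs.append(net.upper_bounds[j])
            cols.append(col)
        # member biomass metabolite produced by its biomass reaction
        bm_id = add_met(f"{label}__BIOMASS", label)
        biomass_mets[label] = bm_id
        bio_col = cols[rxn_ids.index(f"{label}__{net.biomass_id}")]
        bio_col[bm_id] = Fraction(1)

    # environmental exchanges for the shared compartment
    for met in sorted(spec.environmental_exchanges):
        rxn_ids.append(f"EX_{met}__shared")
        lbs.append(-_INF)
        ubs.append(_INF)
        cols.append({met_index[f"{met}__shared"]: Fraction(-1)})

    # community biomass: equal (or weighted) shares of member biomasses
    cbm = add_met("BIOMASS__community", "shared")
    total = sum(spec.biomass_shares.values())
    col = {
        biomass_mets[lab]: -Fraction(repr(w / total))
        for lab, w in spec.biomass_shares.items()
    }
    col[cbm] = Fraction(1)
    rxn_ids.append("BIOMASS_community")
    lbs.append(0.0)
    ubs.append(_INF)
    cols.append(col)
    rxn_ids.append("EX_BIOMASS__community")
    lbs.append(0.0)
    ubs.append(_INF)
    cols.append({cbm: Fraction(-1)})

    m, n = len(met_ids), len(rxn_ids)
    S = [[Fraction(0)] * n for _ in range(m)]
    for jcol, col in enumerate(cols):
        for i, v in col.items():
            S[i][jcol] = v
    return MetabolicNetwork(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lower_bounds=lbs,
        upper_bounds=ubs,
        biomass_id="BIOMASS_community",
        compartment_of=comp,
        intermicrobial=intermicrobial,
    )


# ---------------------------------------------------------------------------
# flux variability analysis
# ---------------------------------------------------------------------------

def flux_variability(
    net: MetabolicNetwork,
    reactions: Sequence[int] | None = None,
    growth_floor: float = 0.0,
) -> list[tuple[str, float, float]]:
    """Per-reaction LP min/max flux subject to steady state, bounds, and
    biomass >= ``growth_floor``."""
    if reactions is None:
        reactions = list(range(net.n))
    S = net.S_float()
    lbs = list(net.lower_bounds)
    ubs = list(net.upper_bounds)
    if growth_floor > 0:
        if net.biomass_id is None:
            raise ValidationError("growth floor requires a biomass reaction")
        jb = net.reaction_index(net.biomass_id)
        lbs[jb] = max(lbs[jb], growth_floor)
    bounds = list(zip(lbs, ubs))
    out = []
    for j in reactions:
        c = np.zeros(net.n)
        c[j] = 1.0
        lo = solve_lp(c, A_eq=S, b_eq=np.zeros(net.m), bounds=bounds)
        hi = solve_lp(-c, A_eq=S, b_eq=np.zeros(net.m), bounds=bounds)
        vmin = -math.inf if lo.status == 3 else float(lo.fun)
        vmax = math.inf if hi.status == 3 else float(-hi.fun)
        out.append((net.reaction_ids[j], vmin, vmax))
    return out
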