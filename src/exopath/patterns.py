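"""Flux patterns and the pathway-definition hierarchy.

A flux pattern is the sign pattern of a flux vector restricted to the
analysis subnetwork: the set of (entity, direction) items with nonzero
flux, where an entity is an exchanged metabolite (member-qualified in
community models) or a subnetwork reaction and the direction is import
or export.  Whether the underlying flux vector carried positive biomass
flux is tracked as a growth flag rather than as an item, so patterns
from different pathway definitions are directly comparable.

Four pathway definitions are compared as pattern collections:

* EFM patterns — signs of elementary flux modes restricted to the
  subnetwork;
* ECM patterns — signs of the projected cone's extreme rays;
* EFPs — the patterns that cannot be written as a cancellation-free
  union of other patterns (extracted by union closure);
* MPs — the support-minimal growth-supporting patterns, enumerated
  directly with a binary-integer master program alternated with slave
  feasibility LPs.

Their unique growth-supporting pattern sets are related by
``P_MP ⊆ P_EFP ⊆ P_ECM ⊆ P_EFM``; :func:`verify_hierarchy` checks the
chain constructively and returns counterexample witnesses if it fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from ._lp import lp_feasible, solve_bip
from .network import StandardizedNetwork

__all__ = [
    "FluxPattern",
    "PatternCollection",
    "ComparisonReport",
    "to_patterns",
    "filter_growth",
    "extract_efps",
    "enumerate_mps",
    "compare_collections",
    "verify_hierarchy",
]

Item = tuple[str, str]  # (entity, direction)

ACTIVITY_TOL = 1e-6  # nonzero-flux threshold for float vectors


@dataclass(frozen=True)
class FluxPattern:
    items: frozenset[Item]
    growth: bool

    def __len__(self) -> int:
        return len(self.items)

    def sorted_items(self) -> list[Item]:
        return sorted(self.items)


@dataclass
class PatternCollection:
    definition: str  # EFM | ECM | EFP | MP
    patterns: list[FluxPattern]
    universe: list[Item]
    provenance: str = ""
    # optional LP witnesses (MPs) keyed by pattern position
    witnesses: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.patterns)

    def item_sets(self) -> set[frozenset[Item]]:
        return {p.items for p in self.patterns}

    def __iter__(self):
        return iter(self.patterns)


def _is_active(v) -> bool:
    if isinstance(v, (int, Fraction)):
        return v != 0
    return abs(v) > ACTIVITY_TOL


def to_patterns(
    vectors,
    std: StandardizedNetwork,
    definition: str = "EFM",
    biomass_fluxes=None,
    provenance: str = "",
) -> PatternCollection:
    """Map subnetwork flux vectors to unique flux patterns.

    ``vectors`` are over ``std.subnetwork`` coordinates (nonnegative,
    split).  Duplicate item sets collapse to one pattern; growth flags
    are OR-merged.  Growth is read from the biomass split coordinate if
    the biomass reaction lies in the subnetwork, otherwise from the
    parallel ``biomass_fluxes`` sequence.
    """
    n_sub = len(std.subnetwork)
    j_bio = std.origin[std.biomass_index][0]
    bio_pos = next(
        (
            p
            for p, k in enumerate(std.subnetwork)
            if std.origin[k] == (j_bio, "forward")
        ),
        None,
    )
    if bio_pos is None and biomass_fluxes is None:
        raise ValueError(
            "biomass reaction is not in the subnetwork; biomass_fluxes required"
        )
    merged: dict[frozenset[Item], bool] = {}
    for idx, vec in enumerate(vectors):
        if len(vec) != n_sub:
            raise ValueError("vector dimension mismatch with subnetwork")
        items = frozenset(
            std.items[p] for p in range(n_sub) if _is_active(vec[p])
        )
        if bio_pos is not None:
            grows = _is_active(vec[bio_pos]) and vec[bio_pos] > 0
        else:
            grows = _is_active(biomass_fluxes[idx]) and biomass_fluxes[idx] > 0
        merged[items] = merged.get(items, False) or grows
    patterns = [
        FluxPattern(items=items, growth=g)
        for items, g in sorted(merged.items(), key=lambda kv: sorted(kv[0]))
    ]
    return PatternCollection(
        definition=definition,
        patterns=patterns,
        universe=list(std.items),
        provenance=provenance,
    )


def filter_growth(coll: PatternCollection) -> PatternCollection:
    """Keep only growth-supporting patterns (positive biomass flux)."""
    return PatternCollection(
        definition=coll.definition,
        patterns=[p for p in coll.patterns if p.growth],
        universe=coll.universe,
        provenance=coll.provenance,
    )


def extract_efps(coll: PatternCollection) -> PatternCollection:
    """Elementary flux patterns by union closure.

    A pattern is elementary iff it cannot be built from other patterns
    without cancellations, i.e. iff the union of all patterns that are
    proper subsets of it differs from the pattern itself.  Valid when
    ``coll`` holds the complete unique pattern set of the EFMs or ECMs of
    the subnetwork.
    """
    sets = [p.items for p in coll.patterns]
    kept = []
    for p in coll.patterns:
        union: set[Item] = set()
        for q in sets:
            if q < p.items:
                union |= q
        if frozenset(union) != p.items:
            kept.append(FluxPattern(items=p.items, growth=p.growth))
    return PatternCollection(
        definition="EFP",
        patterns=kept,
        universe=coll.universe,
        provenance=coll.provenance,
    )


# ---------------------------------------------------------------------------
# minimal pathways
# ---------------------------------------------------------------------------

def enumerate_mps(
    std: StandardizedNetwork,
    growth_floor: float = 1e-4,
    use_bounds: bool = True,
    provenance: str = "",
) -> PatternCollection:
    """Enumerate all minimal pathways of the subnetwork.

    An MP is a minimal subnetwork subset T such that a feasible flux
    vector exists with subnetwork support contained in T and biomass flux
    at least ``growth_floor``.  The search alternates a binary-integer
    master program over subnetwork items with slave feasibility LPs: the
    master proposes the largest candidate not containing an already-found
    MP, the candidate's witness support is shrunk to minimality by greedy
    single-item removal with LP re-checks, and each MP (or infeasible
    candidate) is excluded by a cut.  When the master turns infeasible the
    enumeration is complete.

    If the model cannot reach the growth floor at all, the explicit
    "no MPs" result is an empty collection.
    """
    n = std.n
    sub = list(std.subnetwork)
    ns = len(sub)
    S = std.S_float()
    if use_bounds:
        base_bounds = [
            (std.lower_bounds[k], None if std.upper_bounds[k] == np.inf else std.upper_bounds[k])
            for k in range(n)
        ]
    else:
        base_bounds = [(0.0, None)] * n
    jb = std.biomass_index

    def feasible(allowed: set[int]):
        bounds = list(base_bounds)
        for pos, k in enumerate(sub):
            if pos not in allowed:
                bounds[k] = (0.0, 0.0)
        lo, hi = bounds[jb]
        bounds[jb] = (max(lo, growth_floor), hi)
        return lp_feasible(A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds)

    if feasible(set(range(ns))) is None:
        return PatternCollection(
            definition="MP", patterns=[], universe=list(std.items), provenance=provenance
        )

    cuts_A: list[np.ndarray] = []
    cuts_b: list[float] = []
    mps: list[frozenset[int]] = []
    witnesses: dict[int, np.ndarray] = {}
    while True:
        y = solve_bip(
            np.ones(ns),
            A_ub=np.array(cuts_A) if cuts_A else None,
            b_ub=np.array(cuts_b) if cuts_b else None,
            maximize=True,
        )
        if y is None:
            break
        candidate = {i for i in range(ns) if y[i]}
        witness = feasible(candidate)
        if witness is None:
            # no feasible flux inside the candidate: exclude all subsets
            row = np.zeros(ns)
            for i in range(ns):
                if i not in candidate:
                    row[i] = -1.0
            cuts_A.append(row)
            cuts_b.append(-1.0)  # sum_{i not in C} y_i >= 1
            continue
        support = {
            i for i in candidate if abs(witness[sub[i]]) > ACTIVITY_TOL
        }
        current = support if feasible(support) is not None else candidate
        for i in sorted(current, reverse=True):
            trial = current - {i}
            w = feasible(trial)
            if w is not None:
                current = trial
                witness = w
        mp = frozenset(current)
        witnesses[len(mps)] = witness
        mps.append(mp)
        row = np.zeros(ns)
        for i in mp:
            row[i] = 1.0
        cuts_A.append(row)
        cuts_b.append(len(mp) - 1.0)  # exclude supersets of this MP

    patterns = [
        FluxPattern(items=frozenset(std.items[i] for i in mp), growth=True)
        for mp in mps
    ]
    order = sorted(range(len(patterns)), key=lambda i: sorted(patterns[i].items))
    return PatternCollection(
        definition="MP",
        patterns=[patterns[i] for i in order],
        universe=list(std.items),
        provenance=provenance,
        witnesses={new: witnesses[old] for new, old in enumerate(order)},
    )


# ---------------------------------------------------------------------------
# comparison and hierarchy
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    lengths: pd.DataFrame  # definition, pattern index, length
    mp_subset_counts: pd.DataFrame  # per pattern: how many MPs are subsets
    superset_counts: pd.DataFrame  # per pattern: how many EFM/ECM patterns are supersets
    venn: pd.DataFrame  # pairwise overlap sizes between definitions
    hierarchy_holds: bool
    hierarchy_equal: bool
    witnesses: dict[str, list[frozenset[Item]]]


def compare_collections(colls: list[PatternCollection]) -> ComparisonReport:
    """Pairwise subset/superset statistics across pathway definitions.

    All collections must share provenance (same model, subnetwork, and
    growth handling); patterns are compared as item sets.
    """
    provs = {c.provenance for c in colls}
    if len(provs) > 1:
        raise ValueError(f"mismatched provenance: {sorted(provs)}")
    by_def = {c.definition: c for c in colls}

    lengths = pd.DataFrame(
        [
            {"definition": c.definition, "pattern": i, "length": len(p)}
            for c in colls
            for i, p in enumerate(c.patterns)
        ]
    )

    mp_rows = []
    if "MP" in by_def:
        mp_sets = [p.items for p in by_def["MP"].patterns]
        for c in colls:
            for i, p in enumerate(c.patterns):
                cnt = sum(1 for m in mp_sets if m <= p.items)
                mp_rows.append(
                    {"definition": c.definition, "pattern": i, "n_mp_subsets": cnt}
                )
    mp_subset_counts = pd.DataFrame(mp_rows)

    sup_rows = []
    for source in ("EFM", "ECM"):
        if source not in by_def:
            continue
        src_sets = [p.items for p in by_def[source].patterns]
        for c in colls:
            for i, p in enumerate(c.patterns):
                cnt = sum(1 for s in src_sets if s >= p.items)
                sup_rows.append(
                    {
                        "definition": c.definition,
                        "pattern": i,
                        "source": source,
                        "n_supersets": cnt,
                    }
                )
    superset_counts = pd.DataFrame(sup_rows)

    venn_rows = []
    defs = [c.definition for c in colls]
    for a in defs:
        for b in defs:
            venn_rows.append(
                {
                    "a": a,
                    "b": b,
                    "overlap": len(by_def[a].item_sets() & by_def[b].item_sets()),
                }
            )
    venn = pd.DataFrame(venn_rows)

    holds, equal, witnesses = _hierarchy({d: by_def[d] for d in by_def})
    return ComparisonReport(
        lengths=lengths,
        mp_subset_counts=mp_subset_counts,
        superset_counts=superset_counts,
        venn=venn,
        hierarchy_holds=holds,
        hierarchy_equal=equal,
        witnesses=witnesses,
    )


_CHAIN = ["MP", "EFP", "ECM", "EFM"]


def _hierarchy(by_def: dict[str, PatternCollection]):
    present = [d for d in _CHAIN if d in by_def]
    holds = True
    witnesses: dict[str, list[frozenset[Item]]] = {}
    for lo, hi in zip(present, present[1:]):
        missing = sorted(
            by_def[lo].item_sets() - by_def[hi].item_sets(), key=sorted
        )
        if missing:
            holds = False
            witnesses[f"{lo}⊄{hi}"] = missing
    sets = [by_def[d].item_sets() for d in present]
    equal = holds and all(s == sets[0] for s in sets[1:])
    return holds, equal, witnesses


def verify_hierarchy(colls: list[PatternCollection]):
    """Check ``P_MP ⊆ P_EFP ⊆ P_ECM ⊆ P_EFM`` over the supplied tiers.

    Returns ``(holds, equal, witnesses)``: ``equal`` flags the degenerate
    case where all present tiers coincide (every pattern support-minimal);
    ``witnesses`` maps each violated inclusion to the offending patterns.
    """
    by_def = {c.definition: c for c in colls}
    return _hierarchy(by_def)
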