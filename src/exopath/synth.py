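"""Synthetic networks and independent brute-force oracles.

This module generates the fixtures the test suite runs on — a fixed toy
network with known ground truth, randomized small mass-balanced networks
with a guaranteed-growing biomass reaction, and a stylized three-member
cross-feeding community — plus exhaustive oracles for every enumerative
stage.  The oracles deliberately share no code with the double
description / projection / BIP enumerators: minimal supports come from a
numpy nullity test per candidate support, minimal feasible subsets from
an exhaustive LP sweep, and elementary patterns from subcollection
unions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .network import CommunitySpec, MetabolicNetwork, StandardizedNetwork, merge_community

__all__ = [
    "NetworkRecipe",
    "make_toy_network",
    "random_network",
    "make_toy_community",
    "make_rare_pattern_network",
    "oracle_minimal_supports",
    "oracle_minimal_feasible_subsets",
    "oracle_elementary_patterns",
]

_INF = math.inf


# ---------------------------------------------------------------------------
# fixed toy network
# ---------------------------------------------------------------------------

def make_toy_network() -> MetabolicNetwork:
    """Small network with five internal reactions, three boundary
    reactions, and five metabolites (A-D and biomass BM).

    Routes: A is imported (two A per C formed in r1) and carbon flows via
    C to either biomass (through D), to secreted B, or — consuming extra
    imported B — to biomass at higher yield.  Exactly one exchange
    pattern is support-minimal for growth: import A, export BM.
    """
    mets = ["A", "B", "C", "D", "BM"]
    reactions = {
        # id: (stoichiometry, lb, ub)
        "r1": ({"A": -2, "C": 1}, 0.0, _INF),
        "r2": ({"C": -1, "D": 1}, 0.0, _INF),
        "r3": ({"D": -1, "BM": 1}, 0.0, _INF),
        "r4": ({"C": -1, "B": -1, "D": 2}, 0.0, _INF),
        "r5": ({"C": -1, "B": 1}, 0.0, _INF),
        "b1": ({"A": -1}, -_INF, 0.0),  # A import only
        "b2": ({"B": -1}, -_INF, _INF),  # B import or export
        "b3": ({"BM": -1}, 0.0, _INF),  # biomass export; flux = growth rate
    }
    rids = list(reactions)
    S = [
        [Fraction(reactions[r][0].get(met, 0)) for r in rids]
        for met in mets
    ]
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lower_bounds=[reactions[r][1] for r in rids],
        upper_bounds=[reactions[r][2] for r in rids],
        biomass_id="b3",
        compartment_of={m: "e" if m in {"A", "B", "BM"} else "c" for m in mets},
    )


#: Hand-derived ground truth for :func:`make_toy_network` (verified by the
#: oracles in the test suite).  Conversions are canonically scaled (first
#: exchange coordinate at magnitude 1); four EFMs exist because besides
#: the three boundary-distinct routes there is one that balances B
#: through an internal loop (r5 feeding r4) without touching b2.
TOY_GROUND_TRUTH = {
    "n_efms": 4,
    "n_ecms": 3,
    "ecm_conversions": [
        {"A": Fraction(-1), "B": Fraction(1, 2)},
        {"A": Fraction(-1), "BM": Fraction(1, 2)},
        {"A": Fraction(-1), "B": Fraction(-1, 2), "BM": Fraction(1)},
    ],
    "efp_patterns": [
        frozenset({("A", "import"), ("B", "export")}),
        frozenset({("A", "import"), ("BM", "export")}),
        frozenset({("A", "import"), ("B", "import"), ("BM", "export")}),
    ],
    "mp_patterns": [frozenset({("A", "import"), ("BM", "export")})],
}


# ---------------------------------------------------------------------------
# random networks
# ---------------------------------------------------------------------------

@dataclass
class NetworkRecipe:
    """Parameters of the random-network generator.

    Sizes default to the desk scale the enumerators and oracles are
    exercised at (a handful of metabolites, around ten reactions);
    stoichiometric coefficients are small integers and every generated
    network is rejection-sampled until biomass export is feasible at
    1e-3.
    """

    n_metabolites: int = 4
    n_internal: int = 5
    n_boundary: int = 3
    p_reversible: float = 0.3
    max_coefficient: int = 2
    n_biomass_precursors: int = 1
    seed: int = 0
    rejection_budget: int = 200


def random_network(recipe: NetworkRecipe) -> MetabolicNetwork:
    """Generate a mass-balanced random network meeting the recipe.

    Deterministic for a fixed seed; growth feasibility (biomass export
    >= 1e-3) is certified by LP before returning.
    """
    rng = np.random.default_rng(recipe.seed)
    for _ in range(recipe.rejection_budget):
        net = _draw_network(recipe, rng)
        if net is None:
            continue
        if _growth_feasible(net, 1e-3):
            return net
    raise RuntimeError("rejection budget exhausted; recipe too restrictive")


def _draw_network(recipe: NetworkRecipe, rng) -> MetabolicNetwork | None:
    m = recipe.n_metabolites
    mets = [f"M{i}" for i in range(m)] + ["BM"]
    cols: list[dict[str, Fraction]] = []
    rids, lbs, ubs = [], [], []

    def add(rid, stoich, lb, ub):
        rids.append(rid)
        cols.append({k: Fraction(v) for k, v in stoich.items()})
        lbs.append(lb)
        ubs.append(ub)

    for t in range(recipe.n_internal):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        chosen = rng.permutation(m)
        subs = chosen[:n_sub]
        prods = chosen[n_sub : n_sub + n_prod]
        if len(prods) == 0:
            return None
        stoich = {}
        for i in subs:
            stoich[f"M{i}"] = -int(rng.integers(1, recipe.max_coefficient + 1))
        for i in prods:
            stoich[f"M{i}"] = int(rng.integers(1, recipe.max_coefficient + 1))
        if rng.random() < recipe.p_reversible:
            add(f"r{t}", stoich, -10.0, 10.0)
        else:
            add(f"r{t}", stoich, 0.0, 10.0)

    boundary_mets = rng.choice(m, size=min(recipe.n_boundary, m), replace=False)
    for i in sorted(boundary_mets):
        kind = rng.random()
        if kind < 0.4:
            lb, ub = -10.0, 0.0  # import only
        elif kind < 0.6:
            lb, ub = 0.0, 10.0  # export only
        else:
            lb, ub = -10.0, 10.0
        add(f"EX_M{i}", {f"M{i}": -1}, lb, ub)

    k = min(recipe.n_biomass_precursors, m)
    precursors = rng.choice(m, size=k, replace=False)
    stoich = {f"M{i}": -1 for i in precursors}
    stoich["BM"] = 1
    add("biomass", stoich, 0.0, 10.0)
    add("EX_BM", {"BM": -1}, 0.0, 10.0)

    S = [[cols[j].get(met, Fraction(0)) for j in range(len(rids))] for met in mets]
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lower_bounds=lbs,
        upper_bounds=ubs,
        biomass_id="EX_BM",
    )


def _growth_feasible(net: MetabolicNetwork, floor: float) -> bool:
    S = net.S_float()
    lbs = list(net.lower_bounds)
    ubs = list(net.upper_bounds)
    jb = net.reaction_index(net.biomass_id)
    lbs[jb] = max(lbs[jb], floor)
    res = linprog(
        np.zeros(net.n),
        A_eq=S,
        b_eq=np.zeros(net.m),
        bounds=list(zip(lbs, ubs)),
        method="highs",
    )
    return res.status == 0


# ---------------------------------------------------------------------------
# toy cross-feeding community
# ---------------------------------------------------------------------------

def _member(mets, reactions, biomass_id) -> MetabolicNetwork:
    rids = list(reactions)
    S = [
        [Fraction(reactions[r][0].get(met, 0)) for r in rids]
        for met in mets
    ]
    return MetabolicNetwork(
        metabolite_ids=list(mets),
        reaction_ids=rids,
        S=S,
        lower_bounds=[reactions[r][1] for r in rids],
        upper_bounds=[reactions[r][2] for r in rids],
        biomass_id=biomass_id,
    )


def make_toy_community(seed: int = 0) -> tuple[CommunitySpec, MetabolicNetwork]:
    """Three stylized members with obligate cross-feeding.

    * ``pho`` — a phototroph: fixes CO2 with light, secreting O2 and an
      organic acid (acetate) besides growing on fixed carbon + ammonia.
    * ``het`` — an (aerobic) photoheterotroph stand-in: grows on the
      phototroph's acetate and O2, respiring CO2 and fermenting part of
      the acetate to H2.
    * ``red`` — a reducer: grows on H2 + CO2 + ammonia.

    Only light, CO2 and ammonia are exchangeable with the environment, so
    acetate, O2 and H2 must move between members; blocking any single
    member makes community growth infeasible through the equal-share
    community biomass.  ``seed`` is accepted for interface uniformity —
    the community is fixed.
    """
    del seed
    pho = _member(
        ["light", "co2", "nh4", "cx", "o2", "ac", "bm"],
        {
            "photo": ({"light": -1, "co2": -1, "cx": 1, "o2": 1}, 0.0, _INF),
            "grow": ({"cx": -1, "nh4": -1, "bm": 1}, 0.0, _INF),
            "ferm": ({"cx": -1, "ac": 1}, 0.0, _INF),
            "EX_light": ({"light": -1}, -10.0, 0.0),
            "EX_co2": ({"co2": -1}, -10.0, 10.0),
            "EX_nh4": ({"nh4": -1}, -10.0, 0.0),
            "EX_o2": ({"o2": -1}, 0.0, 10.0),
            "EX_ac": ({"ac": -1}, 0.0, 10.0),
            "EX_bm": ({"bm": -1}, 0.0, _INF),
        },
        "EX_bm",
    )
    het = _member(
        ["ac", "o2", "nh4", "co2", "h2", "bm"],
        {
            "resp": ({"ac": -1, "o2": -1, "nh4": -1, "bm": 1, "co2": 1}, 0.0, _INF),
            # anaerobic route: slower growth (2 acetate per biomass), H2 waste
            "ferm_grow": (
                {"ac": -2, "nh4": -1, "bm": 1, "h2": 1, "co2": 2},
                0.0,
                _INF,
            ),
            "ferm2": ({"ac": -1, "h2": 1, "co2": 1}, 0.0, _INF),
            "EX_ac": ({"ac": -1}, -10.0, 0.0),
            "EX_o2": ({"o2": -1}, -10.0, 0.0),
            "EX_nh4": ({"nh4": -1}, -10.0, 0.0),
            "EX_co2": ({"co2": -1}, 0.0, 10.0),
            "EX_h2": ({"h2": -1}, 0.0, 10.0),
            "EX_bm": ({"bm": -1}, 0.0, _INF),
        },
        "EX_bm",
    )
    red = _member(
        ["h2", "co2", "nh4", "bm"],
        {
            "grow3": ({"h2": -2, "co2": -1, "nh4": -1, "bm": 1}, 0.0, _INF),
            "EX_h2": ({"h2": -1}, -10.0, 0.0),
            "EX_co2": ({"co2": -1}, -10.0, 10.0),
            "EX_nh4": ({"nh4": -1}, -10.0, 0.0),
            "EX_bm": ({"bm": -1}, 0.0, _INF),
        },
        "EX_bm",
    )
    spec = CommunitySpec(
        members=[("pho", pho), ("het", het), ("red", red)],
        shared_metabolites={"light", "co2", "nh4", "ac", "o2", "h2"},
        environmental_exchanges={"light", "co2", "nh4", "o2"},
    )
    merged = merge_community(spec)
    # excess photosynthetic O2 vents to the environment but cannot be
    # supplied by it, keeping the phototroph the community's only O2 source
    j = merged.reaction_index("EX_o2__shared")
    merged.lower_bounds[j] = 0.0
    return spec, merged


def make_rare_pattern_network() -> MetabolicNetwork:
    """Sampling fixture with a tiny-volume exchange region.

    Biomass can be made from imported A (wide flux ranges) or from
    imported B, but net B uptake is capped at 1e-3 while every other
    range spans several units — so the sub-region of the flux polytope
    with B import has vanishing volume and global uniform sampling
    practically never visits it, although the pattern {B import, BM
    export} is a valid minimal pathway.
    """
    mets = ["A", "B", "BM"]
    reactions = {
        "rA": ({"A": -1, "BM": 1}, 0.0, _INF),
        "rB": ({"B": -1, "BM": 1}, 0.0, _INF),
        "rAB": ({"A": -1, "B": 1}, 0.0, _INF),  # makes B exportable
        "EX_A": ({"A": -1}, -1000.0, 0.0),
        "EX_B": ({"B": -1}, -1e-3, 1000.0),
        "EX_BM": ({"BM": -1}, 0.0, 1000.0),
    }
    rids = list(reactions)
    S = [[Fraction(reactions[r][0].get(met, 0)) for r in rids] for met in mets]
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lower_bounds=[reactions[r][1] for r in rids],
        upper_bounds=[reactions[r][2] for r in rids],
        biomass_id="EX_BM",
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_minimal_supports(net: MetabolicNetwork, tol: float = 1e-9):
    """All elementary-mode sign patterns by exhaustive support search.

    A candidate support T is elementary iff the columns of S restricted
    to T have a one-dimensional null space whose vector is nonzero on all
    of T and sign-compatible with reaction irreversibility.  Returns a
    set of frozensets of (reaction index, sign) pairs, fully reversible
    modes in canonical orientation (first index positive).
    """
    n = net.n
    if n > 18:
        raise ValueError("oracle guard: too many reactions")
    S = net.S_float()
    reversible = net.reversible
    irrev_neg = [net.upper_bounds[j] <= 0 for j in range(n)]
    rank = np.linalg.matrix_rank(S, tol=tol) if S.size else 0
    out = set()
    for size in range(1, min(n, rank + 1) + 1):
        for T in combinations(range(n), size):
            sub = S[:, T]
            ns = null_space(sub, rcond=tol)
            if ns.shape[1] != 1:
                continue
            v = ns[:, 0]
            if np.min(np.abs(v)) < 1e-7:
                continue  # support is actually smaller
            for cand in (v, -v):
                ok = True
                for pos, j in enumerate(T):
                    if reversible[j]:
                        continue
                    allowed = -1.0 if irrev_neg[j] else 1.0
                    if cand[pos] * allowed <= 0:
                        ok = False
                        break
                if ok:
                    signs = frozenset(
                        (j, 1 if cand[pos] > 0 else -1) for pos, j in enumerate(T)
                    )
                    out.add(_canonical_signs(signs, reversible))
    return out


def _canonical_signs(signs, reversible):
    js = sorted(j for j, _ in signs)
    if all(reversible[j] for j in js):
        first = min(js)
        s_first = next(s for j, s in signs if j == first)
        if s_first < 0:
            return frozenset((j, -s) for j, s in signs)
    return frozenset(signs)


def oracle_minimal_feasible_subsets(
    std: StandardizedNetwork,
    growth_floor: float = 1e-4,
    use_bounds: bool = True,
):
    """All minimal subnetwork subsets admitting growth, by exhaustive LP.

    Sweeps subsets by increasing size, skipping supersets of already
    found minimal sets, so exactly the minimal feasible subsets remain.
    Returns frozensets of subnetwork positions.
    """
    sub = list(std.subnetwork)
    ns = len(sub)
    if ns > 14:
        raise ValueError("oracle guard: subnetwork too large")
    S = std.S_float()
    if use_bounds:
        base = [
            (std.lower_bounds[k], None if std.upper_bounds[k] == _INF else std.upper_bounds[k])
            for k in range(std.n)
        ]
    else:
        base = [(0.0, None)] * std.n
    jb = std.biomass_index

    def feasible(T):
        bounds = list(base)
        for pos, k in enumerate(sub):
            if pos not in T:
                bounds[k] = (0.0, 0.0)
        lo, hi = bounds[jb]
        bounds[jb] = (max(lo, growth_floor), hi)
        res = linprog(
            np.zeros(std.n),
            A_eq=S,
            b_eq=np.zeros(S.shape[0]),
            bounds=bounds,
            method="highs",
        )
        return res.status == 0

    found: list[frozenset[int]] = []
    for size in range(0, ns + 1):
        for T in combinations(range(ns), size):
            Tset = frozenset(T)
            if any(f <= Tset for f in found):
                continue
            if feasible(Tset):
                found.append(Tset)
    return set(found)


def oracle_elementary_patterns(patterns):
    """Patterns not expressible as a union of other patterns.

    Exhaustive: for each pattern, searches subcollections of its proper
    sub-patterns for a union equal to the pattern (with early exit); for
    large candidate lists the equivalent union-of-all test is used.
    """
    pats = [frozenset(p) for p in patterns]
    if len(pats) > 2**14:
        raise ValueError("oracle guard: too many patterns")
    out = set()
    for p in pats:
        cands = [q for q in pats if q < p]
        if len(cands) <= 16:
            buildable = _union_search(p, cands)
        else:
            buildable = frozenset().union(*cands) == p if cands else False
        if not buildable:
            out.add(p)
    return out


def _union_search(target, cands):
    total = len(cands)
    for mask in range(1, 1 << total):
        u = set()
        for i in range(total):
            if mask & (1 << i):
                u |= cands[i]
        if frozenset(u) == target:
            return True
    return False
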