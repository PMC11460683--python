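import json
import math
from fractions import Fraction
from itertools import combinations, product

import numpy as np
import pytest

from exopath.network import (
    CommunitySpec,
    MetabolicNetwork,
    ValidationError,
    flux_variability,
    load_model,
    merge_community,
    network_from_json,
    standardize,
)
from exopath._lp import lp_feasible


def test_json_round_trip_identity(minimal_json_model):
    net = load_model(minimal_json_model, dialect="json")
    assert net.m == 2 and net.n == 3
    assert net.biomass_id == "b2"
    assert set(net.boundary) == {0, 2}
    doc = net.to_json()
    again = network_from_json(doc)
    assert again.reaction_ids == net.reaction_ids
    assert again.S == net.S


def test_undeclared_metabolite_rejected():
    doc = {
        "metabolites": [{"id": "A"}],
        "reactions": [
            {"id": "r", "metabolites": {"A": -1, "ghost": 1}, "lower_bound": 0, "upper_bound": 1}
        ],
    }
    with pytest.raises(ValidationError, match="undeclared"):
        network_from_json(doc)


def test_duplicate_identifiers_rejected():
    with pytest.raises(ValidationError):
        MetabolicNetwork(
            metabolite_ids=["A", "A"],
            reaction_ids=["r"],
            S=[[1], [1]],
            lower_bounds=[0],
            upper_bounds=[1],
        )


def test_standardize_flips_negative_only_reactions(toy_net):
    # b1 has bounds (-inf, 0): written right-to-left, so its standardized
    # column is the negation with nonnegative bounds
    std = standardize(toy_net)
    j = toy_net.reaction_index("b1")
    k = next(i for i, (jj, d) in enumerate(std.origin) if jj == j)
    assert std.origin[k][1] == "backward"
    assert std.lower_bounds[k] == 0.0
    orig_col = toy_net.column(j)
    assert [std.S_std[i][k] for i in range(std.m)] == [-v for v in orig_col]


def test_standardize_splits_reversible_boundary(toy_net):
    std = standardize(toy_net)
    b2_items = [
        std.items[p]
        for p, k in enumerate(std.subnetwork)
        if std.origin[k][0] == toy_net.reaction_index("b2")
    ]
    assert sorted(b2_items) == [("B", "export"), ("B", "import")]
    # split columns of a reversible reaction are negatives of each other
    ks = [k for k, (j, _) in enumerate(std.origin) if j == toy_net.reaction_index("b2")]
    assert len(ks) == 2
    c0 = [std.S_std[i][ks[0]] for i in range(std.m)]
    c1 = [std.S_std[i][ks[1]] for i in range(std.m)]
    assert c0 == [-v for v in c1]


def test_standardize_collapse_round_trip(toy_net):
    """collapse(origin) reproduces original stoichiometry up to sign flips."""
    std = standardize(toy_net)
    for j in range(toy_net.n):
        parts = [k for k, (jj, _) in enumerate(std.origin) if jj == j]
        unit = [Fraction(0)] * std.n
        unit[parts[0]] = Fraction(1)
        back = std.collapse(unit)
        sign = 1 if std.origin[parts[0]][1] == "forward" else -1
        expected_col = [
            sign * std.S_std[i][parts[0]] for i in range(std.m)
        ]
        assert [toy_net.S[i][j] for i in range(toy_net.m)] == expected_col
        assert back[j] == sign


def test_standardized_bounds_nonnegative(toy_std):
    assert all(lb >= 0 for lb in toy_std.lower_bounds)


def test_single_member_merge_is_degenerate(toy_net):
    spec = CommunitySpec(
        members=[("only", toy_net)],
        shared_metabolites={"B"},
        environmental_exchanges={"B"},
    )
    merged = merge_community(spec)
    # all member reactions present with prefix, plus EX for B, biomass pair
    assert {f"only__{r}" for r in toy_net.reaction_ids} <= set(merged.reaction_ids)
    assert "EX_B__shared" in merged.reaction_ids
    assert merged.biomass_id == "BIOMASS_community"
    # same growth capability as the member (scaled by shares)
    S = merged.S_float()
    jb = merged.reaction_index("BIOMASS_community")
    bounds = [
        (max(lb, 0.001) if j == jb else lb, ub)
        for j, (lb, ub) in enumerate(zip(merged.lower_bounds, merged.upper_bounds))
    ]
    assert lp_feasible(A_eq=S, b_eq=np.zeros(merged.m), bounds=bounds) is not None


def test_merge_conserves_shared_metabolites(toy_community):
    """Transfer reactions move metabolites, they do not create them: the
    shared-compartment gain equals the member-compartment loss."""
    spec, merged = toy_community
    for rid in merged.intermicrobial:
        j = merged.reaction_index(rid)
        col = {
            merged.metabolite_ids[i]: merged.S[i][j]
            for i in range(merged.m)
            if merged.S[i][j] != 0
        }
        shared = [v for mid, v in col.items() if mid.endswith("__shared")]
        member = [v for mid, v in col.items() if not mid.endswith("__shared")]
        assert len(shared) == 1 and len(member) == 1
        assert shared[0] == -member[0]


def test_merged_community_counts(toy_community):
    spec, merged = toy_community
    n_members_rxns = sum(net.n for _, net in spec.members)
    # + environmental exchanges + community biomass + its exchange
    assert merged.n == n_members_rxns + len(spec.environmental_exchanges) + 2
    assert len(merged.intermicrobial) > 0


def test_blocking_any_member_kills_community_growth(toy_community):
    """Equal-share community biomass forces balanced growth."""
    spec, merged = toy_community
    S = merged.S_float()
    jb = merged.reaction_index(merged.biomass_id)

    def growth_ok(blocked=None):
        bounds = list(zip(merged.lower_bounds, merged.upper_bounds))
        bounds[jb] = (1e-3, bounds[jb][1])
        if blocked is not None:
            j = merged.reaction_index(blocked)
            bounds[j] = (0.0, 0.0)
        return lp_feasible(A_eq=S, b_eq=np.zeros(merged.m), bounds=bounds) is not None

    assert growth_ok()
    for member, _ in spec.members:
        assert not growth_ok(f"{member}__EX_bm"), member
    # blocking the phototroph's light uptake starves the whole community
    assert not growth_ok("pho__EX_light")


# ---------------------------------------------------------------------------
# flux variability
# ---------------------------------------------------------------------------

def _vertex_ranges(net, growth_floor=0.0):
    """Brute-force FVA oracle: enumerate polytope vertices directly."""
    S = net.S_float()
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n = net.n
    lbs = list(net.lower_bounds)
    ubs = list(net.upper_bounds)
    if growth_floor > 0:
        jb = net.reaction_index(net.biomass_id)
        lbs[jb] = max(lbs[jb], growth_floor)
    free = n - rank
    verts = []
    for idx in combinations(range(n), free):
        for sides in product((0, 1), repeat=free):
            A = [S[i] for i in range(S.shape[0])]
            b = [0.0] * S.shape[0]
            for j, s in zip(idx, sides):
                row = np.zeros(n)
                row[j] = 1.0
                A.append(row)
                b.append(ubs[j] if s else lbs[j])
            A = np.array(A)
            if np.linalg.matrix_rank(A) < n:
                continue
            x, *_ = np.linalg.lstsq(A, np.array(b), rcond=None)
            if np.max(np.abs(A @ x - b)) > 1e-7:
                continue
            if np.all(x >= np.array(lbs) - 1e-8) and np.all(x <= np.array(ubs) + 1e-8):
                verts.append(x)
    verts = np.array(verts)
    return verts.min(axis=0), verts.max(axis=0)


def test_fva_pinned_and_blocked_and_vertex_oracle(toy_net):
    net = MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["b1", "r1", "pin", "b2"],
        S=[[1, -1, 0, 0], [0, 1, -1, -1]],
        lower_bounds=[0, 0, 5, 0],
        upper_bounds=[10, 10, 5, 10],
        biomass_id="b2",
    )
    fva = dict((rid, (lo, hi)) for rid, lo, hi in flux_variability(net))
    assert fva["pin"] == pytest.approx((5, 5))
    # pin consumes 5 of B: b2 range [0,5], b1 = r1 in [5,10]
    lo, hi = _vertex_ranges(net)
    for j, rid in enumerate(net.reaction_ids):
        assert fva[rid][0] == pytest.approx(lo[j], abs=1e-6)
        assert fva[rid][1] == pytest.approx(hi[j], abs=1e-6)

    blocked = MetabolicNetwork(
        metabolite_ids=["A", "B", "C"],
        reaction_ids=["b1", "r1", "dead", "b2"],
        S=[[1, -1, 0, 0], [0, 1, 0, -1], [0, 0, 1, 0]],
        lower_bounds=[0, 0, 0, 0],
        upper_bounds=[10, 10, 10, 10],
        biomass_id="b2",
    )
    fvab = dict((rid, v) for rid, *v in flux_variability(blocked))
    assert fvab["dead"] == pytest.approx((0.0, 0.0))
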