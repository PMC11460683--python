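"""Flux patterns, EFP extraction, MP enumeration, and the hierarchy."""

from fractions import Fraction

import pytest

from exopath.ecm import enumerate_ecms
from exopath.efm import enumerate_efms, pattern_vectors
from exopath.network import MetabolicNetwork, standardize
from exopath.patterns import (
    FluxPattern,
    PatternCollection,
    compare_collections,
    enumerate_mps,
    extract_efps,
    filter_growth,
    to_patterns,
    verify_hierarchy,
)
from exopath.synth import (
    TOY_GROUND_TRUTH,
    NetworkRecipe,
    oracle_elementary_patterns,
    oracle_minimal_feasible_subsets,
    random_network,
)


def chain_network():
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["b1", "r1", "b2"],
        S=[[1, -1, 0], [0, 1, -1]],
        lower_bounds=[0, 0, 0],
        upper_bounds=[10, 10, 10],
        biomass_id="b2",
    )


def all_growth_tiers(net, use_bounds=False):
    std = standardize(net)
    efms = enumerate_efms(std)
    vecs, bio = pattern_vectors(efms, std)
    efm_coll = to_patterns(vecs, std, definition="EFM", biomass_fluxes=bio)
    ecms = enumerate_ecms(std)
    ecm_coll = to_patterns(
        ecms.subnetwork_vectors(),
        std,
        definition="ECM",
        biomass_fluxes=[1 if g else 0 for g in ecms.growth],
    )
    efp_coll = extract_efps(ecm_coll)
    mp_coll = enumerate_mps(std, use_bounds=use_bounds)
    return std, {
        "EFM": filter_growth(efm_coll),
        "ECM": filter_growth(ecm_coll),
        "EFP": filter_growth(efp_coll),
        "MP": mp_coll,
    }, {"EFM": efm_coll, "ECM": ecm_coll, "EFP": efp_coll}


def test_proportional_vectors_collapse_to_one_pattern(toy_std):
    n = len(toy_std.subnetwork)
    v = tuple(Fraction(1) for _ in range(n))
    w = tuple(Fraction(3) for _ in range(n))
    coll = to_patterns([v, w], toy_std, definition="EFM")
    assert coll.count == 1


def test_patterns_equal_hand_computed_sign_sets(toy_std):
    # vector using A import and BM export only
    items = toy_std.items
    vec = tuple(
        Fraction(1) if items[p] in {("A", "import"), ("BM", "export")} else Fraction(0)
        for p in range(len(items))
    )
    coll = to_patterns([vec], toy_std, definition="EFM")
    assert coll.patterns[0].items == frozenset({("A", "import"), ("BM", "export")})
    assert coll.patterns[0].growth


def test_dimension_mismatch_rejected(toy_std):
    with pytest.raises(ValueError, match="dimension"):
        to_patterns([(Fraction(1),)], toy_std)


def test_filter_growth_can_empty_a_collection(toy_std):
    items = toy_std.items
    vec = tuple(
        Fraction(1) if items[p] == ("B", "export") else Fraction(0)
        for p in range(len(items))
    )
    coll = to_patterns([vec], toy_std)
    assert filter_growth(coll).count == 0


def test_union_closure_drops_composite_pattern(toy_std):
    a, b = ("A", "import"), ("B", "export")
    coll = PatternCollection(
        definition="ECM",
        patterns=[
            FluxPattern(frozenset({a}), False),
            FluxPattern(frozenset({b}), False),
            FluxPattern(frozenset({a, b}), False),
        ],
        universe=list(toy_std.items),
    )
    efps = extract_efps(coll)
    assert efps.item_sets() == {frozenset({a}), frozenset({b})}


@pytest.mark.parametrize("seed", range(10))
def test_union_closure_matches_exhaustive_oracle(seed):
    import random

    rng = random.Random(seed)
    universe = [(f"m{i}", "export") for i in range(8)]
    fams = {
        frozenset(rng.sample(universe, rng.randint(1, 5))) for _ in range(12)
    }
    coll = PatternCollection(
        definition="ECM",
        patterns=[FluxPattern(f, True) for f in sorted(fams, key=sorted)],
        universe=universe,
    )
    assert extract_efps(coll).item_sets() == oracle_elementary_patterns(fams)


def test_empty_pattern_family_gives_empty_efps():
    assert oracle_elementary_patterns([]) == set()
    coll = PatternCollection(definition="ECM", patterns=[], universe=[])
    assert extract_efps(coll).count == 0


def test_chain_has_single_mp():
    std = standardize(chain_network())
    mps = enumerate_mps(std)
    assert mps.count == 1
    assert mps.patterns[0].items == frozenset({("A", "import"), ("B", "export")})
    assert mps.patterns[0].growth


def test_toy_mp_matches_ground_truth(toy_std):
    mps = enumerate_mps(toy_std)
    assert [p.items for p in mps.patterns] == TOY_GROUND_TRUTH["mp_patterns"]


def test_infeasible_growth_floor_gives_no_mps():
    net = chain_network()
    net.upper_bounds[2] = 0.5
    std = standardize(net)
    assert enumerate_mps(std, growth_floor=1.0).count == 0


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("use_bounds", [True, False])
def test_mps_match_exhaustive_subset_oracle(seed, use_bounds):
    net = random_network(
        NetworkRecipe(n_metabolites=4, n_internal=5, n_boundary=3, seed=seed)
    )
    std = standardize(net)
    mps = enumerate_mps(std, use_bounds=use_bounds)
    expected = oracle_minimal_feasible_subsets(std, use_bounds=use_bounds)
    got = {
        frozenset(std.items.index(it) for it in p.items) for p in mps.patterns
    }
    # oracle returns subnetwork positions; items are position-aligned
    assert got == {frozenset(t) for t in expected}


def test_compare_identical_collections(toy_std):
    mps = enumerate_mps(toy_std)
    report = compare_collections([mps])
    assert report.hierarchy_holds
    # every pattern is its own subset and superset exactly once
    assert (report.venn.overlap == mps.count).all()


def test_compare_counts_match_quadratic_recount(toy_net):
    _, growth, _ = all_growth_tiers(toy_net)
    report = compare_collections(list(growth.values()))
    mp_sets = [p.items for p in growth["MP"].patterns]
    for row in report.mp_subset_counts.itertuples():
        coll = growth[row.definition]
        p = coll.patterns[row.pattern]
        assert row.n_mp_subsets == sum(1 for m in mp_sets if m <= p.items)


def test_provenance_mismatch_rejected(toy_std):
    a = enumerate_mps(toy_std, provenance="one")
    b = enumerate_mps(toy_std, provenance="two")
    with pytest.raises(ValueError, match="provenance"):
        compare_collections([a, b])


def test_hierarchy_equality_flag(toy_std):
    mps = enumerate_mps(toy_std)
    clone = PatternCollection(
        definition="EFP", patterns=list(mps.patterns), universe=mps.universe
    )
    holds, equal, witnesses = verify_hierarchy([mps, clone])
    assert holds and equal and not witnesses


def test_toy_hierarchy_strict_chain(toy_net):
    _, growth, _ = all_growth_tiers(toy_net)
    holds, equal, _ = verify_hierarchy(list(growth.values()))
    assert holds
    assert not equal  # MP ⊊ EFP on the toy network
    assert growth["MP"].item_sets() < growth["EFP"].item_sets()


@pytest.mark.parametrize("seed", range(8))
def test_hierarchy_on_random_networks(seed):
    net = random_network(
        NetworkRecipe(n_metabolites=5, n_internal=5, n_boundary=3, seed=seed + 50)
    )
    _, growth, _ = all_growth_tiers(net)
    holds, _, witnesses = verify_hierarchy(list(growth.values()))
    assert holds, witnesses


@pytest.mark.parametrize("seed", range(8))
def test_efp_route_invariance(seed):
    """EFPs from EFM patterns equal EFPs from ECM patterns."""
    net = random_network(
        NetworkRecipe(n_metabolites=4, n_internal=5, n_boundary=3, seed=seed)
    )
    _, _, raw = all_growth_tiers(net)
    assert extract_efps(raw["EFM"]).item_sets() == extract_efps(raw["ECM"]).item_sets()


@pytest.mark.parametrize("seed", range(8))
def test_mps_are_support_minimal_efps(seed):
    net = random_network(
        NetworkRecipe(n_metabolites=4, n_internal=5, n_boundary=3, seed=seed + 25)
    )
    _, growth, _ = all_growth_tiers(net)
    efp_sets = growth["EFP"].item_sets()
    minimal = {
        p for p in efp_sets if not any(q < p for q in efp_sets)
    }
    assert growth["MP"].item_sets() == minimal


@pytest.mark.parametrize("seed", range(6))
def test_shortest_pathways_agree_across_definitions(seed):
    net = random_network(
        NetworkRecipe(n_metabolites=4, n_internal=5, n_boundary=3, seed=seed + 75)
    )
    _, growth, _ = all_growth_tiers(net)
    shortest = {}
    for name, coll in growth.items():
        if coll.count == 0:
            continue
        k = min(len(p) for p in coll.patterns)
        shortest[name] = {p.items for p in coll.patterns if len(p) == k}
    assert len({frozenset(s) for s in map(frozenset, shortest.values())}) == 1
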