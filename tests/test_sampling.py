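"""Uniform flux sampling: validity, calibration, and convergence."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import kstest

from exopath.network import MetabolicNetwork, standardize
from exopath.patterns import FluxPattern, enumerate_mps
from exopath.sampling import check_convergence, sample_fluxes, sample_per_pathway
from exopath.synth import make_rare_pattern_network


def simplex_network():
    """Three producers feeding one pinned consumer: the feasible set of
    (x1, x2, x3) is the 2-simplex {x >= 0, x1 + x2 + x3 = 1}."""
    return MetabolicNetwork(
        metabolite_ids=["M"],
        reaction_ids=["x1", "x2", "x3", "sink"],
        S=[[1, 1, 1, -1]],
        lower_bounds=[0, 0, 0, 1],
        upper_bounds=[1, 1, 1, 1],
        biomass_id="sink",
    )


def box_network():
    """Two independent exchanges through one metabolite each: a box."""
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["inA", "outA", "inB", "outB"],
        S=[[1, -1, 0, 0], [0, 0, 1, -1]],
        lower_bounds=[0, 0, 0, 0],
        upper_bounds=[1, 1, 2, 2],
        biomass_id="outA",
    )


def test_pinned_reaction_constant_across_samples():
    ss = sample_fluxes(simplex_network(), 200, growth_floor=0.0, seed=1, thinning=5)
    j = ss.reaction_ids.index("sink")
    assert np.allclose(ss.samples[:, j], 1.0, atol=1e-9)


def test_simplex_centroid_recovered_within_three_standard_errors():
    n = 10_000
    ss = sample_fluxes(simplex_network(), n, growth_floor=0.0, seed=7, thinning=10)
    # analytic centroid of the 2-simplex: (1/3, 1/3, 1/3);
    # coordinate variance of a Dirichlet(1,1,1) marginal: 1/18
    for rid in ("x1", "x2", "x3"):
        j = ss.reaction_ids.index(rid)
        mean = ss.samples[:, j].mean()
        se = np.sqrt(1.0 / 18.0) / np.sqrt(n / 50)  # conservative ESS
        assert abs(mean - 1.0 / 3.0) < 3 * se, (rid, mean)


def test_box_marginals_uniform_by_ks():
    ss = sample_fluxes(box_network(), 10_000, growth_floor=0.0, seed=3, thinning=10)
    for rid, hi in (("inA", 1.0), ("inB", 2.0)):
        j = ss.reaction_ids.index(rid)
        stat, _ = kstest(ss.samples[:, j] / hi, "uniform")
        assert stat < 0.05, (rid, stat)


def test_all_samples_inside_fva_ranges():
    ss = sample_fluxes(box_network(), 2_000, growth_floor=0.0, seed=5, thinning=5)
    assert ss.fraction_within_fva() == 1.0


def test_samples_satisfy_steady_state_and_bounds():
    net = box_network()
    ss = sample_fluxes(net, 1_000, growth_floor=0.0, seed=9, thinning=5)
    S = net.S_float()
    assert np.max(np.abs(S @ ss.samples.T)) < 1e-6
    lbs = np.array(net.lower_bounds)
    ubs = np.array(net.upper_bounds)
    assert (ss.samples >= lbs - 1e-9).all()
    assert (ss.samples <= ubs + 1e-9).all()


def test_seed_determinism():
    a = sample_fluxes(box_network(), 500, growth_floor=0.0, seed=11, thinning=5)
    b = sample_fluxes(box_network(), 500, growth_floor=0.0, seed=11, thinning=5)
    c = sample_fluxes(box_network(), 500, growth_floor=0.0, seed=12, thinning=5)
    assert np.array_equal(a.samples, b.samples)
    assert not np.array_equal(a.samples, c.samples)


def test_convergence_statistic():
    ss = sample_fluxes(box_network(), 4_000, growth_floor=0.0, seed=2, thinning=5)
    rep = check_convergence(ss)
    assert rep["passed"] and rep["max_rhat"] <= 1.05

    # identical constant chains -> statistic exactly 1
    const = sample_fluxes(simplex_network(), 400, growth_floor=0.0, seed=1, thinning=2)
    j = const.reaction_ids.index("sink")
    rep2 = check_convergence(const)
    assert rep2["rhat"][j] == pytest.approx(1.0)

    # deliberately unmixed chains fail
    bad = sample_fluxes(box_network(), 400, growth_floor=0.0, seed=4, thinning=2)
    drift = np.linspace(0, 1, bad.n)[:, None] * np.ones((1, len(bad.reaction_ids)))
    bad.samples = bad.samples + drift
    assert not check_convergence(bad)["passed"]

    with pytest.raises(ValueError, match="100 samples"):
        small = sample_fluxes(box_network(), 50, growth_floor=0.0, seed=1, thinning=2)
        check_convergence(small)


def test_rare_pattern_region_unvisited_globally_but_sampled_per_pathway():
    """A tiny-volume exchange region is missed by global sampling at
    n = 10,000 yet fully accessible when sampling its pathway alone."""
    net = make_rare_pattern_network()
    ss = sample_fluxes(net, 10_000, growth_floor=0.1, seed=13, thinning=10)
    j = ss.reaction_ids.index("EX_B")
    assert (ss.samples[:, j] < -1e-6).sum() == 0  # B never imported

    std = standardize(net)
    mps = enumerate_mps(std, growth_floor=1e-4)
    rare = FluxPattern(frozenset({("B", "import"), ("BM", "export")}), True)
    assert rare.items in mps.item_sets()
    per = sample_per_pathway(net, std, rare, 500, seed=13, growth_floor=1e-4, thinning=5)
    jb = per.reaction_ids.index("EX_B")
    assert (per.samples[:, jb] <= -1e-6 + 1e-12).all()  # B imported in every sample
    # support of every sample matches the pathway: no A import
    ja = per.reaction_ids.index("EX_A")
    assert np.allclose(per.samples[:, ja], 0.0, atol=1e-9)


def test_mp_covering_only_route_has_identical_support(toy_net):
    # bounded copy of the toy network so the polytope has finite volume
    bounded = MetabolicNetwork(
        metabolite_ids=list(toy_net.metabolite_ids),
        reaction_ids=list(toy_net.reaction_ids),
        S=[row[:] for row in toy_net.S],
        lower_bounds=[max(lb, -10.0) for lb in toy_net.lower_bounds],
        upper_bounds=[min(ub, 10.0) for ub in toy_net.upper_bounds],
        biomass_id=toy_net.biomass_id,
    )
    toy_std = standardize(bounded)
    mps = enumerate_mps(toy_std)
    mp = mps.patterns[0]
    ss = sample_per_pathway(bounded, toy_std, mp, 300, seed=21, thinning=5)
    jb1 = ss.reaction_ids.index("b1")
    jb3 = ss.reaction_ids.index("b3")
    jb2 = ss.reaction_ids.index("b2")
    assert (ss.samples[:, jb1] < 0).all()  # A imported everywhere
    assert (ss.samples[:, jb3] > 0).all()  # biomass exported everywhere
    assert np.allclose(ss.samples[:, jb2], 0.0, atol=1e-9)  # B untouched
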