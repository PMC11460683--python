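"""Uniform flux sampling of the growth-constrained flux polytope.

The sampler is artificial-centering hit-and-run (ACHR) in null-space
coordinates: feasible points are parameterized as ``r = r0 + B y`` with
``B`` an orthonormal basis of the null space of the stoichiometric
matrix, so every iterate satisfies the steady-state constraint to
machine precision and only the box bounds (plus the growth floor) limit
the line searches.  Directions are drawn through previously accepted
points relative to the running center, which adapts the proposal to the
polytope's shape; chains are thinned to reduce autocorrelation.

Per-pathway sampling restricts the polytope to one minimal pathway by
zero-fixing all subnetwork exchanges outside the pathway and giving the
pathway's own items a small activity floor, making even tiny flux
regions (which global sampling practically never visits) accessible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from ._lp import InfeasibleProblem, lp_feasible, solve_lp
from .network import MetabolicNetwork, StandardizedNetwork, flux_variability
from .patterns import FluxPattern

__all__ = [
    "SampleSet",
    "sample_fluxes",
    "sample_per_pathway",
    "check_convergence",
]

_BOUND_TOL = 1e-9
_STEADY_TOL = 1e-6
_THINNING = 100


@dataclass
class SampleSet:
    reaction_ids: list[str]
    samples: np.ndarray  # n_samples x n_reactions
    seed: int
    growth_floor: float
    thinning: int
    fva: list[tuple[str, float, float]]

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def empirical_ranges(self) -> np.ndarray:
        return np.vstack([self.samples.min(axis=0), self.samples.max(axis=0)]).T

    def fraction_within_fva(self, tol: float = 1e-6) -> float:
        lo = np.array([a for _, a, _ in self.fva])
        hi = np.array([b for _, _, b in self.fva])
        ok = (self.samples >= lo - tol) & (self.samples <= hi + tol)
        return float(ok.all(axis=1).mean())


def _sample_box_polytope(
    S: np.ndarray,
    lbs: np.ndarray,
    ubs: np.ndarray,
    n: int,
    seed: int,
    thinning: int,
) -> np.ndarray:
    """ACHR over {r | S r = 0, lb <= r <= ub} in null-space coordinates."""
    rng = np.random.default_rng(seed)
    m, nr = S.shape
    # coordinates pinned by equal bounds join the equality system so that
    # sampling directions never move them (their step range is empty)
    pinned = np.nonzero(ubs - lbs < 1e-12)[0]
    rows = [S] if m else []
    for j in pinned:
        row = np.zeros((1, nr))
        row[0, j] = 1.0
        rows.append(row)
    A = np.vstack(rows) if rows else np.zeros((0, nr))
    B = null_space(A) if A.size else np.eye(nr)
    if B.shape[1] == 0:
        x = lp_feasible(A_eq=S, b_eq=np.zeros(m), bounds=list(zip(lbs, ubs)))
        if x is None:
            raise InfeasibleProblem("empty flux polytope")
        return np.tile(x, (n, 1))

    # warm-up points: bound-tightened LP vertices along random objectives
    warm = []
    for _ in range(max(2 * B.shape[1], 10)):
        c = B @ rng.standard_normal(B.shape[1])
        res = solve_lp(c, A_eq=S, b_eq=np.zeros(m), bounds=list(zip(lbs, ubs)))
        warm.append(res.x)
    warm = np.array(warm)
    center = warm.mean(axis=0)

    def line_range(x, d):
        """Step interval [lo, hi] keeping x + t*d inside the box."""
        pos = d > 1e-14
        neg = d < -1e-14
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lb = (lbs - x) / d
            t_ub = (ubs - x) / d
        lowers = np.concatenate([t_lb[pos], t_ub[neg]])
        uppers = np.concatenate([t_ub[pos], t_lb[neg]])
        lo = lowers.max() if lowers.size else -np.inf
        hi = uppers.min() if uppers.size else np.inf
        return lo, hi

    x = warm[rng.integers(len(warm))].copy()
    samples = np.empty((n, nr))
    stored = 0
    accepted = list(warm)
    it = 0
    failures = 0
    while stored < n:
        if failures > 10_000:
            raise RuntimeError("sampler stalled: no admissible direction found")
        it += 1
        ref = accepted[rng.integers(len(accepted))]
        d = ref - center
        nd = np.linalg.norm(d)
        if nd < 1e-12:
            d = B @ rng.standard_normal(B.shape[1])
            nd = np.linalg.norm(d)
        d = d / nd
        # re-project onto the null space to kill drift
        d = B @ (B.T @ d)
        nd = np.linalg.norm(d)
        if nd < 1e-12:
            failures += 1
            continue
        d /= nd
        lo, hi = line_range(x, d)
        if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo < 1e-12:
            failures += 1
            continue
        failures = 0
        alpha = rng.uniform(lo, hi)
        x = np.clip(x + alpha * d, lbs, ubs)
        center = center + (x - center) / (len(accepted) + 1)
        accepted.append(x.copy())
        if len(accepted) > 1000:
            accepted.pop(0)
        if it % thinning == 0:
            samples[stored] = x
            stored += 1
    return samples


def sample_fluxes(
    net: MetabolicNetwork,
    n: int,
    growth_floor: float = 0.1,
    seed: int = 0,
    thinning: int = _THINNING,
) -> SampleSet:
    """Draw ``n`` approximately uniform flux samples with biomass flux at
    least ``growth_floor``; validated against FVA ranges."""
    lbs = np.array(net.lower_bounds, dtype=float)
    ubs = np.array(net.upper_bounds, dtype=float)
    if growth_floor > 0:
        jb = net.reaction_index(net.biomass_id)
        lbs[jb] = max(lbs[jb], growth_floor)
    S = net.S_float()
    if lp_feasible(A_eq=S, b_eq=np.zeros(net.m), bounds=list(zip(lbs, ubs))) is None:
        raise InfeasibleProblem("flux polytope empty at this growth floor")
    fva = flux_variability(net, growth_floor=growth_floor)
    # FVA ranges bound every feasible flux; tighten the sampling box
    lo = np.maximum(lbs, np.array([a for _, a, _ in fva]) - _BOUND_TOL)
    hi = np.minimum(ubs, np.array([b for _, _, b in fva]) + _BOUND_TOL)
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise ValueError(
            "flux polytope is unbounded; uniform sampling is undefined"
        )
    samples = _sample_box_polytope(S, lo, hi, n, seed, thinning)
    return SampleSet(
        reaction_ids=list(net.reaction_ids),
        samples=samples,
        seed=seed,
        growth_floor=growth_floor,
        thinning=thinning,
        fva=fva,
    )


def sample_per_pathway(
    net: MetabolicNetwork,
    std: StandardizedNetwork,
    mp: FluxPattern,
    n: int,
    seed: int = 0,
    growth_floor: float = 1e-4,
    activity_floor: float = 1e-6,
    thinning: int = _THINNING,
) -> SampleSet:
    """Sample the flux sub-polytope of one minimal pathway.

    Subnetwork exchanges outside the pathway are fixed to zero and each
    pathway item gets the small activity floor, so every sample's
    subnetwork sign pattern equals the pathway.
    """
    lbs = np.array(net.lower_bounds, dtype=float)
    ubs = np.array(net.upper_bounds, dtype=float)
    for pos, k in enumerate(std.subnetwork):
        j, direction = std.origin[k]
        item = std.items[pos]
        sign = 1.0 if direction == "forward" else -1.0
        if item in mp.items:
            if sign > 0:
                lbs[j] = max(lbs[j], activity_floor)
            else:
                ubs[j] = min(ubs[j], -activity_floor)
        else:
            # forbid flux in this split direction; the opposite split
            # part is handled in its own iteration
            if sign > 0:
                ubs[j] = min(ubs[j], 0.0)
            else:
                lbs[j] = max(lbs[j], 0.0)
    jb = net.reaction_index(net.biomass_id)
    lbs[jb] = max(lbs[jb], growth_floor)
    if np.any(lbs > ubs):
        raise InfeasibleProblem("pathway incompatible with model bounds")
    restricted = MetabolicNetwork(
        metabolite_ids=list(net.metabolite_ids),
        reaction_ids=list(net.reaction_ids),
        S=[row[:] for row in net.S],
        lower_bounds=lbs.tolist(),
        upper_bounds=ubs.tolist(),
        biomass_id=net.biomass_id,
        compartment_of=dict(net.compartment_of),
        intermicrobial=set(net.intermicrobial),
    )
    return sample_fluxes(
        restricted, n, growth_floor=0.0, seed=seed, thinning=thinning
    )


def check_convergence(samples: SampleSet, threshold: float = 1.05) -> dict:
    """Split-chain potential-scale-reduction diagnostic.

    The sample sequence is split into four consecutive segments treated
    as chains; the statistic compares between- and within-chain variance
    per reaction.  Passes iff all values are at most ``threshold``.
    """
    X = samples.samples
    if X.shape[0] < 100:
        raise ValueError("need at least 100 samples for a convergence check")
    n_chains = 4
    seg = X.shape[0] // n_chains
    chains = np.stack([X[i * seg : (i + 1) * seg] for i in range(n_chains)])
    rhat = _split_rhat(chains)
    return {
        "rhat": rhat,
        "max_rhat": float(np.nanmax(rhat)),
        "passed": bool(np.all(rhat <= threshold)),
    }


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction over (chains, draws, dims)."""
    m, n, d = chains.shape
    means = chains.mean(axis=1)  # m x d
    variances = chains.var(axis=1, ddof=1)  # m x d
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    rhat = np.ones(d)
    nz = W > 1e-24
    rhat[nz] = np.sqrt(var_plus[nz] / W[nz])
    return rhat
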