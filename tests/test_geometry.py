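from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy.linalg import null_space

from exopath._lp import lp_feasible
from exopath.geometry import (
    ConeH,
    NonPointedCone,
    RayCeilingExceeded,
    canonicalize_ray,
    double_description,
    in_conic_hull,
    project_cone,
)


def _support_oracle(A, n):
    """Brute force: all support-minimal sign-feasible nullspace directions
    of {x >= 0, A x = 0} — the extreme rays of a pointed nullspace cone."""
    A = np.array(A, dtype=float)
    rank = np.linalg.matrix_rank(A) if A.size else 0
    out = set()
    for size in range(1, min(n, rank + 1) + 1):
        for T in combinations(range(n), size):
            ns = null_space(A[:, T], rcond=1e-9)
            if ns.shape[1] != 1:
                continue
            v = ns[:, 0]
            if np.min(np.abs(v)) < 1e-7:
                continue
            if np.all(v > 0) or np.all(v < 0):
                out.add(frozenset(T))
    return out


def test_single_solution_line_in_orthant():
    rays = double_description(ConeH(n=2, equalities=[[1, -1]]))
    assert rays.rays == [(Fraction(1), Fraction(1))]


def test_orthant_generators():
    rays = double_description(ConeH(n=3))
    assert set(rays.supports) == {frozenset({0}), frozenset({1}), frozenset({2})}


@pytest.mark.parametrize("seed", range(8))
def test_random_cone_matches_support_oracle(seed):
    rng = np.random.default_rng(seed)
    A = rng.integers(-2, 3, size=(4, 7))
    rays = double_description(ConeH(n=7, equalities=A.tolist()))
    assert set(rays.supports) == _support_oracle(A, 7)
    # every ray satisfies the constraints exactly
    for r in rays.rays:
        assert all(v >= 0 for v in r)
        for row in A:
            assert sum(Fraction(int(a)) * v for a, v in zip(row, r)) == 0


def test_row_order_invariance():
    rng = np.random.default_rng(42)
    A = rng.integers(-2, 3, size=(4, 6)).tolist()
    base = double_description(ConeH(n=6, equalities=A)).rays
    for perm_seed in range(3):
        perm = np.random.default_rng(perm_seed).permutation(len(A))
        shuffled = [A[i] for i in perm]
        assert double_description(ConeH(n=6, equalities=shuffled)).rays == base


def test_conic_generation_and_minimality():
    """Sampled cone points decompose over the rays; no ray is redundant."""
    rng = np.random.default_rng(11)
    A = rng.integers(-2, 3, size=(3, 6))
    rays = double_description(ConeH(n=6, equalities=A.tolist())).rays
    assert len(rays) >= 3
    R = np.array([[float(v) for v in r] for r in rays])
    for _ in range(20):
        lam = rng.uniform(0, 1, size=len(rays))
        point = lam @ R
        assert in_conic_hull(point, rays)
    for i, r in enumerate(rays):
        assert not in_conic_hull(r, rays[:i] + rays[i + 1 :])


def test_identity_projection_keeps_cone():
    cone = ConeH(n=4, equalities=[[1, -1, 0, 0]], inequalities=[[0, 1, -1, 0]])
    proj = project_cone(cone, [0, 1, 2, 3])
    assert double_description(proj).rays == double_description(cone).rays


def test_chain_projection_forced_by_substitution():
    # {b1 = r1 = b2 >= 0} projected to (b1, b2) is {b1 = b2 >= 0}
    cone = ConeH(n=3, equalities=[[1, -1, 0], [0, 1, -1]])
    proj = project_cone(cone, [0, 2])
    rays = double_description(proj)
    assert rays.rays == [(Fraction(1), Fraction(1))]


@pytest.mark.parametrize("seed", range(5))
def test_projection_membership_agrees_with_lp(seed):
    """x in projection <=> exists extension feasible in the full cone."""
    rng = np.random.default_rng(seed)
    n, keep = 6, [0, 1, 2]
    A = rng.integers(-2, 3, size=(3, n))
    cone = ConeH(n=n, equalities=A.tolist())
    proj = project_cone(cone, keep)
    Af = np.array(A, dtype=float)
    for _ in range(100):
        x = rng.uniform(0, 2, size=len(keep))
        # full-cone existential feasibility via LP
        bounds = [(float(x[keep.index(i)]),) * 2 if i in keep else (0, None) for i in range(n)]
        ext = lp_feasible(A_eq=Af, b_eq=np.zeros(3), bounds=bounds) is not None
        # membership in the projected H-description (floats, tolerant)
        member = all(
            sum(c * xi for c, xi in zip(row, x)) >= -1e-9 for row in proj.inequalities
        ) and all(
            abs(sum(c * xi for c, xi in zip(row, x))) <= 1e-9 for row in proj.equalities
        ) and all(
            x[k] >= -1e-12 for k in range(len(keep)) if proj.nonneg[k]
        )
        assert ext == member


@pytest.mark.parametrize("seed", range(5))
def test_projection_commutes_with_ray_enumeration(seed):
    """Rays of the projected cone equal the extreme projections of the
    full cone's rays — the geometric core of conversion-mode enumeration."""
    rng = np.random.default_rng(seed + 100)
    n, keep = 6, [0, 1, 4]
    A = rng.integers(-2, 3, size=(3, n))
    cone = ConeH(n=n, equalities=A.tolist())
    route_a = double_description(project_cone(cone, keep)).rays
    full = double_description(cone).rays
    projected = {
        canonicalize_ray([r[i] for i in keep])
        for r in full
        if any(r[i] != 0 for i in keep)
    }
    projected = sorted(projected)
    route_b = [
        v
        for i, v in enumerate(projected)
        if not in_conic_hull(v, projected[:i] + projected[i + 1 :])
    ]
    assert sorted(route_a) == sorted(route_b)


def test_non_pointed_cone_reported():
    with pytest.raises(NonPointedCone):
        double_description(
            ConeH(n=2, equalities=[[1, 1]], nonneg=[False, False])
        )


def test_ray_ceiling_aborts_with_progress():
    cone = ConeH(n=8, equalities=[[1, -1, 1, -1, 1, -1, 1, -1]])
    with pytest.raises(RayCeilingExceeded) as exc:
        double_description(cone, max_rays=4)
    assert exc.value.n_rays > 4


def test_verify_adjacency_accepts_correct_rays():
    A = [[1, -1, 0], [0, 1, -1]]
    rays = double_description(ConeH(n=3, equalities=A), verify_adjacency=True)
    assert len(rays) == 1


# ---------------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402

_matrix = st.lists(
    st.lists(st.integers(min_value=-2, max_value=2), min_size=5, max_size=5),
    min_size=2,
    max_size=3,
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(_matrix)
def test_rays_satisfy_constraints_and_are_irredundant(rows):
    """Every returned ray lies in the cone; none generates another."""
    cone = ConeH(n=5, equalities=rows)
    rays = double_description(cone)
    for r in rays.rays:
        assert cone.contains(r)
    for i, r in enumerate(rays.rays):
        assert not in_conic_hull(r, rays.rays[:i] + rays.rays[i + 1 :])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(_matrix, st.permutations(list(range(5))))
def test_coordinate_relabelling_equivariance(rows, perm):
    """Permuting coordinates permutes the canonical rays accordingly."""
    base = double_description(ConeH(n=5, equalities=rows)).rays
    permuted_rows = [[row[perm[j]] for j in range(5)] for row in rows]
    permuted = double_description(ConeH(n=5, equalities=permuted_rows)).rays
    expected = sorted(
        canonicalize_ray([r[perm[j]] for j in range(5)]) for r in base
    )
    assert permuted == expected
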