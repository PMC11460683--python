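"""Exact polyhedral cone geometry.

Two primitives underlie all pathway enumeration here:

* :func:`double_description` converts a cone given by equalities and
  inequalities (an H-representation) into its extreme rays, in exact
  rational arithmetic.  This is the classical double description method:
  start from the nonnegative orthant, whose extreme rays are the unit
  vectors, and refine the ray set one constraint at a time.  Adjacency of
  rays is decided combinatorially — two extreme rays are adjacent iff no
  third ray's active set contains the intersection of theirs — which is
  exact for pointed cones.

* :func:`project_cone` computes the H-representation of a cone's
  orthogonal projection onto a coordinate subset by Gaussian elimination
  on the equalities followed by Fourier-Motzkin elimination of the
  remaining dropped variables, pruning redundant inequalities after each
  elimination with a Farkas-lemma LP so the description stays minimal.

All coefficients are kept as primitive integer vectors internally and
exposed as :class:`fractions.Fraction`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from ._lp import lp_feasible

__all__ = [
    "ConeH",
    "RayCeilingExceeded",
    "RaySet",
    "NonPointedCone",
    "double_description",
    "project_cone",
    "in_conic_hull",
]


class NonPointedCone(ValueError):
    """The cone contains a full line; it has no extreme-ray description."""


class RayCeilingExceeded(RuntimeError):
    """Enumeration aborted: intermediate ray count exceeded the ceiling.

    Carries partial-progress information instead of silently truncating.
    """

    def __init__(self, n_rays: int, n_processed: int, n_total: int):
        super().__init__(
            f"ray ceiling exceeded: {n_rays} rays after "
            f"{n_processed}/{n_total} constraints"
        )
        self.n_rays = n_rays
        self.n_processed = n_processed
        self.n_total = n_total


def _as_int_row(row: Sequence) -> tuple[int, ...]:
    fr = [v if isinstance(v, Fraction) else Fraction(v) for v in row]
    lcm = 1
    for v in fr:
        lcm = lcm * v.denominator // math.gcd(lcm, v.denominator)
    ints = [int(v * lcm) for v in fr]
    g = 0
    for v in ints:
        g = math.gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    return tuple(ints)


def _primitive(vec) -> tuple[int, ...]:
    g = 0
    for v in vec:
        g = math.gcd(g, abs(v))
    if g > 1:
        return tuple(v // g for v in vec)
    return tuple(vec)


@dataclass
class ConeH:
    """H-representation of a cone: ``A x = 0``, ``B x >= 0``, and
    coordinate nonnegativity per ``nonneg`` (all coordinates by default)."""

    n: int
    equalities: list[tuple[int, ...]] = field(default_factory=list)
    inequalities: list[tuple[int, ...]] = field(default_factory=list)
    nonneg: list[bool] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cone dimension must be >= 1")
        self.equalities = [_as_int_row(r) for r in self.equalities]
        self.inequalities = [_as_int_row(r) for r in self.inequalities]
        if self.nonneg is None:
            self.nonneg = [True] * self.n
        for r in self.equalities + self.inequalities:
            if len(r) != self.n:
                raise ValueError("constraint row has wrong length")

    def contains(self, x: Sequence) -> bool:
        x = [Fraction(v) for v in x]
        if any(self.nonneg[i] and x[i] < 0 for i in range(self.n)):
            return False
        for a in self.equalities:
            if sum(ai * xi for ai, xi in zip(a, x)) != 0:
                return False
        for b in self.inequalities:
            if sum(bi * xi for bi, xi in zip(b, x)) < 0:
                return False
        return True


@dataclass
class RaySet:
    """Canonicalized extreme rays (first nonzero entry scaled to +-1 with
    magnitude 1), sorted lexicographically for reproducibility."""

    n: int
    rays: list[tuple[Fraction, ...]]

    @property
    def supports(self) -> list[frozenset[int]]:
        return [frozenset(i for i, v in enumerate(r) if v != 0) for r in self.rays]

    def __len__(self) -> int:
        return len(self.rays)


def canonicalize_ray(ray: Sequence) -> tuple[Fraction, ...]:
    """Scale so the first nonzero entry has magnitude 1, preserving the
    ray's direction (for nonnegative rays the lead becomes exactly 1)."""
    fr = [Fraction(v) for v in ray]
    lead = next((v for v in fr if v != 0), None)
    if lead is None:
        raise ValueError("zero vector is not a ray")
    return tuple(v / abs(lead) for v in fr)


# ---------------------------------------------------------------------------
# double description
# ---------------------------------------------------------------------------

def _sorted_rows(rows: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    # deterministic insertion order: fewest nonzeros first, ties by value
    return sorted(set(rows), key=lambda r: (sum(1 for v in r if v != 0), r))


class _DD:
    """Incremental double description over integer rays.

    Each ray carries a bitmask of its active inequality constraints
    (coordinate zeros first, processed extra inequalities after), which
    makes the combinatorial adjacency test a set of word operations.
    """

    def __init__(self, n: int):
        self.n = n
        self.rays: list[tuple[int, ...]] = [
            tuple(1 if j == i else 0 for j in range(n)) for i in range(n)
        ]
        self.zbits: list[int] = [
            (((1 << n) - 1) ^ (1 << i)) for i in range(n)
        ]
        self.ineq_rows: list[tuple[int, ...]] = []
        self.dim = n

    def _new_ray_bits(self, ray: tuple[int, ...]) -> int:
        bits = 0
        for j in range(self.n):
            if ray[j] == 0:
                bits |= 1 << j
        for t, row in enumerate(self.ineq_rows):
            if sum(a * b for a, b in zip(row, ray)) == 0:
                bits |= 1 << (self.n + t)
        return bits

    def _packed(self) -> np.ndarray:
        nc = self.n + len(self.ineq_rows)
        words = (nc + 63) // 64
        Z = np.zeros((len(self.rays), words), dtype=np.uint64)
        mask64 = (1 << 64) - 1
        for ri, bits in enumerate(self.zbits):
            for w in range(words):
                Z[ri, w] = (bits >> (64 * w)) & mask64
        return Z

    def _adjacent_pairs(self, pos: list[int], neg: list[int]) -> list[tuple[int, int]]:
        if not pos or not neg:
            return []
        Z = self._packed()
        need = max(self.dim - 2, 0)
        neg_arr = np.array(neg)
        out = []
        for p in pos:
            masks = Z[p] & Z[neg_arr]
            mcounts = np.bitwise_count(masks).sum(axis=1)
            for k in np.nonzero(mcounts >= need)[0]:
                q = neg[k]
                mask = masks[k]
                covered = np.all((Z & mask) == mask, axis=1)
                covered[p] = covered[q] = False
                if not covered.any():
                    out.append((p, q))
        return out

    def add_constraint(self, row: tuple[int, ...], equality: bool) -> None:
        vals = [sum(a * b for a, b in zip(row, ray)) for ray in self.rays]
        pos = [i for i, v in enumerate(vals) if v > 0]
        neg = [i for i, v in enumerate(vals) if v < 0]
        if not pos and not neg:
            if not equality:
                # all rays active: record the row so active sets stay exact
                self.ineq_rows.append(row)
                bit = 1 << (self.n + len(self.ineq_rows) - 1)
                self.zbits = [b | bit for b in self.zbits]
            return
        pairs = self._adjacent_pairs(pos, neg)
        combos = []
        for p, q in pairs:
            vp, vq = vals[p], vals[q]
            rp, rq = self.rays[p], self.rays[q]
            combo = _primitive([vp * b - vq * a for a, b in zip(rp, rq)])
            if any(v != 0 for v in combo):
                combos.append(combo)
        if equality:
            keep_idx = [i for i, v in enumerate(vals) if v == 0]
            self.rays = [self.rays[i] for i in keep_idx]
            self.zbits = [self.zbits[i] for i in keep_idx]
            for c in combos:
                self.rays.append(c)
                self.zbits.append(self._new_ray_bits(c))
            self.dim -= 1
        else:
            keep_idx = [i for i, v in enumerate(vals) if v >= 0]
            self.ineq_rows.append(row)
            bit = 1 << (self.n + len(self.ineq_rows) - 1)
            new_rays, new_bits = [], []
            for i in keep_idx:
                new_rays.append(self.rays[i])
                new_bits.append(self.zbits[i] | (bit if vals[i] == 0 else 0))
            for c in combos:
                new_rays.append(c)
                new_bits.append(self._new_ray_bits(c))
            self.rays, self.zbits = new_rays, new_bits


def double_description(
    cone: ConeH, verify_adjacency: bool = False, max_rays: int | None = None
) -> RaySet:
    """Extreme rays of a pointed H-cone, deterministically ordered.

    Free coordinates (``nonneg[i] == False``) are handled by an internal
    plus/minus split; if the cone contains a full line a
    :class:`NonPointedCone` error is raised rather than silently
    truncating the result.
    """
    free = [i for i in range(cone.n) if not cone.nonneg[i]]
    if free:
        lifted = _lift_free(cone, free)
        lifted_rays = double_description(lifted, verify_adjacency, max_rays).rays
        raw = []
        for r in lifted_rays:
            vec = list(r[: cone.n])
            for k, i in enumerate(free):
                vec[i] = r[i] - r[cone.n + k]
            if any(v != 0 for v in vec):
                raw.append(tuple(vec))
        rays = sorted({canonicalize_ray(vec) for vec in raw})
        ray_set = set(rays)
        for c in rays:
            if tuple(-v for v in c) in ray_set:
                raise NonPointedCone("cone contains a full line")
        return RaySet(n=cone.n, rays=rays)

    dd = _DD(cone.n)
    todo = [(r, True) for r in _sorted_rows(cone.equalities)]
    todo += [(r, False) for r in _sorted_rows(cone.inequalities)]
    for t, (row, is_eq) in enumerate(todo):
        dd.add_constraint(row, equality=is_eq)
        if max_rays is not None and len(dd.rays) > max_rays:
            raise RayCeilingExceeded(len(dd.rays), t + 1, len(todo))
    rays = sorted({canonicalize_ray(r) for r in dd.rays})
    if verify_adjacency:
        _verify_extremality(cone, rays)
    return RaySet(n=cone.n, rays=rays)


def _lift_free(cone: ConeH, free: list[int]) -> ConeH:
    """Rewrite free coordinates x_i = x_i^+ - x_i^- with both parts >= 0."""
    n2 = cone.n + len(free)

    def lift_row(row):
        return tuple(list(row) + [-row[i] for i in free])

    return ConeH(
        n=n2,
        equalities=[lift_row(r) for r in cone.equalities],
        inequalities=[lift_row(r) for r in cone.inequalities],
        nonneg=[True] * n2,
    )


def _verify_extremality(cone: ConeH, rays) -> None:
    """Debug check: each ray's active constraints have rank n-1."""
    units = [tuple(1 if j == i else 0 for j in range(cone.n)) for i in range(cone.n)]
    for r in rays:
        active = list(cone.equalities)
        for row in cone.inequalities + [u for i, u in enumerate(units) if cone.nonneg[i]]:
            if sum(a * b for a, b in zip(row, r)) == 0:
                active.append(row)
        M = np.array(active, dtype=float)
        if M.size == 0 or np.linalg.matrix_rank(M, tol=1e-9) != cone.n - 1:
            raise AssertionError("ray fails the rank-(n-1) extremality test")


# ---------------------------------------------------------------------------
# Fourier-Motzkin projection
# ---------------------------------------------------------------------------

def _scaled_floats(row) -> list[float]:
    """Row as floats scaled by its max magnitude (overflow-safe)."""
    mx = max((abs(v) for v in row if v != 0), default=1)
    if mx.bit_length() > 500:
        return [float(Fraction(v, mx)) for v in row]
    m = float(mx)
    return [float(v) / m for v in row]


def _eliminate_with_equalities(eqs, ineqs, drop: set[int]):
    """Use equality rows to eliminate dropped variables exactly.

    Pivots are chosen by a Markowitz-style criterion (sparsest row, then
    the dropped variable occurring in fewest rows) to limit fill-in.
    """
    eqs = [tuple(r) for r in eqs]
    ineqs = [tuple(r) for r in ineqs]
    drop = set(drop)
    while True:
        pivot = None
        best = None
        for ei, row in enumerate(eqs):
            nnz_row = sum(1 for v in row if v != 0)
            for v in drop:
                if row[v] == 0:
                    continue
                col_count = sum(1 for r in eqs if r[v] != 0) + sum(
                    1 for r in ineqs if r[v] != 0
                )
                score = (nnz_row - 1) * (col_count - 1)
                key = (score, nnz_row, v, ei)
                if best is None or key < best:
                    best = key
                    pivot = (ei, v)
        if pivot is None:
            break
        ei, v = pivot
        eqrow = eqs[ei]
        eqs = eqs[:ei] + eqs[ei + 1 :]
        pv = eqrow[v]

        def subst(row):
            rv = row[v]
            if rv == 0:
                return row
            if pv > 0:
                new = [pv * a - rv * b for a, b in zip(row, eqrow)]
            else:
                new = [-pv * a + rv * b for a, b in zip(row, eqrow)]
            return _primitive(new)

        eqs = [subst(r) for r in eqs]
        ineqs = [subst(r) for r in ineqs]
        drop.discard(v)
    eqs = [r for r in eqs if any(v != 0 for v in r)]
    return eqs, ineqs, drop


def _prune_redundant(ineqs, eqs, n):
    """Drop inequalities implied by the rest.

    Farkas' lemma for homogeneous systems: ``c x >= 0`` is implied by
    ``D x >= 0, E x = 0`` iff ``c = D^T y + E^T z`` for some ``y >= 0``.
    The LP runs in floats; a row is only removed when the solver finds a
    certificate, so near-ties err on the side of keeping rows.
    """
    rows = []
    seen = set()
    for r in sorted(ineqs, key=lambda r: (sum(1 for v in r if v != 0), r)):
        t = tuple(r)
        if t in seen or all(v == 0 for v in t):
            continue
        seen.add(t)
        rows.append(t)
    E = (
        np.array([_scaled_floats(r) for r in eqs], dtype=float).T
        if eqs
        else np.zeros((n, 0))
    )
    i = 0
    while i < len(rows):
        others = rows[:i] + rows[i + 1 :]
        D = (
            np.array([_scaled_floats(r) for r in others], dtype=float).T
            if others
            else np.zeros((n, 0))
        )
        A = np.hstack([D, E])
        if A.shape[1] == 0:
            i += 1
            continue
        c = np.array(_scaled_floats(rows[i]), dtype=float)
        bounds = [(0, None)] * D.shape[1] + [(None, None)] * E.shape[1]
        if lp_feasible(A_eq=A, b_eq=c, bounds=bounds) is not None:
            rows.pop(i)
        else:
            i += 1
    return rows


def project_cone(cone: ConeH, keep: Sequence[int]) -> ConeH:
    """Exact H-description of the projection of ``cone`` onto ``keep``.

    Variables outside ``keep`` are eliminated first through the equality
    rows (Gaussian substitution) and then by Fourier-Motzkin; redundant
    inequalities are removed after each variable elimination so the
    intermediate descriptions stay minimal.
    """
    keep = list(keep)
    if not keep:
        raise ValueError("keep set must be nonempty")
    if any(i < 0 or i >= cone.n for i in keep):
        raise ValueError("keep indices out of range")
    drop = set(range(cone.n)) - set(keep)

    ineqs = list(cone.inequalities)
    for i in range(cone.n):
        if cone.nonneg[i]:
            ineqs.append(tuple(1 if j == i else 0 for j in range(cone.n)))
    eqs, ineqs, drop = _eliminate_with_equalities(cone.equalities, ineqs, drop)
    ineqs = _prune_redundant(ineqs, eqs, cone.n)

    while True:
        candidates = {}
        for v in drop:
            p = sum(1 for r in ineqs if r[v] > 0)
            m = sum(1 for r in ineqs if r[v] < 0)
            if p + m > 0:
                candidates[v] = p * m
        if not candidates:
            break
        v = min(candidates, key=lambda k: (candidates[k], k))
        pos = [r for r in ineqs if r[v] > 0]
        neg = [r for r in ineqs if r[v] < 0]
        zero = [r for r in ineqs if r[v] == 0]
        combos = []
        for rp in pos:
            for rn in neg:
                # rp[v]*rn - rn[v]*rp: both multipliers positive, v cancels
                combo = _primitive([rp[v] * a - rn[v] * b for a, b in zip(rn, rp)])
                if any(c != 0 for c in combo):
                    combos.append(combo)
        ineqs = _prune_redundant(zero + combos, eqs, cone.n)
        drop.discard(v)

    def restrict(row):
        return tuple(row[i] for i in keep)

    out_eqs = []
    for r in eqs:
        if any(r[i] != 0 for i in drop):
            raise AssertionError("equality still references a dropped variable")
        rr = restrict(r)
        if any(v != 0 for v in rr):
            out_eqs.append(rr)
    nonneg_out = [cone.nonneg[i] for i in keep]
    out_ineqs = []
    for r in ineqs:
        rr = restrict(r)
        nz = [(k, v) for k, v in enumerate(rr) if v != 0]
        if not nz:
            continue
        if len(nz) == 1 and nz[0][1] > 0:
            nonneg_out[nz[0][0]] = True
            continue
        out_ineqs.append(rr)
    return ConeH(
        n=len(keep),
        equalities=sorted(set(out_eqs)),
        inequalities=sorted(set(out_ineqs)),
        nonneg=nonneg_out,
    )


# ---------------------------------------------------------------------------
# conic membership (LP oracle used across modules and tests)
# ---------------------------------------------------------------------------

def in_conic_hull(v, rays, tol: float = 1e-7) -> bool:
    """Is ``v`` a nonnegative combination of ``rays``?  (For vectors with
    a common sign structure this is conformal membership.)"""
    v = [float(x) for x in v]
    if not rays:
        return all(abs(x) <= tol for x in v)
    R = np.array([[float(x) for x in r] for r in rays], dtype=float).T
    target = np.array(v, dtype=float)
    scale = max(1.0, np.abs(target).max())
    sol = lp_feasible(A_eq=R / scale, b_eq=target / scale, bounds=[(0, None)] * R.shape[1])
    return sol is not None
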