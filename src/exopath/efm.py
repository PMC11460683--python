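"""Elementary flux mode enumeration.

EFMs are the elementary (conformally non-decomposable) generators of the
flux cone ``{r | N r = 0, r >= 0}`` of an all-irreversible network.  We
enumerate them with the exact double description method on the split
(standardized) network, where the cone is pointed, then map the rays back
to the original reaction coordinates: futile forward/backward two-cycles
created by splitting a reversible reaction are discarded, and a fully
reversible mode — whose mirror image is also a ray of the split cone — is
reported once in canonical orientation (first nonzero original coordinate
positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .geometry import ConeH, canonicalize_ray, double_description
from .network import StandardizedNetwork

__all__ = ["EfmSet", "enumerate_efms", "restrict_to_subnetwork"]

DEFAULT_RAY_CEILING = 2_000_000


@dataclass
class EfmSet:
    """Complete EFM set in original reaction coordinates."""

    std: StandardizedNetwork
    vectors: list[tuple[Fraction, ...]]  # over original reactions

    @property
    def count(self) -> int:
        return len(self.vectors)

    @property
    def supports(self) -> list[frozenset[int]]:
        return [
            frozenset(j for j, v in enumerate(vec) if v != 0) for vec in self.vectors
        ]


def enumerate_efms(
    std: StandardizedNetwork, max_rays: int | None = DEFAULT_RAY_CEILING
) -> EfmSet:
    """Enumerate all EFMs of the standardized network.

    Practical only for small and medium networks — the count grows
    combinatorially.  If the intermediate ray count exceeds ``max_rays``
    a :class:`~exopath.geometry.RayCeilingExceeded` is raised with
    partial-progress information.
    """
    cone = ConeH(n=std.n, equalities=[tuple(row) for row in std.S_std])
    rays = double_description(cone, max_rays=max_rays)

    # split pairs of each original reversible reaction
    split_pairs: dict[int, set[int]] = {}
    for k, (j, _) in enumerate(std.origin):
        split_pairs.setdefault(j, set()).add(k)

    seen: set[tuple[Fraction, ...]] = set()
    vectors: list[tuple[Fraction, ...]] = []
    for ray, support in zip(rays.rays, rays.supports):
        origins = {std.origin[k][0] for k in support}
        if len(origins) == 1 and len(support) == 2:
            j = next(iter(origins))
            if support == split_pairs[j]:
                continue  # futile two-cycle from a split reversible
        orig = std.collapse(ray)
        if all(v == 0 for v in orig):
            continue
        canon = canonicalize_ray(orig)
        reversible = std.base.reversible
        fully_reversible = all(reversible[j] for j, v in enumerate(canon) if v != 0)
        if fully_reversible:
            lead = next(v for v in canon if v != 0)
            if lead < 0:  # canonical orientation: first nonzero positive
                canon = tuple(-v for v in canon)
        if canon in seen:
            continue  # mirror image of a fully reversible mode
        seen.add(canon)
        vectors.append(canon)
    vectors.sort()
    return EfmSet(std=std, vectors=vectors)


def restrict_to_subnetwork(
    efms: EfmSet, std: StandardizedNetwork
) -> list[tuple[Fraction, ...]]:
    """Truncate each EFM to the subnetwork's split coordinates.

    Order is preserved and duplicates are retained — deduplication
    happens at the pattern level.  The split coordinates of a reversible
    reaction receive the positive and negative parts of the original
    flux, so entries are nonnegative.
    """
    out = []
    for vec in efms.vectors:
        sub = []
        for k in std.subnetwork:
            j, direction = std.origin[k]
            v = vec[j]
            sub.append(max(v, Fraction(0)) if direction == "forward" else max(-v, Fraction(0)))
        out.append(tuple(sub))
    return out


def subnetwork_generators(
    efms: EfmSet, std: StandardizedNetwork
) -> list[tuple[Fraction, ...]]:
    """Split-coordinate restrictions of every EFM orientation.

    The restrictions of all EFMs generate the projected cone, but a fully
    reversible mode contributes both of its orientations (its mirror
    image is also a ray of the split cone and restricts differently).
    A biomass coordinate is appended when the biomass reaction is not in
    the subnetwork, matching the ECM ray layout.
    """
    j_bio = std.origin[std.biomass_index][0]
    bio_in_sub = any(std.origin[k][0] == j_bio for k in std.subnetwork)
    rev = std.base.reversible
    out = []
    for vec in efms.vectors:
        orientations = [vec]
        if all(rev[j] for j, v in enumerate(vec) if v != 0):
            orientations.append(tuple(-v for v in vec))
        for v in orientations:
            sub = []
            for k in std.subnetwork:
                j, d = std.origin[k]
                x = v[j]
                sub.append(
                    max(x, Fraction(0)) if d == "forward" else max(-x, Fraction(0))
                )
            if not bio_in_sub:
                sub.append(max(v[j_bio], Fraction(0)))
            out.append(tuple(sub))
    return out


def pattern_vectors(
    efms: EfmSet, std: StandardizedNetwork
) -> tuple[list[tuple[Fraction, ...]], list[Fraction]]:
    """Subnetwork vectors and biomass fluxes for pattern extraction.

    Like :func:`restrict_to_subnetwork` but orientation-complete: a fully
    reversible mode contributes both orientations, since each is a valid
    elementary vector with its own sign pattern.  (Such modes never carry
    biomass flux — the biomass reaction is irreversible — so growth
    flags are unaffected.)
    """
    j_bio = std.origin[std.biomass_index][0]
    rev = std.base.reversible
    vectors, bio = [], []
    for vec in efms.vectors:
        orientations = [vec]
        if all(rev[j] for j, v in enumerate(vec) if v != 0):
            orientations.append(tuple(-v for v in vec))
        for v in orientations:
            sub = []
            for k in std.subnetwork:
                j, d = std.origin[k]
                x = v[j]
                sub.append(
                    max(x, Fraction(0)) if d == "forward" else max(-x, Fraction(0))
                )
            vectors.append(tuple(sub))
            bio.append(v[j_bio])
    return vectors, bio


def biomass_fluxes(efms: EfmSet, std: StandardizedNetwork) -> list[Fraction]:
    """Biomass flux of each EFM (for growth flags when the biomass
    reaction is not part of the subnetwork)."""
    j_bio = std.origin[std.biomass_index][0]
    return [vec[j_bio] for vec in efms.vectors]
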