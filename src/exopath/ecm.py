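"""Elementary conversion mode enumeration.

ECMs are the elementary generators of the flux cone's projection onto a
subnetwork — for the boundary subnetwork, the conversion cone whose
points are net metabolite conversions.  Projecting first and enumerating
extreme rays second is what lets ECMs scale past EFMs: the projection is
computed by exact Fourier-Motzkin elimination of the internal
coordinates, and the (pointed, because subnetwork fluxes are split and
nonnegative) projected cone is handed to the double description method.

Internal reversible reactions are kept as single free net-flux variables
during projection — splitting them first and eliminating both parts gives
the same projected cone with twice the work.  The biomass flux is carried
along as one extra kept coordinate so growth support of each ray is
known; it is not part of the conversion itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .geometry import ConeH, RaySet, double_description, project_cone
from .network import StandardizedNetwork

__all__ = ["EcmSet", "enumerate_ecms", "conversion_cone_summary"]

DEFAULT_RAY_CEILING = 2_000_000


@dataclass
class EcmSet:
    """Extreme rays of the projected cone.

    ``rays`` live over the kept coordinates: the subnetwork split
    coordinates in ``std.subnetwork`` order, followed by one biomass-flux
    coordinate when the biomass reaction is not itself in the subnetwork.
    ``conversions`` give each ray as a net metabolite conversion
    (− import / + export).
    """

    std: StandardizedNetwork
    rays: RaySet
    growth: list[bool]
    conversions: list[dict[str, Fraction]]

    @property
    def count(self) -> int:
        return len(self.rays)

    def subnetwork_vectors(self) -> list[tuple[Fraction, ...]]:
        n_sub = len(self.std.subnetwork)
        return [r[:n_sub] for r in self.rays.rays]


def _projection_system(std: StandardizedNetwork):
    """Cone over [subnetwork split coords..., biomass fwd?, internal nets...].

    Internal irreversible reactions keep their (flipped-if-needed) columns
    with a nonnegativity constraint; internal reversible reactions become
    free net-flux variables.  Returns (cone, keep, bio_keep_pos) where
    ``bio_keep_pos`` indexes the biomass coordinate within ``keep``.
    """
    net = std.base
    j_bio = std.origin[std.biomass_index][0]
    sub_origin = {std.origin[k][0] for k in std.subnetwork}
    n_sub = len(std.subnetwork)

    columns: list[tuple[list[Fraction], bool]] = []
    for k in std.subnetwork:
        columns.append(([std.S_std[i][k] for i in range(std.m)], True))

    if j_bio in sub_origin:
        bio_keep_pos = next(
            p
            for p, k in enumerate(std.subnetwork)
            if std.origin[k] == (j_bio, "forward")
        )
        keep = list(range(n_sub))
    else:
        bio_keep_pos = n_sub
        columns.append(
            ([std.S_std[i][std.biomass_index] for i in range(std.m)], True)
        )
        if net.reversible[j_bio]:
            bwd = next(
                k for k, (j, d) in enumerate(std.origin)
                if j == j_bio and d == "backward"
            )
            columns.append(([std.S_std[i][bwd] for i in range(std.m)], True))
        keep = list(range(n_sub + 1))

    for j in range(net.n):
        if j in sub_origin or j == j_bio:
            continue
        col = net.column(j)
        lb, ub = net.lower_bounds[j], net.upper_bounds[j]
        if lb < 0 < ub:
            columns.append((col, False))  # free net flux
        elif ub <= 0:
            columns.append(([-v for v in col], True))
        else:
            columns.append((col, True))

    nvar = len(columns)
    equalities = [
        tuple(columns[c][0][i] for c in range(nvar)) for i in range(std.m)
    ]
    nonneg = [flag for _, flag in columns]
    return ConeH(n=nvar, equalities=equalities, nonneg=nonneg), keep, bio_keep_pos


def enumerate_ecms(
    std: StandardizedNetwork, max_rays: int | None = DEFAULT_RAY_CEILING
) -> EcmSet:
    """Enumerate ECMs as extreme rays of the projected flux cone.

    Futile two-cycle rays (simultaneous import and export through the
    split parts of one reaction, zero net conversion, no growth) are
    dropped; remaining rays are deduplicated by canonical form and
    deterministically ordered.
    """
    cone, keep, bio_keep_pos = _projection_system(std)
    projected = project_cone(cone, keep)
    rays_all = double_description(projected, max_rays=max_rays)

    n_sub = len(std.subnetwork)
    pair_of: dict[int, int] = {}
    for a in range(n_sub):
        ja, _ = std.origin[std.subnetwork[a]]
        for b in range(a + 1, n_sub):
            jb, _ = std.origin[std.subnetwork[b]]
            if ja == jb:
                pair_of[a] = b
                pair_of[b] = a

    rays, growth = [], []
    for ray, support in zip(rays_all.rays, rays_all.supports):
        if len(support) == 2:
            a, b = sorted(support)
            if pair_of.get(a) == b:
                continue  # futile import/export two-cycle
        rays.append(ray)
        growth.append(ray[bio_keep_pos] > 0)

    conversions = []
    for ray in rays:
        conv: dict[str, Fraction] = {}
        for pos in range(n_sub):
            v = ray[pos]
            if v == 0:
                continue
            entity, direction = std.items[pos]
            signed = v if direction == "export" else -v
            conv[entity] = conv.get(entity, Fraction(0)) + signed
        conversions.append({k: v for k, v in conv.items() if v != 0})

    return EcmSet(
        std=std,
        rays=RaySet(n=projected.n, rays=rays),
        growth=growth,
        conversions=conversions,
    )


def conversion_cone_summary(ecms: EcmSet) -> pd.DataFrame:
    """Per (metabolite, direction) count of rays using the exchange."""
    if ecms.count == 0:
        raise ValueError("empty ECM set")
    counts: dict[tuple[str, str], int] = {}
    for conv in ecms.conversions:
        for met, v in conv.items():
            direction = "export" if v > 0 else "import"
            counts[(met, direction)] = counts.get((met, direction), 0) + 1
    rows = [
        {"metabolite": met, "direction": d, "n_rays": c}
        for (met, d), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["metabolite", "direction", "n_rays"])
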