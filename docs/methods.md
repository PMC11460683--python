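# Methods

## Model representation and standardization

A `MetabolicNetwork` stores stoichiometry as exact rationals
(`fractions.Fraction`) and flux bounds as floats: enumeration needs exact
sign patterns, linear programs do not. Coefficients read from SBML or
JSON are converted through their shortest decimal representation, so
values like 0.0709 are represented exactly.

Boundary reactions are detected structurally — a reaction touching
exactly one metabolite — and follow the convention that for a reaction
written `met →`, positive flux exports (secretes) the metabolite and
negative flux imports it. `standardize` produces the all-irreversible
re-encoding: irreversible reactions that only admit negative flux are
flipped, and every reversible reaction is split into a forward and a
backward part with nonnegative flux. The analysis subnetwork is the set
of split boundary coordinates (optionally plus intermicrobial transfer
reactions in community models), each labelled with an
(entity, import/export) item.

The biomass reaction is identified by id pattern (`biomass`/`growth`,
case-insensitive) with an explicit override available. Growth of a
pathway is recorded as a flag (positive biomass flux in the underlying
vector), not as a pattern item, because the biomass reaction is internal
in genome-scale models and is removed with the other internal reactions
before signs are taken. When duplicate item sets merge, growth flags are
OR-combined.

## Cone geometry

`double_description` maintains the extreme rays of an H-cone
incrementally, starting from the nonnegative orthant (rays = unit
vectors) and adding one constraint at a time. Rays are primitive integer
vectors; adjacency of a positive/negative ray pair uses the
combinatorial test — no third ray's active set contains the
intersection of the pair's active sets — which is exact for pointed
cones, with active sets kept as packed bitmasks and a popcount
pre-filter (|Z₁∩Z₂| ≥ dim−2). An optional algebraic rank check
(`verify_adjacency=True`) re-validates each output ray at O(n³) cost per
ray; it is off by default because the combinatorial test is already
exact. Free coordinates are handled by an internal plus/minus split;
if a full line survives, `NonPointedCone` is raised rather than
returning a truncated ray set. Output rays are canonicalized (first
nonzero entry scaled to magnitude 1) and sorted, making results
independent of constraint order.

`project_cone` eliminates non-kept variables in two stages: Gaussian
substitution through the equality rows (pivot chosen by a
Markowitz-style fill-in criterion), then Fourier–Motzkin elimination,
pairing positive and negative rows of the pivot variable. After each
elimination the description is pruned: a row c is removed iff the
Farkas LP finds y ≥ 0, z with D᷀y + E᷀z = c over the remaining rows.
The LP runs in floats with rows scaled by their largest coefficient
(arbitrary-precision integers can exceed float range); a row is only
removed when the solver produces a certificate, so numerical near-ties
err on the side of keeping rows, which costs time but not correctness.

## EFM and ECM enumeration

EFMs are the extreme rays of the split cone {r ≥ 0, N_split r = 0}.
Futile two-cycles (forward+backward of one split reversible) are
discarded; a fully reversible mode, whose mirror image is also a ray, is
counted once in canonical orientation (first nonzero coordinate
positive). For pattern extraction, however, both orientations of a
fully reversible mode contribute their sign patterns
(`pattern_vectors`); without this, P_ECM ⊆ P_EFM can fail on networks
with reversible exchange cycles. Growth-supporting patterns are
unaffected because the biomass reaction is irreversible.

ECMs are the extreme rays of the flux cone's projection onto the
subnetwork, computed projection-first: this is precisely what makes the
conversion route scale past EFMs. The projection system keeps the split
subnetwork coordinates plus one biomass-flux coordinate (so growth
support of each ray is known) and represents each internal reversible
reaction as a single free net-flux variable — equivalent to splitting
and eliminating both parts, at half the variable count. Extreme rays
that are pure import/export two-cycles of one exchange (zero net
conversion) are dropped; the remaining rays are deduplicated by
canonical form, and each extends to a full feasible flux vector (checked
by LP in the tests). On e_coli_core this route enumerates the full
conversion cone in seconds where exact EFM enumeration takes hours.

EFM/ECM enumeration uses the homogeneous cone — finite bounds do not
enter, per the definition of the flux cone. A configurable ray ceiling
(default 2,000,000) aborts enumeration with partial-progress information
rather than truncating silently.

## EFPs and MPs

EFPs are extracted from the complete unique pattern set of either tier
by union closure: a pattern is elementary iff the union of all patterns
that are proper subsets of it differs from the pattern itself. The
extraction is route-invariant (EFM patterns and ECM patterns give the
same EFPs), which the tests assert on every random network.

MPs are enumerated directly: a minimal subnetwork subset T such that
flux exists with subnetwork support ⊆ T and biomass ≥ the growth floor
(default 1e-4 h⁻¹). A binary master program over subnetwork items
proposes the largest candidate that contains no already-found MP; a
slave LP tests feasibility. Feasible candidates are reduced to their
witness support and shrunk to minimality by greedy single-item removal
with LP re-checks (the removal test is plain subset-feasibility — no
activity floor is imposed on the remaining items, since that would
strengthen the test and can stop above a true minimum). Each MP adds a
"not this superset" cut, each infeasible candidate a "not any subset"
cut; termination at master infeasibility guarantees completeness, which
the exhaustive-subset LP oracle confirms on every random test network.
An infeasible growth floor yields an explicit empty collection.

By default MP enumeration respects the model's bounds (the floor is the
only inhomogeneous constraint added). Cross-definition comparisons use
`use_bounds=False` so that all four tiers are enumerated under identical
homogeneous constraints — the hierarchy is only guaranteed under equal
conditions. On e_coli_core the distinction matters: with the ATP
maintenance bound active there are 33 MPs, under the cone conditions 34.

Activity thresholds: exact-rational vectors use exact nonzero tests;
float LP witnesses use 1e-6. Patterns and reports are ordered
lexicographically by sorted item ids, making all outputs byte-stable.

## Frequencies

Exchange frequency is the fraction of unique patterns (growth-supporting
in headline tables; raw collections remain available) containing an
(entity, direction) item; the full subnetwork universe is listed,
including explicit zeros. Pairwise frequencies count joint occurrence;
interaction frequencies count patterns in which one member exports and
another imports the same shared metabolite. Differences between
definitions are reported as fractions and percentage points (1 decimal).

## Community construction

`merge_community` prefixes member reactions (`<member>__<reaction>`),
rewires member boundary reactions of shared metabolites onto
`<met>__shared` metabolites in a shared compartment (these become
internal transfer reactions, tagged for subnetwork selection), and
creates environmental exchange reactions only for the declared
environmental subset. Each member's biomass reaction additionally
produces a member-biomass pseudo-metabolite; a community biomass
reaction consumes these in (default equal) shares, so no member's
biomass has an outlet except balanced community growth — blocking any
single member makes growth infeasible.

The shipped toy community is a stylized phototrophic mat: a phototroph
fixes CO2 with light and secretes an organic acid and O2; a heterotroph
grows on that acid and O2, respiring CO2 and fermenting part of the acid
to H2; a reducer grows on H2 + CO2. Light, CO2, ammonia, and O2 are
environmental — O2 export-only, so the phototroph stays the sole O2
source — while the acid and H2 must move between members. This
reproduces the qualitative structure of obligate cross-feeding (nonempty
producer→consumer table, member essentiality), not any measured
stoichiometry.

## Flux sampling

`sample_fluxes` runs artificial-centering hit-and-run in null-space
coordinates: points are parameterized as r = r₀ + B y with B an
orthonormal null-space basis of the stoichiometric matrix (coordinates
pinned by equal bounds join the equality system), so steady state holds
to machine precision and only box bounds limit the line search.
Directions pass through previously accepted points relative to the
running center; chains are thinned (default every 100 steps). The
sampling box is pre-tightened to FVA ranges, which also provides the
validity check (all samples within FVA ranges); an unbounded polytope is
rejected since uniform sampling is undefined on it. Convergence is
assessed with a split-chain potential-scale-reduction statistic over
four consecutive segments, passing at ≤ 1.05.

Per-pathway sampling fixes all subnetwork exchanges outside a given MP
to zero and imposes a small activity floor (1e-6) on the MP's own items,
so every sample's exchange sign pattern equals the pathway. This is the
mechanism that makes tiny-volume flux regions — present in pathways but
essentially invisible to global uniform sampling — accessible.

## Synthetic data and oracles

The random-network generator draws small integer stoichiometries
(defaults: 3–6 metabolites, ~5 internal reactions, 2–3 boundary
reactions, reversibility probability ~0.3), adds a biomass reaction
consuming one or more precursors with an export for the biomass
metabolite, and rejection-samples until growth ≥ 1e-3 is LP-feasible.
Networks are deterministic per seed. These sizes keep every enumerator
and every exhaustive oracle below a second or two per network, so
hundreds of networks fit in a test run. The generator emulates the
structural properties the analysis assumes (mass-balanced cores,
single-metabolite exchanges, feasible growth) but not biological realism
— no element conservation, thermodynamics, or realistic pathway lengths
— so passing tests certify algorithmic correctness, not biological
fidelity, on real models.

Three oracles are implementation-independent of the enumerators:
minimal supports by exhaustive nullity-1 tests per candidate support
(numpy SVD; elementary-mode supports have at most rank+1 members);
minimal feasible subsets by an exhaustive LP sweep in increasing size
with superset pruning; elementary patterns by subcollection-union
search. Size guards (n ≤ 18 reactions, |S| ≤ 14, ≤ 2¹⁴ patterns) keep
them honest about their exponential cost.

## Known limitations

* Exact EFM enumeration is desk-scale: the e_coli_core EFM tier
  (100,274 modes) runs but takes hours; genome-scale EFM enumeration is
  out of reach, as is expected for the definition itself.
* Fourier–Motzkin with LP pruning keeps descriptions minimal but
  intermediate blow-up is possible on adversarial networks; the ray
  ceiling and the pruning LPs are the safety valves.
* Farkas pruning and conic-membership checks run in float LPs with
  conservative tolerances; the enumeration itself is exact.
* The sampler targets bounded polytopes only and its uniformity is
  asymptotic; calibration tests bound centroid error on known geometry
  rather than proving uniformity.
* Genome-scale external models (the H. pylori GEM, the mat-community
  member models) are inputs, not package contents; the corresponding
  benchmarks require the files to be supplied.
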