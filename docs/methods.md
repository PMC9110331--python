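# Methods

## The structural hierarchy

The package analyses one configuration of rigid water molecules at a time
(oxygen + two hydrogens per molecule, orthorhombic periodic box, lengths
in Å, times in fs).  Coordinates are stored as given; the minimum-image
convention is applied inside every geometric operation, so inputs may be
wrapped or unwrapped.

**Hydrogen bonds.**  Molecules *i*, *j* are bonded iff some hydrogen of
one lies strictly closer than `hb_cutoff` (default 2.5 Å) to the oxygen
of the other under minimum image.  There is no angular term and no
energetic criterion.  Boundary equality is excluded (strict `<`).
Bifurcated bonds are allowed: one hydrogen within the cutoff of two
acceptors contributes two edges.  Multiple H···O contacts between one
pair collapse to a single undirected edge; each donating contact is kept
as an edge annotation so donation counts (≤ 2 per molecule) can be
audited.  Neighbor queries go through a periodic k-d tree; the O(N²)
27-image scan exists only as a test oracle.

**SP rings.**  A ring is a cycle of at most `max_ring_size` (default 8)
molecules such that for *every* pair of members the shorter arc along the
cycle equals their shortest-path distance in the full graph.  The
criterion is applied to all vertex pairs (not only antipodal ones); this
choice is fixed and mirrored exactly by the brute-force oracle the tests
compare against.  Enumeration does a DFS rooted at each cycle's smallest
node with distance-based pruning, then filters candidates with truncated
BFS distances; correctness is defined by the oracle, not the search
order.  Rings of size 3 are admitted (only the upper bound is
specified).

**Cage fragments.**  A fragment is a minimal set of rings, with
cardinality in `fragment_ring_counts` (default {3,4,5}), in which every
covered H-bond edge lies in exactly two member rings — a closed
2-complex.  Minimality means no proper subset of ≥ 3 rings is itself
closed.  Exact double coverage (rather than allowing boundary edges
covered once) is a deliberate fixing of an under-determined definition;
it reproduces the theta-cage behaviour that anchors the method: paths of
(2,2,3) H-bonds give one (4,5,5) fragment of 6 molecules, (3,3,4) gives
(6,7,7) with 9, (2,2,6) gives (4,8,8) with 9, and in general a theta
cage with path edge counts (p₁,p₂,p₃) has 2 + Σ(pᵢ−1) molecules.
Fragments may share rings and molecules; no exclusivity is imposed.

A consequence of the all-pairs SP criterion worth knowing: a theta
cage's largest cycle survives only when the two shortest paths tie
(p₁ = p₂ after sorting).  Otherwise the largest cycle has a shortcut and
only two of the three rings are SP rings, so no fragment forms.  Every
3-ring signature the method's literature reports — (4,5,5), (4,6,6),
(4,7,7), (4,8,8), (6,7,7), (6,8,8) — indeed has its two larger rings
equal.  `CageSpec.is_sp_realizable()` exposes the predicate.

**Water clusters.**  Fragments sharing ≥ 1 ring are joined in the
fragment network with edge weight = number of shared rings.  Clusters are
Louvain communities of that network (weighted modularity, resolution 1.0,
both configurable), materialized as the union of member-fragment
molecules; cluster size *S* counts those molecules.  Louvain randomness
is fixed by seeding the node traversal order, making runs reproducible.
Molecules in rings shared across community boundaries belong to both
clusters; global coverage is |union of cluster molecules| / N.  Rings in
no fragment ("isolated rings") and molecules in neither a cluster nor an
isolated ring ("debris") are tracked for the dynamics stage.

## Morphology and scaling

Cluster geometry is computed in real space: the cluster is unwrapped by
BFS over its H-bond subgraph, each molecule placed at its minimum-image
position relative to its BFS parent.  The alpha shape is the classical
alpha complex — Delaunay tetrahedra with circumradius ≤ `alpha_radius`
(default 3.5 Å; oxygens only) — with volume the summed tetrahedron
volume and area the summed area of facets belonging to exactly one
retained tetrahedron.  A small relative tolerance (1e-9) on the
circumradius comparison makes exactly co-spherical inputs (e.g. surface
samples of a sphere at alpha = R) behave like the limiting case.
Clusters with < 4 points or degenerate geometry report V = A = NaN and
are excluded from fits.  L is the maximum pairwise O–O distance
(convex-hull-accelerated above 400 points), r = L/2.

Fits: `radius_scaling_fit` returns the log–log slopes d_V (V vs r) and
d_S (A vs r); `surface_volume_fit` fits ln A = a ln V + b separately
below/above a 100 Å³ split; `shape_factor_reference` gives the analytic
intercepts at slope 2/3 — ln(4π) − (2/3)ln(4π/3) ≈ 1.576 (sphere),
ln 6 ≈ 1.792 (cube), ln√3 + (2/3)ln(6√2) ≈ 1.975 (tetrahedron).  The
size-distribution exponent τ of n_S ~ S^(−τ) is fitted by least squares
on logarithmically binned counts (density per bin vs geometric bin
center); a continuous-Pareto MLE is available as an alternative.  At 10⁵
samples both recover generating exponents in {2.0, 2.44, 3.0} with bias
< 0.05.  Isosbestic points between two distributions on a common grid
are located as sign changes of their smoothed difference (moving
average, default 5 bins); identical or proportional distributions yield
none.

## Energetics and descriptors

Pair energies use the SPC/E model: q_O = −0.8476 e, q_H = +0.4238 e,
O–O Lennard-Jones σ = 3.166 Å, ε = 0.650 kJ/mol; all nine charge pairs
plus the O–O LJ term under minimum image, truncated to zero when the
O–O distance reaches `energy_cutoff` (default 10 Å, matching the
nonbonded cutoff of the simulations this analysis targets).  No Ewald or
tail correction: the cluster energy E_S is a plain sum over intra-cluster
pairs, in kJ/mol, with an eV conversion for reporting.  The linear fit
E_S = aS + b requires ≥ 3 distinct sizes.

The LSI of a molecule orders its oxygen neighbours r₁ < r₂ < … and sets
n = #{rᵢ < 3.7 Å}; with gaps Δ(i) = r_{i+1} − rᵢ for i = 1..n (the last
gap reaches across the shell boundary) and Δ̄ their mean, LSI =
(1/n) Σ (Δ(i) − Δ̄)² in Å².  Ties produce zero gaps and are included; a
molecule with no neighbour inside, or none beyond, the cutoff is
undefined and excluded from averages.  Perfect ice (four neighbours at
2.75 Å, next shell at 4.49 Å) gives ≈ 0.57 Å², the tetrahedral upper
bound; disordered shells give values near zero.

Local density profiles place a 4.6 Å probe sphere at the cluster's own
oxygen atoms (default) or on deterministic radial shells, count the
*other* oxygens of the frame inside the probe under minimum image, and
bin ρ_local = count / probe volume by distance from the cluster's
geometric center (unweighted oxygen mean; a mass-weighted center over
all nine sites per three molecules is the alternative, used by default
for cluster–cluster RDFs).  RDFs are pair-distance histograms normalized
by ideal-gas shell counts at the partner selection's density, computed
with periodic tree counting; r_max is capped at half the shortest box
length.

## Dynamics

Between consecutive frames every molecule belongs to a cluster (C), an
isolated ring (R) or the debris (m).  Entities sharing molecules across
the frame boundary are linked; each connected component of that
bipartite graph is one event, classified as: changeless (one cluster to
one identical-membership cluster — strict equality, no grace for a
single joining molecule, which the lifetime definition "without
assumptions" supports); merge (exactly one product cluster, reactants
containing ≥ 1 cluster or ≥ 1 ring); split (the mirror); complex
(everything else — including debris-only condensation, which the merge
pattern's i_c ≥ 1 ∨ i_R ≥ 1 side condition excludes).  Components
conserve their molecule sets by construction; reversing the frame order
swaps merge and split counts exactly.  A cluster's lifetime is the
length of a maximal run of frames with identical membership, reported in
units of the frame interval Δt (default 10 fs); event rates are
fractions over all events touching at least one cluster.

## Synthetic structures

The generators produce *topology-guaranteed* fixtures, not thermodynamic
water:

* **Theta cages** — poles on the z axis, paths on meridional arcs,
  refined by penalty minimization (edges to the 2.8 Å target, non-edges
  pushed beyond 4.0 Å), then verified against hard margins: edge O–O
  < 3.4 Å (so O···H < 2.4 Å after placing the donor hydrogen 1 Å along
  the bond) and non-edge O–O > 3.6 Å (so no spurious O···H < 2.5 Å).
  Violations raise; the builder never consults the detection code, so
  detection-vs-intention tests are a genuine round trip.  Donors are
  oriented path-wise (one path from pole A, two from pole B), keeping
  donations ≤ 2; free hydrogens take the clearance-maximizing direction
  from a deterministic 192-direction set.
* **Ice lattices** — ice-Ih (lonsdaleite, 8 molecules per orthorhombic
  cell, O–O 2.75 Å) and ice-Ic (diamond); the 4-regular bond graph is
  oriented along an Eulerian circuit, which yields exactly two donations
  per molecule (the ice rules) without search.  Cubic ice requires ≥ 3
  cells per direction so that no ≤ 8-cycle can wind around the box.
* **Random packings** — seeded dart throwing at a target density with a
  minimum-separation rejection, random rigid-water orientations; a
  bulk-like negative control with essentially no rings.
* **Statistical generators** — discrete power-law size samples by
  inverse CDF on a truncated support (tail mass < 1e-5 for τ ≥ 2), and
  uniform area-weighted surface samples of spheres, cubes and regular
  tetrahedra for shape-factor validation.

All generators are bit-reproducible under a fixed seed.

## What the tests do and do not show

Synthetic fixtures exercise every pipeline stage against independent
oracles (27-image brute force, exhaustive cycle enumeration, exhaustive
modularity maximization, closed-form solids, hand-evaluated worked
values) at desk scale — hundreds of molecules, single cages, 10⁵-sample
estimator checks.  They do not reproduce the statistics of bulk
simulated water (τ ≈ 2.44, d_V ≈ 2.89, > 95% coverage, isosbestic
points, transformation rates), which require ~10⁵-molecule trajectories;
those quantities are covered by estimator-recovery tests on generators
with known parameters instead.

## Known limitations

* The SP-ring census of hexagonal ice contains 8-rings as well as
  6-rings under the all-pairs criterion (verified against the exhaustive
  oracle); an all-hexagon census requires the cubic-ice fixture.
* Louvain is a greedy heuristic: on small dense graphs its first-level
  aggregation can lock in a partition strictly below the exhaustive
  modularity optimum, and reseeding the node order does not always
  escape (a reproducible 8-node, 12-edge counterexample exists).  The
  partitions it returns are still node-move locally optimal and never
  worse than singletons.
* Energies use plain cutoff truncation; absolute cluster energies are
  not comparable to Ewald-based values, though size trends are.
* Triclinic boxes, flexible/polarizable water models, and fragment
  cages of more than 5 rings are out of scope.
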