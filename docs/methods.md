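# Methods

## The model

Surface-adsorbed trimeric DNA tiles (3-point stars, 3PS) are represented
as two-dimensional patchy discs: a hard core of diameter σ = 1 (the length
unit) carrying three attractive patches at body-frame angles 0°, 120° and
240°. Two discs bind with square-well energy −ε when their centre distance
lies in [σ, σ+δ] and a pair of mutually facing patches is each aligned with
the centre–centre axis to within the patch half-width θ_pw. The defaults
σ = 1, δ = 0.038 (≈ 0.6 nm of blunt-end stacking reach), θ_pw = 0.3 rad and
ε = 6 kT describe the π–π stacking interface of a 3PS tile. With θ_pw < π/3
and 120° patch spacing, a particle pair can never form two simultaneous
patch contacts, and no particle can hold more than three bonds.

Each patch is a two-state unit: *closed* (active, bondable — the two
double helices of the arm are parallel) or *open* (inactive). A free patch
is open with equilibrium probability P_open; the state energies are
w(open) = −ln P_open and w(closed) = −ln(1−P_open), so an isolated patch's
Boltzmann open-fraction is exactly P_open. P_open encodes interface
flexibility; the reference experiments correspond to a fairly rigid
interface, P_open ≤ 0.2.

The monomer–surface interaction enters as a **kinetic barrier**, not a
field: a Metropolis move pays an extra penalty E_s (in kT) if it would
(a) break at least one existing bond, or (b) flip the state of any patch
of a particle that currently holds a bond. The penalty is asymmetric — it
is never credited to the reverse move — so it changes kinetics, and it is
what shifts the gas ↔ crystal balance: with E_s = 0 bonds break as fast
as they form and the system stays a two-dimensional gas; moderate E_s
stabilizes early nuclei; large E_s freezes both defects (bond breaking)
and patch states of bound tiles (valence trapping), degrading crystalline
order and radial growth. Reading (b) as covering *all* patches of a bound
particle, rather than only the patch engaged in the bond, is deliberate:
valence trapping of bound tiles is the mechanism by which strong surface
coupling suppresses radial growth, and it requires slowed state switching
of the *free* patches of bound tiles.

Simulation protocol: N particles (1500 in a 150×150 box at full scale;
the reduced-scale studies use 400 in a 77.5×77.5 box, the same bulk density)
are placed by rejection sampling with random orientations and all patches
open, then evolved by single-particle translations (uniform, max 0.35 σ),
rotations (max 0.4 rad) and patch flips, mixed 45/45/10. Step sizes give
30–70% acceptance in the dilute phase. One sweep = N attempted moves.
A run is flagged converged when the sliding-window mean bond count over
the last 20% of sweeps changes by less than 1%. Identical seeds give
bit-identical trajectories (the kernel uses an xorshift128+ generator
seeded from the run seed).

## Order statistics

Frames and images are reduced to the same representation: an embedded
planar graph of trivalent junctions. Faces are enumerated by the angular
next-edge walk (each directed edge consumed exactly once; the most
negative signed area cycle per component is the outer boundary). Internal
faces larger than 12 sides are treated as pores and logged, not counted.
Per component, Euler's identity V − E + F_internal = 1 is a standing
invariant. Simulation clusters that wrap the periodic box cannot be
unwrapped consistently and are excluded from face analysis.

* **Hexagon content** — hexagons / all internal faces with 4–12 sides.
  Keeping the 4- and 9–12-sided classes in the denominator avoids silently
  inflating content when pores and large defects are present; the range is
  configurable.
* **Network density (ND)** — per connected component, observed polygon
  count divided by the polygon count of the *ideal* honeycomb cluster
  with the same number of monomers. The ideal reference is the
  face-maximal polyhex, grown greedily cell by cell (each new cell shares
  the maximum number of vertices with the cluster, ties broken toward the
  centre); this reproduces the extremal counts n_min(h) = 2h + 1 +
  ⌈√(12h−3)⌉ and the centred-flake closed form (V = 6k² monomers hold
  3k²−3k+1 hexagons). Components need ≥ 6 monomers and ≥ 1 face to be
  scored. Reported ND for the simulation studies is the plain mean over
  scored components pooled across post-convergence frames and replicate
  seeds; a monomer-weighted mean (large networks dominating, as in
  per-window weighted means of the experimental analysis) is also
  available (`NetworkMetrics.nd_weighted_mean`).
* **Defect motifs** — non-hexagon faces are clustered by shared-edge
  adjacency. A cluster forming a single closed cycle with equal pentagon
  and heptagon counts is a *ring defect* (disclination charge Σ(6−n) = 0).
  A path-like cluster with pentagons:heptagons ≈ 1:1 and no octagons is a
  misorientation grain boundary (5+7 unit); a cluster containing octagons
  with pentagons:octagons ≈ 2:1 and no heptagons is a translational grain
  boundary (5+5+8 unit). Composition tolerances are ±25% (configurable).
  Everything else is reported as isolated, with pentagon-neighbour counts
  attached to every heptagon and octagon.

## Image pipeline

The AFM chain mirrors standard post-processing for lattice-on-mica data,
with every step recorded in the image's preprocessing record:

1. heights capped to the [0.5, 99.99] percentile values (linear
   interpolation convention);
2. Otsu foreground threshold (256-bin histogram);
3. per-scan-line polynomial background removal excluding foreground,
   applied twice with the mask recomputed in between (degree 2 by
   default; fits fall back to the previous line when a line has fewer
   than degree+1 background pixels); background median set to 0;
4. clamping to [0, h_max], h_max the global 99.5th percentile of
   foreground heights, tightened to the line's own foreground percentile
   on lines that are > 90% background (our concrete instantiation of a
   dynamic threshold; the constants live in the preprocessing record);
5. segmentation (Otsu + morphological closing, small objects removed),
   skeletonization to 1-pixel centre lines;
6. particle detection: monomer centres carry more material than arm
   midpoints and image as bright blobs, so nodes are 2D local maxima of
   the lightly smoothed height map above the Otsu threshold, at least a
   third of a lattice edge apart; maxima further than 3 px from the
   skeleton are discarded;
7. bond detection: skeleton pixels are partitioned by multi-source
   breadth-first growth from the nodes; two nodes whose regions meet on
   the skeleton are bonded. Spurs and floating fragments never connect
   two nodes and vanish.

Junction-only detection (branch points of the skeleton) misses the
divalent boundary monomers of finite flakes; the brightness criterion
recovers them. This presumes monomer centres are brighter than arms,
which holds for the forward model below and for real 3PS tiles (three
arms overlap at the centre).

Hexagon areas are shoelace polygon areas in nm². Self-sorting thresholds
follow the reference-distribution convention: the 95th percentile of the
short-species hexagon-area distribution and the 5th percentile of the
long-species distribution (linear-interpolation percentiles); hexagons
below/above/between are labelled short/long/intermediate, with an
overlapping-threshold flag when the references cross. Area distributions
are Gaussian KDEs (Silverman bandwidth), with a histogram fallback below
ten areas.

## Synthetic data

The generator provides ground truth for every pipeline stage. Perfect
flakes and patches are built cell-by-cell on the hexagonal grid (integer
vertex keys, no floating-point identity issues). Local defects are graph
surgeries on a host flake, followed by spring relaxation (bond springs at
the lattice edge length plus weak second-neighbour springs, which remove
the shear floppiness of a bare honeycomb): vacancies (remove a trivalent
node → 12-gon pore), Stone–Wales rotation (rotate one bond 90° → two
pentagons + two heptagons; each heptagon touches exactly two pentagons),
and a single 5|7 dislocation (remove one bond, re-chord the merged
decagon through a boundary vertex at cycle distance 4; the construction
searches candidates deterministically and accepts the first whose
re-enumerated census gains exactly one pentagon and one heptagon).

Extended defects are built in *seed space*: hexagon centres form a
triangular lattice, and the network is recovered as the Voronoi diagram
of the seeds (merging seeds closer than 0.7 spacings, 2% deterministic
jitter to break degeneracies, spring relaxation of the vertices). A disc
of seeds rotated by 30° yields a closed alternating 5/7 ring — 6 pairs
for a 1.6-spacing core, 12 pairs for a 3.1-spacing core; ring sizes
outside {6, 12} are not constructible this way and are rejected. Two
half-plane seed grains misoriented by φ yield an emergent 5/7 dislocation
boundary. An 8-fold disclination core (one seed ringed by eight) yields
an octagon flanked by four alternating pentagons; the +2 charge cannot
embed in a flat far field alone, so compensating 5|7 pairs appear further
out — as they do around real over-coordinated cores. The translational
grain boundary is built by its physical mechanism: seam dimers that
cannot bond across a mismatched gap reconstruct as a line of divacancy
units (remove every other seam dimer, rebond the dangling pairs), giving
the 5+5+8 repeating unit with pentagon:octagon exactly 2:1. Greedy
distance-based stitching of the two half-lattices was tried first and
rejected: a pure translational mismatch relaxes into uniform shear (a
topologically perfect but strained lattice), so the boundary defects the
mechanism produces in rigid tiles never emerge from distance greediness.

Mixed-species lattices draw a species per monomer (a tile's three
half-arms share its species); each bond's rest length is the sum of its
endpoints' arm lengths, and the relaxed hexagon areas interpolate between
the pure-species areas with a single broad mode, the signature of
non-sorting.

The forward imaging model renders edges as Gaussian ridges (height 2 nm,
FWHM 4 nm — dsDNA on mica), brightens every monomer centre with a wider
blob (FWHM 7 nm, ×1.4), applies Gaussian tip blur (2 nm), then adds
per-scan-line linear+quadratic drift (±0.3 nm) and Gaussian pixel noise
(σ = 0.15 nm) at 3 nm/pixel. Rasterization runs on a 3× supersampled
grid and block-averages down, since the ridge width is comparable to the
pixel size. What the generator does *not* emulate: tip–sample
convolution asymmetry, inter-frame thermal drift, adsorbed debris, and
partially resolved (sub-monolayer) material. Exact census recovery on
these renders therefore demonstrates the pipeline's correctness on
clean, well-resolved data, not its robustness to every real-world
artifact; recovery degrades gracefully (and is logged, not asserted)
at higher noise.

## Study sizes and numerical choices

The reduced-scale simulation study uses N = 400 at the reference density
(77.5×77.5 box), 4·10⁵ sweeps for the order-parameter conditions (the
bond count is near its plateau; the convergence flag is reported) with
the last 10 of 20 recorded frames analyzed, and 10⁵ sweeps for the
nucleation scan, where what matters is only whether a nucleus holding
≥ 10% of the particles persists through the final third of the run.
Three replicate seeds per condition. At this scale the networks hold
tens of polygons, so per-condition means carry visible sampling noise;
the package reports pooled means across components, frames and seeds.

Tie-breaking and degenerate inputs: face walks start from the smallest
directed edge (deterministic); coincident node coordinates raise an
error naming the nodes; constant images are returned unchanged by the
percentile cap and flagged by Otsu; p_open ∈ {0, 1} freezes patch states
and disables flip moves rather than producing infinite state energies;
placement at area fraction > 0.55 is refused.

## Known limitations

* Single-particle moves only: clusters do not diffuse or rotate as
  units, so late-stage coarsening is slower than any dynamics with
  collective moves; at reduced scale the largest cluster reaches ~10–15%
  of the particles rather than the system-spanning networks seen at
  full experimental scale, and absolute hexagon content and ND sit
  below the large-network values.
* ND of small components is harsh: a 40-monomer cluster with a single
  missing boundary polygon loses several percent of ND, so reduced-scale
  ND means are biased low relative to micrometre-scale networks.
* The dynamic-threshold step is a documented stand-in for an
  instrument-specific procedure whose exact form is not public.
* The image pipeline assumes an approximately planar, single-layer
  lattice; overlapping layers and three-dimensional aggregates are out
  of scope.
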