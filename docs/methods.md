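# Methods

This note documents the algorithms, the parameter defaults and the numerical
choices behind `netskel`, and what the synthetic phantoms do and do not
establish about real data.

## Conventions

Arrays are indexed `(z, y, x)`, slice-major, matching multi-page TIFF
layout. Physical coordinates are continuous: voxel `(i, j, k)` covers the
half-open box `[i·dz, (i+1)·dz) × [j·dy, (j+1)·dy) × [k·dx, (k+1)·dx)` with
its center at the half-offsets. Coordinate tables list columns `x y z`.
Voxel dimensions always come from the run configuration; TIFF metadata is
ignored because axial calibration in microscope files is unreliable.
Material (foreground) connectivity is 26, background connectivity 6 — the
standard complementary pair; mixing them differently breaks the Jordan
separation property on the digital lattice.

## Preprocessing

* **Gaussian blur** (default width 1 voxel per axis, reflective borders).
  Noise in the raw image otherwise surfaces downstream as spurious short
  side chains of the skeleton; blurring first is cheaper than pruning more
  aggressively later.
* **Binarization** is per-slice, either Otsu (256-bin between-class
  variance; the default) or the percentile rule
  `I_T = I_10 + V_u (I_90 − I_10)`. Percentiles use linear-interpolation
  quantiles; the material test is a strict `>`, so a constant slice
  binarizes to background (it is also flagged degenerate, and a degenerate
  Otsu slice is forced to background outright since Otsu is undefined
  without two classes). Thresholds are computed on the *blurred* stack:
  blurring is a noise model, and the threshold should see the same data the
  skeletonization will.
* **Morphological closing** with a digital ellipsoid whose semi-axes are
  given in physical units and converted per axis, so anisotropic voxels
  yield an anisotropic element. Membership is the continuous test
  Σ(dᵢ/aᵢ)² ≤ 1 *without* rounding the semi-axes up: a semi-axis below one
  voxel contributes no off-center offsets, which is what makes the contact
  rule exact — two flat binarized faces connect iff their gap is at most
  twice the element radius. The volume is zero-padded by the element extent
  before closing, which makes the operation extensive (output ⊇ input) and
  idempotent also at the image border. Default semi-axes 0.25 σ, so gaps
  below 0.5 σ close; two touching particles always remain connected, while
  genuinely separate strands (≥ 1 σ apart under the phantom conventions) do
  not fuse.
* **Small-cluster removal** deletes 26-connected components smaller than
  `min_fraction` (default 0.01) of the total material voxel count; the
  denominator is total material, so the rule is scale-free in structure
  size. Surviving clusters keep distinct labels and are reported as
  separate network structures. Removing everything is an error, not an
  empty result.
* **Hole filling** fills 6-connected background components that touch no
  volume face and contain at most `max_hole_voxels` voxels (default: the
  voxel volume of one particle, π σ³/6). Face-touching background is pore
  space and is never filled.

## Thinning

Deletion conditions per candidate voxel `i` with neighborhood `D_3(i)`:

1. **border** in the current sweep direction (that face neighbor is
   background; out-of-bounds counts as background);
2. **not an end point**: `D_3(i)` holds more than two material voxels —
   end points are protected so strand tips survive;
3. **Euler invariant**: deleting `i` leaves χ unchanged. χ is computed from
   the simplicial analog of the (26, 6) digital image: every non-empty set
   of foreground voxels fitting in a 2×2×2 block spans a simplex, and χ is
   the alternating simplex count. The per-block contribution table (256
   entries) is *derived at import time* by direct subset enumeration —
   nothing is transcribed from the literature, and tests verify the table
   against both an explicit slow enumeration and an independent library
   implementation. Deleting `i` only changes the 8 blocks containing it
   (the octants of `D_3(i)`), so the χ-delta is a sum of 8 two-lookup
   terms.
4. **simple point**: the 26 neighbors form exactly one 26-connected
   component after deletion, and exactly one 6-connected background
   component within the 18-neighborhood touches a face neighbor of `i`
   (the standard two topological numbers characterization).

Each full pass sweeps the six border directions in the fixed order −z, +z,
−y, +y, −x, +x. Candidates of a sub-iteration are collected simultaneously,
then re-checked sequentially in `(z, y, x)` scan order before deletion,
because a deletion can invalidate a later candidate. Passes repeat until a
full pass deletes nothing; the procedure is therefore idempotent and fully
deterministic. Thinning works on the lattice and ignores physical
anisotropy — the Euler/simple machinery is lattice-combinatorial — and
physical units re-enter only when lengths are measured.

Two geometric facts worth knowing. First, thinning a flat-capped solid tube
retreats the skeleton from the caps by up to the tube radius; how much
depends on the tube's orientation relative to the sweep order (directions
swept before the cross-section collapses lose one slice per pass). The tube
phantom therefore defaults to the x axis, where the measured 60-voxel
cylinder keeps 58 of 60 voxels. Second, end-point protection leaves
one-voxel stubs at staircase corners of curved strands; these are exactly
the artifacts the cleaning stage removes.

## Graph extraction and cleaning

Voxel classification counts material voxels of `D_3` *including* the
center: 2 → end, 3 → link (a path interior), >3 → branching. Adjacent
branching voxels are clumped into a single node — dense junction regions of
a thin skeleton routinely contain several mutually adjacent branching
voxels that represent one physical junction. Isolated voxels (count 1) are
flagged end nodes of degree 0. Link paths include the attachment node
voxels at both ends, so Λ (the sum of physical step lengths along the path;
a z-step costs dz, an xy-diagonal √(dx²+dy²)) is well defined, and
Λ ≥ the Euclidean endpoint distance always. A closed chain of link voxels
with no node attaches to a synthetic degree-2 "cycle-anchor" node at its
lexicographically smallest voxel.

Cleaning iterates three procedures, in this order, to a fixed point
(at most `max_iterations` = 10 rounds, warning on non-convergence):

1. **side-chain pruning**: terminal links (an endpoint of degree 1) with
   Λ < 1.5 σ are deleted together with their end node; strict `<`, repeated
   within the step so spur cascades collapse.
2. **canal-node merging**: nodes with exactly two link incidences dissolve;
   the merged link has Λ = Λ₁ + Λ₂ (plus the traversed intra-node steps in
   the rare case of a multi-voxel canal node, so ΣΛ is conserved exactly in
   the generic single-voxel case). Cycle anchors are exempt — a loop needs
   one anchor to stay representable; a node whose whole degree comes from a
   single loop is re-flagged as an anchor.
3. **node collection**: single-linkage clustering of node positions at
   cutoff 0.9 σ (strict `<`, transitive closure). A cluster becomes one
   node at the member voxel nearest the member-position centroid (ties
   broken by lowest `(z, y, x)`), links re-attach, and intra-cluster links
   shorter than the cutoff are absorbed; longer ones become loops.

Node kinds are recomputed from final degrees (1 → end, ≥3 → branching).
Multi-links between the same node pair are retained: they are genuine
parallel strands. Pruning measures Λ along the path, not end-to-end —
consistent with the definition of link length. Cleaning never increases
node or link counts.

## Statistics

* **Box-edge correction** is a margin exclusion zone (default 1.5 σ):
  nodes within the margin of any box face leave N_N, links with an excluded
  endpoint leave N_L, and densities divide by the margin-shrunken volume.
  Margin 0 disables the correction (closed-box convention: positions
  exactly on the boundary count as inside).
* **Densities** are reported per µm³ and per σ³; conversion needs σ in µm,
  so when the grid is specified in σ units and no µm value is supplied the
  µm densities are reported as missing rather than guessed.
* **Ñ(Λ)** is a probability density (counts / (N · bin width)); default 20
  equal-width bins from 0 to the maximum Λ. Histogram counts at a given
  margin equal N_L at the same margin.
* **Tortuosity** builds the 26-adjacency graph of the skeleton voxels with
  physical step weights; for each axis, a multi-source Dijkstra from the
  lower-face voxel shell yields, for every upper-face voxel A, the shortest
  along-skeleton λ and the reached partner B, hence λ_Euc. Ratios pool over
  the three axes (per-axis means are also reported, so other weightings can
  be formed later); mean and standard deviation are over paths. Because a
  thinned strand retreats about one strand radius from a box face, terminals
  are taken from a shell of configurable depth `face_depth` (pipeline
  default 1.0 σ; 1 voxel when no σ context exists) rather than the literal
  face layer, which would almost always be empty. Degenerate pairs with
  λ_Euc = 0 are skipped; λ ≥ λ_Euc holds exactly, so ξ ≥ 1 per path. If no
  axis has a spanning path the result is flagged non-percolating.

## Phantoms: what they emulate and what they do not

The generator produces solid tubes, arcs, junctions and tori (closed-form
geometry, topology verified against the χ oracle at generation time), and a
bead-on-a-graph gel: nodes dart-thrown with ≥ 5 σ separation in a 40 σ box,
one node pulled onto each box face so the structure percolates in all three
directions, a Kruskal spanning structure plus ~0.3·n extra short edges, and
beads of diameter σ laid every 0.4 σ along the edges. Three constraints
keep the ground truth recoverable and are themselves physically motivated:
node degree ≤ 3 (higher-degree junctions generically skeletonize into split
Y-pairs closer than any sensible collection radius), ≥ 55° between edges
sharing a node, and ≥ 2 σ between unrelated strands (anything closer fuses
under the closing element, as it would in a real image). The ground-truth
graph is the generative graph with degree-2 waypoints contracted — exactly
what a curve skeleton sees. The image corruption applies a linear
depth-intensity drift and additive Gaussian noise, then clips at zero.

What the phantoms do **not** model: finite PSF anisotropy in the corrupted
image (available separately via `default_psf`, an anisotropic Gaussian with
defaults 0.21 σ lateral / 0.75 σ axial, truncated at 3 standard deviations),
Poisson photon statistics, particle polydispersity, and genuinely dense
gels where strands run closer than 2 σ. Passing the phantom suite shows the
chain is correct and self-consistent, not that the default parameters are
optimal for any particular microscope.

Rendered spheres use voxel-center inclusion without anti-aliasing (the PSF
convolution supplies realism); a point-emitter mode renders one voxel per
particle instead of a solid sphere.

## Numerical choices and problem sizes

* Digitized curve lengths measured as 26-adjacency chain sums overestimate
  the true length by up to ~5.5% averaged over directions (the classical
  staircase bias); shortest-path corner cuts recover part of it. Length
  checks on curved phantoms therefore use a 5% tolerance at the radii used
  (quarter arc R = 40 measures +3.4%); axis-aligned strands are exact.
* The semicircular-arc tortuosity check uses R = 80 voxels, tube radius 2
  and a 2-voxel face shell; it measures ξ = 1.53 against π/2 ≈ 1.571. The
  small negative bias is inherent to the "every top-face voxel" pooling at
  a face-tangential entry, not a discretization artifact.
* The topology-preservation suite uses 100 random 24³ volumes (Bernoulli
  0.3 fill followed by closing with radius 1) — large enough to contain
  thousands of nontrivial handles and cavities in aggregate, small enough
  to verify in seconds. The bead-network route comparison renders at
  0.25 σ voxels (160³), the smallest grid at which a σ-diameter strand
  spans 4 voxels.
* Thinning inner loops are JIT-compiled (numba); all other heavy steps are
  vectorized numpy/scipy. Everything is deterministic: one seeded generator
  flows through the phantom module, and no stage uses unordered iteration.

## Known limitations

* Link thickness/radius is not estimated; the fractal dimension is not
  computed (the link-length distribution it relates to is).
* Tortuosity pairs each top-face voxel with its path-nearest bottom-face
  voxel; other pairing rules (all pairs, nearest-crossing) would give
  slightly different ξ. Per-axis values are reported to allow re-weighting.
* Very thick structures (strand radius ≫ 10 voxels) thin correctly but
  slowly, as the sequential re-check is per-voxel.
* Proprietary microscope formats (LIF/CZI/ND2) and BigTIFF are out of
  scope; convert to plain multi-page TIFF first.
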