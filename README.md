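# netskel

Mesoscopic network analysis of aggregated particulate matter — colloidal
gels, fiber networks, protein or biofilm scaffolds — from 3D microscopy
stacks or explicit particle coordinates.

Local measures (pair correlations, coordination numbers) describe how
particles pack, but the mechanics of a gel is largely set by its *network*:
how strands branch, how long they are, and how erratically they wind through
space. `netskel` extracts that network and quantifies it. The pipeline is

1. **preprocess** — Gaussian blur, per-slice binarization, ellipsoidal
   morphological closing, small-cluster removal, 3D-enclosed hole filling;
2. **skeletonize** — topology-preserving 3D thinning down to a
   single-voxel-thin backbone;
3. **graphify** — conversion of the skeleton into a graph of nodes and
   links, followed by cleaning of skeletonization artifacts;
4. **netstats** — quantitative output: counts, densities, link-length
   distribution, tortuosity, with box-edge correction.

Coordinate data (e.g. from Brownian-dynamics simulations or particle
tracking) is first rendered into an image stack — optionally convolved with
a point-spread function — and then follows the identical route, so
experiment and simulation can be compared quantitatively. The method does
not need individually resolvable particles; it works directly on the
binarized material volume.

## The model

**Binarization.** Each z-slice is thresholded independently (this
compensates depth-dependent intensity loss). The automatic threshold is
Otsu's method; the manual one is

&nbsp;&nbsp;&nbsp;&nbsp;*I*<sub>T</sub> = *I*<sub>10</sub> + *V*<sub>u</sub> (*I*<sub>90</sub> − *I*<sub>10</sub>),

where *I*<sub>10</sub>, *I*<sub>90</sub> are the intensities below which 10%
and 90% of the slice's pixels fall and *V*<sub>u</sub> ∈ [0, 1] is
user-chosen. A voxel is material iff its intensity strictly exceeds
*I*<sub>T</sub>.

**Thinning.** Border voxels are deleted iteratively unless the deletion
would change the topology. A voxel *i* is deletable iff, in its 3×3×3
neighborhood *D*₃(*i*): it is not an *end point* (*D*₃ contains exactly two
material voxels), it is *Euler invariant* (deletion leaves the Euler
characteristic χ = objects − tunnels + cavities unchanged; evaluated from a
per-octant lookup table), and it is a *simple point* (deletion preserves
local 26-connectivity of material and 6-connectivity of background). Passes
sweep the six border directions in fixed order with a sequential re-check,
so the result is deterministic and idempotent.

**Graph.** Counting material voxels in *D*₃ (center included): 2 → end
voxel, 3 → link voxel, >3 → branching voxel. Adjacent branching voxels clump
into one node; link voxels trace paths between nodes; the link length Λ is
the physical path length (anisotropic voxels respected). Cleaning iterates
three procedures to a fixed point: side chains shorter than 1.5 σ are
pruned (σ = particle diameter), *canal nodes* (degree 2) are merged into
their through-link, and nodes closer than 0.9 σ are collected into one.

**Statistics.** Node/link counts *N*<sub>N</sub>, *N*<sub>L</sub> and
densities ρ<sub>N</sub>, ρ<sub>L</sub> (µm⁻³ and σ⁻³), the normalized
link-length distribution *Ñ*(Λ), and the tortuosity

&nbsp;&nbsp;&nbsp;&nbsp;ξ = ⟨λ / λ<sub>Euc</sub>⟩,

the mean ratio of along-backbone path length to Euclidean end-to-end
distance over all paths connecting opposite box faces in any Cartesian
direction (ξ ≥ 1; larger = more erratic strands). All counts exclude a
margin zone at the box faces.

## Worked example

`examples/04_gel_two_routes.py` builds a synthetic bead-network gel
(50 generative nodes in a 40 σ box, beads of diameter σ laid along the
strands) and analyzes it twice — once from the particle coordinates, once
from a rendered image corrupted with depth drift and Gaussian noise:

```
ground truth: N_N = 38, N_L = 52
coordinates : N_N = 38, N_L = 52, rho_N = 5.94e-04 sigma^-3, rho_L = 8.12e-04 sigma^-3, xi = 1.74 +/- 0.12 (47 paths)
noisy image : N_N = 38, N_L = 52, rho_N = 5.94e-04 sigma^-3, rho_L = 8.12e-04 sigma^-3, xi = 1.76 +/- 0.13 (48 paths)
```

Both routes recover the generator's graph exactly; the tortuosity of the
two routes agrees to 1%. The other examples skeletonize a cylinder
(Λ = 57 voxels on a 60-voxel axis, ξ = 1.000), clean a spurred junction to
the ideal *N*<sub>L</sub>/*N*<sub>N</sub> = 0.75, and thin a torus to a
single closed cycle with χ = 0.

## Command line

```bash
netskel run --input stack.tif --sigma 1.72 --voxel 0.105 0.105 0.21 --out results/
netskel run --config run.yaml          # batch mode, flags override the file
netskel phantom beads --out phantoms/  # emit synthetic fixtures
netskel version
```

Each run writes node/link tables (CSV), a JSON report, the histogram CSV,
the cleaned-skeleton TIFF, diagnostic overlays (binarization filter,
preprocessing diff, skeleton + branching nodes over the raw image, three
maximum-intensity projections) and a log of every parameter used. Repeated
runs with the same configuration are byte-identical.

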