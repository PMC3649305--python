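# Methods

## The model

A whole-body bone SPECT volume is treated as a cranial-to-caudal stack
of transaxial slices indexed `(z, y, x)`.  The method assumes that
bone-to-bone anatomical continuity shows up as *overlap between
binarized cross-sections on adjacent slices*, so the skeleton can be
represented as a directed graph ("bone graph"): nodes are per-slice
2D connected components of the thresholded volume, and a paired
down-link/up-link exists between two regions on adjacent slices iff
their `(x, y)` pixel sets intersect.  Each direction carries the
overlap weight `w_ij = |R(i)|·|R(i)∩R(j)|/|R(i)∪R(j)|²`, which is 0 for
disjoint and 1 for identical regions.  Restricting edges to adjacent
slices (rather than any pair of planes) keeps the up/down traversal
semantics meaningful; the asymmetric pair is kept on the edges and all
cluster-level quantities consume the symmetrized mean, making cluster
similarity `S(A,B)` symmetric and additive.

## Thresholding

Bone is separated from soft tissue by a single global threshold `T`
obtained by the closed-form bilevel moment-preserving rule: the first
three gray-level moments determine two representative levels `z0 < z1`
and a below-fraction `p0` (the two-point Gauss quadrature of the
histogram), and `T` is placed midway between the histogram bins
straddling the `p0` cumulative-mass cut.  Binarization is strict
(`value > T`).

The histogram fed to this rule is *boundary-weighted*: only voxels
whose 3D gradient magnitude reaches the `gradient_percentile` quantile
(default 0.9) contribute.  Flat background air and flat organ interiors
otherwise dominate the histogram and pull `T` down to just above the
soft-tissue level, which surrounds every bone with a one-voxel
partial-volume halo and can bridge nearby structures.  At the 0.9
quantile the histogram samples genuine tissue transitions and `T` lands
between the soft and bone levels; 0.5 was tried first and rejected for
exactly the halo behaviour above, because with Poisson noise the median
gradient magnitude is noise, not boundary.  For a constant volume the
operation refuses to guess and asks for the plain histogram
(`gradient_percentile=0`).

The oracle equivalence between the fractile rule and an exhaustive
moment-discrepancy search is asserted for two-population histograms,
where the bilevel model is well-posed; on such inputs the two cuts
coincide in ≳90% of random draws and never differ by more than one bin
(the fractile may sit one bin off the discrepancy optimum exactly at a
mode's edge).  On arbitrary multimodal histograms the equivalence is
not well-defined and is not claimed.

## Cluster extraction

`extract_cluster` seeds `C1` at the neck node and repeats: for every
cluster with `S_1i > 0`, compute
`d_i = |S_1i − S_other| / max(S_1i, S_other)`; merge if `d_i < 0.5`
(ties split), else decompose the cluster's image region.  All clusters
except `C1` remain singletons, so decomposition always acts on a single
node's pixel set `M`.  Reference regions follow the dilation/erosion
construction with a 5×5 square element: the `C1`-side neighbour's
projection dilated and clipped to `M`, plus each connected component of
the eroded remainder (made disjoint from the first member by
subtraction, which the source construction leaves unspecified).  The
references grow synchronously (3×3 steps) inside `M`; pixels reached by
two fronts in the same round become dams and block growth.  The *parts*
are the grown label regions plus any pockets left unreachable behind
dams — not the connected components of `M` minus the dams, because a
meeting front is a 4-connected barrier with diagonal gaps that does not
disconnect anything under 8-connectivity.  Replaced nodes get fresh
ids, recomputed features, and edges rebuilt only toward their two
adjacent slices (locality is tested).

Two practical rules close gaps the procedure's description leaves open:

* **Terminal rule.**  A chain end has `S_other = 0`, hence `d = 1`,
  hence "split" — but decomposition cannot change anything there.  If a
  split yields no topology change, the node is merged when its
  symmetrized similarity to `C1` exceeds `merge_floor` (default 0.05),
  otherwise its edges to `C1` are cut.  This guarantees progress and
  keeps terminal vertebrae.
* **Iteration cap.**  `cap_factor·|V|` events (default 10·|V|);
  exceeding it raises a non-convergence error carrying the event log,
  never a silent truncation.

A known failure mode is deliberately preserved: when a large blob is
fused to the spine through a very short attachment over several
consecutive slices, each split's dilated reference claims a ~2-pixel
collar of the blob, the collar joins `C1`, and the next slice's split
starts deeper — the blob is progressively absorbed.  This is the
ectopic-kidney behaviour seen when the kidney touches the spine, and
the gap-0 phantom reproduces it; with an attachment bridge longer than
the per-slice creep (or any separation ≥ 2 voxels) the decomposition
severs cleanly and no kidney voxel reaches the final mask.

## Landmarks

*Neck*: walk down-links from the largest region of the most cranial
slice, always into the largest child, tracking the running maximum
bounding-box area; the first node under `neck_ratio` (default 0.40) of
that maximum is `RP_Neck`.  Before clustering, edges crossing above the
neck slice are severed (`restrict_below_neck`): the landmark's purpose
is to bound the spine superiorly, and without the cut the cluster
climbs into the skull through the terminal rule.

*Legs and hip*: the caudal third of the binarized volume is collapsed
into `p(x)`, the per-x foreground count.  An exhaustive between-class-
variance threshold splits it; exactly two above-threshold runs are
required (else a leg-separation error).  Per-side y-profiles give ROI
centres (argmax, smallest index on ties) and diameters
`roi_sigma_multiplier · σ` of the weighted y-profile, floored at 3
pixels.  The multiplier defaults to 3: with discrete circular legs the
run-clipped y-profile has a flat maximal plateau and the smallest-index
tie rule biases the centre by up to half the plateau width, which a
2σ disc does not cover (2σ remains available and is what the uniform-
profile worked example uses).  Nodes whose centroid falls inside a
disc are leg nodes; both sets are traversed up-links in lockstep
rounds, and in the first round whose visited sets intersect the most
caudal common node is `RP_Hip-joint`.

*Pelvis*: in a working copy of the binarized volume, everything outside
the legs' x-span and every spine- or leg-marked region is erased; a
6-connected 3D region growing from all remaining foreground pixels of
the hip slice delimits the pelvic ring, and spine-mask voxels inside
its `[z_upper, z_lower]` range are removed.  This is what excludes the
bladder (hotter than bone, connected to the sacrum through
partial-volume ghost slices) at the known cost of the sacral spine
inside that range.

## The phantom

The generator emulates exactly the anatomy the method depends on, on a
64×64×180 grid (the full pipeline runs in ~2 s on one CPU): a head
widest at its base (so the neck transition is sharp), a cervical neck
cylinder, a vertebral column with ±0.7-voxel periodic radius
modulation ending in a narrower sacral tip inside the pelvic ring, thin
rib bars (3 voxels in y, 2 slices in z — realistic rib calibre at
~4.4 mm voxels) attached to thoracic vertebrae, an elliptic pelvic ring
whose lateral bands overlap the two long leg cylinders at the designed
hip slice (the graph's single Y-merge), a bladder sphere inside the
ring interior, and kidney ellipsoids at `kidney_spine_gap` voxel
columns from the spine (default 4; 0 = touching).  Uptake is
soft : bone : kidney : bladder = 1 : 6 : 8 : 12 with a soft-tissue
envelope obtained by dilating the skeleton; a Gaussian of
`psf_sigma = 1` voxel models the partial-volume effect and Poisson
noise is applied at `count_scale = 200` expected counts at bone uptake
(a low-noise, long-acquisition protocol).  Geometry is analytic and
seed-independent; the count noise is the only stochastic element,
drawn from one generator seeded by `PhantomSpec.seed`.

What the phantom does **not** model: reconstruction artifacts,
attenuation and scatter, non-uniform uptake within a structure, patient
motion, arms, and lesion hot spots.  Passing the recovery tests
therefore shows that the graph clustering, landmark detection and
pelvis exclusion behave as designed under blur and counting noise — it
does not certify performance on clinical reconstructions.

Inter-structure clearances are ≥ 4–5 voxels wherever structures must
stay distinct, because at clinical blur a one-voxel halo is expected
around every bone; the intended connections (leg-ring overlap at the
hip, spine-bladder ghost chain through the sacrum, gap-0 kidney fusion)
are likewise built in deliberately.

## Numerical choices

* Connectivity: 8-connected within slices (bone cross-sections are
  blobby; diagonal necks should not split regions), 26-connectivity for
  the spine-mask invariant, 6-connected region growing for the pelvis,
  zero-padded 3×3×3 opening for the final mask.
* Ties everywhere resolve to the smallest index / id, making every
  stage deterministic; the pipeline is bit-reproducible for a given
  volume and configuration.
* Degenerate inputs raise typed errors naming the stage (constant
  volume, single-valued histogram, missing legs, empty hip slice,
  empty final mask); an empty mask is never returned silently.
* Analyze 7.5 output uses little-endian int16 when counts fit (the
  format has no unsigned 16-bit type), float32 otherwise.

## Problem sizes

The shipped test-suite and acceptance-script sizes: phantom pipelines
on the 64×64×180 grid (~0.9 s generation + ~1.5 s extraction each),
100 random ≤200-node graphs for the termination property, 100 random
mask pairs for the TP+FN identity, and oracle sweeps on ≤64-bin
histograms, ≤16×16 slices and ≤32×32 regions.  The whole suite runs in
well under a minute on one CPU.
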