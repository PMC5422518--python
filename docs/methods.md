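# Methods

## Scope and model

`mandifem` simulates the load transfer through a mouse mandible during
mastication with small-strain isotropic linear elasticity.  Four
scenarios are modelled — gnawing (incisal biting) and chewing (molar
biting), each at a soft- and a hard-pellet bite force — using published
bite-load components and muscle allocation fractions (see the README
table).  Everything upstream of the solve is synthetic: a parametric
phantom replaces the micro-CT scan, so every stage of the pipeline can
be validated against known ground truth.

Coordinates: x anteroposterior (+x anterior), y mediolateral,
z superoinferior (+z dorsal); units mm, N, MPa.  Voxel `[i,j,k]` is
centred at `origin + (index + 0.5) * spacing`; mesh nodes lie on the
voxel-corner lattice.

## The phantom and what it does (not) emulate

The phantom is a simplified full mandible in a 15 x 8 x 6 mm box at
0.1 mm voxels: two hemimandibles joined at an anterior symphysis, each
with a corpus beam, an ascending ramus carrying condylar, coronoid and
angular processes, one curved incisor (circular arc through the corpus;
enamel shell, dentin, pulp, mesenchymal growing end) and a three-molar
row (enamel cap, dentin body, pulp core), every tooth wrapped in a
0.2 mm periodontal-ligament (PDL) shell seated in alveolar bone.
Grayscale is tissue mean intensity (eight equally spaced levels in
[0, 255], ordered enamel > dentin > cortical > alveolar > PDL >
mesenchyme > pulp > background), blurred by a Gaussian point-spread
function and corrupted by additive Gaussian noise; a seed fixes the
noise exactly, and labels are noise-independent.

Defaults were chosen once as the study conditions: noise sigma 6
(about 1/6 of the inter-class gap, a clean laboratory scan), blur sigma
0.02 mm (a sub-voxel PSF: the real scan resolved enamel and PDL as
separate entities, so the phantom is generated well-resolved), PDL
thickness 0.2 mm (two voxels — the minimum at which a layer is
resolvable), pulp radius 0.2 mm (two voxels, so the pulp has interior
voxels not dominated by interface gradients).

What the phantom does **not** emulate: anatomically curved bone
surfaces (all bodies are boxes, ellipsoids and tubes, so surface strain
patterns are blockier than reality), beam-hardening or ring artifacts,
intensity inhomogeneity, enamel anisotropy, one-sided incisor enamel,
and the open alveolar crest geometry of real sockets.  Passing tests
therefore demonstrate correctness of the *method* under controlled
conditions, not fidelity of absolute stress values for a real mandible.

## Segmentation

Thresholds are estimated from the intensity histogram after excluding
the top 10% gradient-magnitude voxels (central differences), i.e.
partial-volume voxels on tissue interfaces, so class levels are
estimated from interior voxels.  The k-class partition maximizes
between-class variance.  Two implementation points matter:

- The optimum is found by an exact O(k·nbins²) dynamic program over
  256 bins (within-class sum of squares decomposes over contiguous bin
  runs).  Common implementations enumerate cut combinations and are
  infeasible at k = 8.
- Tissue compartments differ in volume by orders of magnitude (pulp
  ~1e3 voxels, background ~6e5) while sitting ~4 noise-sigma apart, and
  the count-weighted Otsu optimum then prefers splitting the dominant
  mode over isolating a faint one.  Bin counts are therefore
  log-weighted, and a dominant dark (background) mode is handled
  explicitly: its spread is estimated by a MAD fit to its dark flank,
  the first cut placed at mode + 2 sigma (a ~97.7% background
  quantile), and the remaining classes partitioned above that cut.
  With the default equally spaced class means the resulting cuts land
  within ~5% of the true inter-class midpoints at noise = 0.25x the
  class gap.

Classes map to tissues by intensity rank.  A voxel exactly equal to a
cut joins the lower class.  Optional cleanup removes connected
components below 20 voxels (26-connectivity) and fills small enclosed
cavities, reassigning each suspect voxel to the majority class among
its non-suspect 26-neighbours — a voxel is never moved to a class
absent from its original neighbourhood, so cleanup cannot invent
tissue.  Large enclosed regions (pulp inside dentin) are legitimate
anatomy and are not "filled".

Known limitation: structures thinner than the PSF cannot retain their
interior intensity, so per-class Dice under a one-voxel blur is bounded
well below 1 for the enamel shell and pulp regardless of algorithm;
accuracy claims are therefore stated and tested at the noise-only
condition.

## Meshing

Voxels are grouped into `coarsen`-cubed blocks; each block's label is
the majority vote (ties to the lowest code), background-majority blocks
are dropped, and blocks containing >= 3 distinct tissues keep their
majority *tissue* so thin multi-tissue interfaces survive coarsening.
Each retained block splits into five tetrahedra whose mirror parity
alternates with block parity, making face diagonals of neighbouring
blocks coincide: the mesh is conforming and tiles the retained blocks
exactly (volume conservation to round-off).  Triangle surfaces come
from marching cubes on the binary tissue mask after a ~1-voxel Gaussian
anti-aliasing (guarded so no connected component is lost), which
removes the stair-step area bias of binary marching cubes (a binary
sphere otherwise over-estimates area by ~9%; anti-aliased it is within
0.5%).

## Finite elements

TET4/CST elements: stiffness `V·B^T·D·B`, Voigt order
[xx, yy, zz, xy, yz, zx] with engineering shear.  Assembly is
vectorized; the reduced system (fixed dofs eliminated, prescribed
displacements moved to the right-hand side) is solved by sparse LU,
with a CG + ILU fallback beyond ~4e5 dofs; the relative residual must
be <= 1e-8 or the solve raises.  Reactions are `K u - f` on constrained
rows.  Stress is element-constant; nodal values, where needed for
display, are volume-weighted averages.  Verification: patch test and
uniaxial cube exact to round-off; slender cantilever (L/h = 10, ten
elements through the thickness) within 1.9% of the Euler–Bernoulli tip
deflection, with monotonically decreasing error under refinement; six
rigid modes per element; equilibrium of reactions and loads to 1e-15
relative.

TMJ constraints fix all translations of condylar-surface nodes within
about one element of each condyle's mediolateral axis.  The selected
patch spans a little curvature, so no rigid mode survives while
rotation about the axis meets only weak elastic resistance; if the
selection is collinear the band widens, and failing that the
constructor raises.  Muscle `F_z` shares sum to 0.88 by construction
and are not renormalized — the TMJ reactions close equilibrium, which
is also where the (physical) constraint-point stress concentration
appears.

## Analysis choices

- Regional statistics use element-constant von Mises values; the
  headline statistic is the 99th percentile, since the raw maximum is
  dominated by the constraint-point singularity under refinement (the
  maximum is reported alongside).
- Skeletal regions are axis-aligned boxes (dumped with every run for
  auditability); dental regions are tissue-based, with the
  incisor/molar split by signed distance to the respective tooth
  surfaces (scale-free, stable under coarsening).  The dorsal-ramus
  region excludes the articulated condylar dome for the same
  singularity reason.
- The convergence study solves hard-pellet gnawing (the largest load)
  at coarsening levels (4, 3, 2) on one fixed label volume and tracks
  per-entity p99 von Mises.  The mandible-bone entity converges to
  within 1%; the incisor, molar and PDL entities do not reach 5%,
  because block coarsening moves stair-step bimaterial interfaces (with
  stiffness contrasts up to 4e4) by up to half a block per level and
  the PDL is only two voxels thick.  This is reported, not hidden: the
  study table carries all four entities.
- `pdl_cushioning_test` compares peak alveolar-bone stress between the
  published PDL modulus and a 100x-stiffened PDL under both chewing
  loads.  In this phantom the compliant PDL *raises* the alveolar peak
  (ratio stiff/soft ~ 0.2): the teeth span the bent corpus, so a stiff
  PDL couples the much stiffer teeth into the bending load path and
  shields the compliant alveolar bone, while a compliant PDL ring acts
  as a soft inclusion around which bending flux detours.  For a rigid
  tooth on an elastic foundation the socket tractions are statically
  determinate, so local load-spreading by a softer ligament has no
  leverage against this global-bending effect.  The comparison is
  reported as measured; an ordering the other way (cushioning) should
  not be expected from a beam-like geometry with teeth crossing the
  neutral axis.
- Similarly, on this phantom gnawing stresses the dorsal ramus more
  than chewing (bending moment ~4x larger), so "chewing concentrates
  stress dorsally" holds only in the immediate molar region; the
  scenario report makes both comparisons explicit.
- The lever oracle (`sigma = F·d·c/I`, rectangular section) is a
  closed-form sanity check for the gnawing-vs-chewing ordering, not a
  calibration.

## Numerical details and degenerate inputs

Degenerate (non-positive-volume) elements raise with the element id.
Majority ties in meshing go to the lowest tissue code; threshold ties
to the lower class; both documented and tested.  A constant volume or
k exceeding the distinct intensity count is a degenerate-input error in
threshold estimation.  A phantom whose PDL would be thinner than one
voxel is rejected, naming the parameter.  All randomness flows from the
single phantom seed (default 20170509); identical specs give
bit-identical volumes.

## Problem sizes

Default runs mesh the segmented default phantom (150 x 80 x 60 voxels)
at coarsening 3: ~26k elements, ~22k dofs, ~1 s per scenario solve
after a shared factorization.  The convergence study's finest level
(coarsening 2) has ~86k elements.  These sizes were chosen as the
smallest at which the regional statistics and the verification oracles
are stable; all of them are configuration parameters.
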