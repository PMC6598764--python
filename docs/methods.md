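# Methods

## Problem and model

Hepatocytes are not simple columnar epithelial cells with one apical pole:
their apical (bile-facing) membrane forms several patches and belts spread
over the cell surface, and their basal (sinusoid-facing) membrane occupies
the complement. `hepnem` quantifies this organization at two scales:

1. **Per cell** — the apical (or basal) membrane pattern is summarized by
   a nematic tensor. The cell surface, a triangulated mesh with per-vertex
   membrane labels, is radially projected onto the unit sphere centered at
   the cell's volumetric centroid (this assumes star-convexity; violations
   are counted). A triangle belongs to the marker set when at least two of
   its vertices carry the marker label. With A_i the solid angle of
   projected triangle i and n_i the unit direction of its spherical
   centroid,

       N = (3/2) · Σ_{i∈marker} A_i (n_i ⊗ n_i − I/3) / Σ_{i∈marker} A_i .

   N is symmetric and traceless; its eigenvalues ordered σ2 ≤ σ3 ≤ σ1 (sum
   zero) and eigenvectors give the **bipolar axis** a1 (σ1, largest) and
   the **ring axis** a2 (σ2, smallest). Two point-like antipodal marker
   caps give σ1 = 1 with a2 undefined; a thin marker belt gives σ2 = −1/2
   with a1 undefined. Real cells sit between the extremes — both axes
   carry information, i.e. polarity is biaxial.

2. **Per lobule** — a reference direction field J is built from the vein
   geometry: each triangle of the central-vein (CV) and portal-vein (PV)
   surface meshes contributes a point charge at its centroid with strength
   proportional to its relative area, +1 total on the CV and −1 on the PV.
   The potential χ(r) = Σ q_i/|r−r_i| is the Green's-function superposition
   (equivalently the steady state of diffusion from source to sink), and
   J = ∇χ, normalized, is the local CV–PV direction. Alignment of any axis
   family {e_i} with references {g_i} is scored by

       S = (1/N) Σ_i [ (3/2)(e_i·g_i)² − 1/2 ]  ∈ [−1/2, 1],

   1 parallel, 0 isotropic, −1/2 perpendicular. For biaxial objects with
   orthonormal triads, purely uniaxial order about the first axis predicts
   S2 = −S1/2; a measured S2 above this baseline is evidence of biaxial
   order (tested one-sided, paired across replicates, with a sign-flip
   permutation cross-check).

Network skeletons (sinusoids, bile canaliculi) get the same treatment with
length-weighted segment orientations; the local preferred axis around a
cell uses segments whose midpoint falls within one hepatocyte diameter
(20 μm, configurable), clipped to the ball so only in-ball length counts.

Layered order is detected from segmented density grids: both structures
are mean-projected along the imaging z-axis, cross-correlated with the
normalized cross-correlation

    C_SH[k,l] = 1/(N_S+N_H) Σ_{n,m} (S[n,m]−μ_S)(H[n+k,m+l]−μ_H)/(σ_S σ_H),

and the 2D correlation is mean-projected onto the layer-normal direction
with 1.5 μm bins. With this prefactor two
identical images give C[0,0] = 1/2 rather than 1 (an overlap-normalized variant
is available behind `mode="overlap"`). The mean-centered second image is
zero-padded outside its valid range; this choice (rather than padding the
raw image) makes C_SH[k,l] = C_HS[−k,−l] exact, which we treat as a
defining property of the statistic.

## Period estimation and significance

The correlation profile of a layered tissue is periodic but not
cosine-like: complementary structures (hepatocyte vs sinusoid) produce
sharp *minima* at multiples of the period separated by broad plateaus,
in-phase structures sharp maxima. The period is therefore the mean spacing
of successive significant extrema of one sign — maxima and minima are
evaluated as separate families and the more prominent family wins; for a
cosine profile both give the same answer, and a single extremum reports
its lag. Extremum positions are refined by 3-point quadratic
interpolation, and extrema closer than the minimum credible lag (5 μm)
are merged.

Significance uses a line-scramble null: every line of one image is
independently circularly shifted along the profile direction, which
preserves each line's content and the overlap envelope while destroying
the inter-line phase coherence that layering creates (a rigid shift of
the whole image would merely translate the profile and have no power).
200 resamples define a 95% band on the maximum absolute oscillation; a
profile with no extremum above the band yields "no period", which is the
expected outcome along the CV–PV (control) direction.

## Synthetic lobules

The generator emulates the statistical structure the analysis assumes,
with every stage's ground truth stored:

* **Cells**: icospheres (subdivision 4, 5120 faces) with 5% radial
  jitter, radius 10 μm. Apical labels are Bernoulli draws from a pattern
  density — antipodal caps about a1 (`pure_bipolar`), a belt normal to a2
  (`pure_ring`), or their mixture (default, weight 0.5). Sharpness κ
  (default 40) sets the belt half-width ≈ ±9°; the mixture's caps use κ/4
  so both components carry comparable marker mass (a cap holds ~1/κ of
  the sphere, a belt ~1/√κ; equal nominal weights would drown the bipolar
  signal). Basal labels are placed on the complement, concentrated by the
  dual pattern (bipolar and ring roles swapped, width κ/4, on a 0.25
  uniform background): this is the geometry of apical–basal repulsion and
  reproduces the observed sign pattern — same-type apical/basal axes
  perpendicular, different-type parallel. A literal full-complement basal
  would be nearly isotropic and its axes pure noise.
* **Lobule**: a box (default 300×200×100 μm) with CV (r=25 μm) and PV
  (r=20 μm) as parallel cylinders at opposite x-ends, tessellated to
  ≤15 μm edges so the surface-charge density is approximately uniform.
  Cell centers are dart-throwing Poisson-disk samples at 0.9× cell
  diameter separation (confluent but non-overlapping). True bipolar axes
  follow a Watson distribution (density ∝ exp(κ(u·J)²), the axial
  analogue of von Mises–Fisher) about the local J with κ_align = 5,
  chosen so S(a1,J) ≈ 0.55–0.65, the ordered-tissue regime. With ring
  coupling on (default), the ring axis is biased toward the in-plane
  component of J (κ = 5), giving ring-axis order above the uniaxial
  baseline while keeping S(a2,J) < 0; with it off, the in-plane angle is
  uniform and S2 = −S1/2 holds. Sinusoid skeletons are chains (150
  chains, 8 × 5 μm steps) with segment orientations Watson-distributed
  about J at κ = 10.
* **Layered grids**: alternating slabs perpendicular to an in-plane
  normal; each 24 μm period holds one 4 μm sinusoid slab (hepatocyte =
  exact complement; 24 = 20 μm hepatocyte + 4 μm sinusoid diameter), the
  slab position jittered per layer by ±10% of the spacing, and a 2 μm
  bile-canaliculi slab centered between sinusoid slabs. Default volume
  150×150×60 μm at 0.3 μm voxels.
* The disordered (`kd_preset`) condition reduces κ_align and the sinusoid
  κ to 0.5 and disables ring coupling while leaving all per-cell pattern
  parameters untouched — tissue-level order collapses, per-cell (σ1, σ2)
  distributions do not.

What the generator does **not** emulate: realistic cell shapes beyond
star-convex jittered spheres, network topology (loops, branching
hierarchies), partial-volume and segmentation noise in the density grids,
and any mechanistic coupling between cells and networks (axes are drawn
independently around J rather than emerging from interactions). Passing
tests therefore validate the estimators and their statistical behavior
under the assumed structure, not the biological claims themselves.

## Numerical choices

* Solid angles by the Van Oosterom–Strackee formula (signed; negative
  triangles are star-convexity violations, counted, used unsigned).
* Volumetric centers by signed-tetrahedron centroids for closed meshes
  (every edge shared by exactly two triangles); vertex centroid with a
  warning otherwise.
* Eigen-decompositions via `numpy.linalg.eigh`; axes are sign-free, the
  stored representative has non-negative z (ties: y, then x); no
  statistic depends on the representative.
* Degeneracy tolerance 0.05 on the defining eigenvalue gap; degenerate
  axes are excluded from alignment averages (their direction is noise).
* Gaussian local averaging (sd 20 μm ≈ one hepatocyte diameter)
  normalizes by the summed kernel weight, so the principal eigenvalue is
  an interpretable local order weight in [0, 1]; the principal axis is
  unaffected by the normalization. Isolated cells keep their own axis.
* Reference-field evaluations are refused within 2 μm of any charge
  (near-surface singularities); stagnation points (|∇χ| < 1e-14) return
  an absent direction.
* Welch's unequal-variance t-test for two-condition comparisons; the
  biaxiality excess is tested with a one-sided paired t-test across
  replicates plus a sign-flip permutation cross-check.
* Watson sampling by vectorized rejection on cos θ against the uniform
  envelope (acceptance ~1/(2κ); exact, no approximation).

## Problem sizes

Analyses in the test suite run on lobules of 60–800 cells and grids at
0.3 or 0.6 μm voxels; the reproduction script uses the generator defaults
(300 cells, 150×150×60 μm grids at 0.3 μm, 200 null resamples). These
sizes put Monte-Carlo error comfortably below the tolerances asserted
(e.g. 800 ground-truth axes give a standard error of ~0.012 on S against
a 0.03 tolerance).

## Known limitations

* The spherical projection requires star-convex cells; strongly
  non-convex segmentations would need a different projection.
* The 1/(N_S+N_H) prefactor makes profile values depend on the image-size
  ratio; comparisons across differently sized regions should use the
  overlap-normalized variant.
* The line-scramble null assumes the profile direction is close to one
  image axis; for oblique directions the scramble axis is the nearest
  image axis, an approximation.
* Period estimation assumes at least two periods fit in the region of
  interest and a single dominant spacing.
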