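# Methods

## Problem setting

Muscles segmented from MRI arrive as closed triangulated surfaces with
arbitrary, specimen-specific vertex counts and no anatomical landmarks.
The pipeline quantifies shape variation across such a cohort without
constructing landmarks by hand: surfaces are rigidly superimposed, a mean
surface is built iteratively, shape differences are measured by a
closest-point metric that is insensitive to vertex count, and the
resulting distance matrix is ordinated and related to participant
covariates.

## Superimposition

**Kabsch/Umeyama.** For corresponded point sets the weighted
least-squares similarity transform is closed-form via SVD of the weighted
cross-covariance; the determinant-sign correction excludes reflections.
Collinear configurations (second singular value at numerical zero) are
rejected.

**Pose initialization.** ICP is local, so each mesh is first centered and
rotated so its vertex-covariance eigenvectors align with the coordinate
axes (long axis to z). Axis signs come from the sign of the mixed
third-order moment E[p_j·|p|²] along each axis. The plain coordinate
skewness E[p_j³] is the textbook choice but is structurally zero whenever
vertices are distributed symmetrically along an axis even though the
*shape* is not — a tapering muscle sampled uniformly along its length is
exactly this case — and an uninformative sign means a coin-flip 180°
flip per specimen that ICP cannot undo. The mixed moment sees the taper
(and the anterior bow) directly and makes the pose deterministic and
consistent across independent samplings of one surface. When the two
informative axes are fixed, the third sign follows from det(R) = +1.

**Size.** Optional size removal (on by default) scales each mesh to unit
root-mean-square vertex radius. RMS radius is the sampling-invariant
analog of centroid size: centroid size itself grows with √(vertex count),
so normalizing by it would rescale physically identical muscles sampled
at different densities by up to √2 — which in early testing made the
first ordination axis the vertex count rather than any shape mode.
`centroid_size` (the classical definition) is still provided as the
geometric-morphometrics size measure.

**ICP.** Alternates closest-point correspondence with the Kabsch fit.
The default correspondence is point-to-triangle (each moving vertex to
its closest point on the fixed *surface*, via a face-centroid KD-tree
with exact per-triangle projection); vertex-to-vertex is available but
measurably stalls about 1 mm from the optimum at 10³-vertex sampling,
because its fixed points are quantized to the vertex spacing. Iteration
stops when the relative improvement of the correspondence RMS falls below
`tol` (1e-6 standalone; 1e-4 inside the group loop, where registration is
revisited every outer pass anyway). The reported transform is the best
observed, so results are non-increasing in the iteration budget.

## Group-wise alignment (GPSA)

Given a prototype: (1) ICP-register every specimen onto the current
reference, (2) homologize — for each reference vertex take the nearest
specimen vertex (ties to the lowest index), (3) average the homologized
sets into the new reference; repeat. Convergence is declared when the RMS
reference-vertex change drops below `tol` × (reference RMS size), i.e. a
scale-free 0.1% of mesh size by default (~65 µm for a calf muscle); an
absolute millimetre tolerance would be either meaningless or arbitrarily
strict in the unit-size working frame. With rough, coarsely sampled
surfaces the reference can keep wobbling just above the threshold; the
result is then returned with `converged=False` and is still a valid
superimposition — the wobble is orders of magnitude below the shape
signal.

The prototype is chosen as the specimen with the lowest (or rank-k
lowest, for when a first choice is rejected on visual inspection) mean
pairwise distance after single-pass pairwise ICP; a full GPSA per
candidate is what the sensitivity sweep does. The interspecimen distance
matrix is computed once, on the final aligned specimens, with the
vertex-based symmetric metric.

## Ordination

Classical scaling: B = -½·J·(D∘D)·J, eigendecomposition, scores =
eigenvectors × √eigenvalue. Negative eigenvalues (possible because the
surface metric need not be Euclidean) are dropped and their total
magnitude logged; variance percentages are shares of the positive
total. Axis signs follow one convention — the specimen with the largest
absolute score is made positive — so plots are reproducible. Extreme
shapes are linear per-vertex regressions of homologized coordinates on
axis scores through the mean; the variation heat map is the per-vertex
displacement norm between the two extremes.

## Covariate models

OLS with dummy coding against young/female reference levels; body mass
enters as its natural log; the age-by-sex interaction is available.
Backward stepwise elimination supports an AIC criterion (default) and a
significance (alpha) criterion, both respecting marginality: an
interaction leaves before its main effects, and main effects are
protected while their interaction remains. Partial r² per term is
t²/(t²+df), which equals the residual-sum-of-squares ratio definition
identically for single-column terms. Group comparisons use Welch's
t-test when both samples pass Shapiro–Wilk at α = 0.05, otherwise
Mann–Whitney. No multiple-testing correction is applied across axes or
muscles; this is recorded in the model metadata. Effect-plot data export
provides partial residuals (residuals plus the term's contribution), the
partial-regression line through the covariate-adjusted means, and
confidence bounds from the coefficient's standard error.

## Synthetic populations

The generator produces closed fusiform generalized cylinders — not
anatomically faithful muscles — with three latent factors:

- **girth** scales both cross-section semi-axes (×(1+0.1·girth));
- **elongation** scales length (×(1+0.1·elongation));
- **torsion** twists cross-sections about the long axis in the proximal
  40% only, by `torsion_max` = 0.4 rad (≈23°) per factor SD — sized so
  the torsion mode carries a variance share comparable to the torsion
  modes reported for real muscle cohorts (on the order of 10–20%) rather
  than disappearing into the sampling-noise floor.

The profile tapers to points at both ends, is widest just proximal of
mid-belly, and the centerline bows slightly (6% of length): these
asymmetries are anatomically motivated and make the principal-axis pose
of every specimen well determined. Vertices sit exactly on the surface
at jittered parameter positions, so two specimens never share grid
structure (emulating independent segmentations and exercising the
landmark-free property); per-specimen vertex counts are drawn from a
range (default 800–1600). Additional Gaussian vertex noise (default
0.5 mm) models segmentation roughness. Covariates follow the shape by
construction: height tracks realized length (r ≈ 0.8), mass is lognormal
around a BMI-linked mean of height, activity is group-dependent, and
volume is measured from the generated mesh itself. Default cohort sizes
are 21 young and 15 older; the default ageing effect is −1 SD girth and
+0.5 SD elongation in the older group, plus +0.5 SD girth for male sex.

What passing tests do and do not show: the generator's surfaces are
smooth, unimodal and noise-stationary, so recovery results demonstrate
the statistical machinery, not robustness to segmentation artefacts,
non-fusiform anatomy (e.g. soleus aponeurosis geometry) or missing data.

## Problem sizes and numerical choices

Test and acceptance runs use populations of 30 specimens at 800–1600
vertices (factor recovery, group-effect power; vertex noise 0.1 mm so
sampling, not noise, is the binding resolution limit), 10–12 specimens at
300–600 vertices for pipeline/determinism checks, and 200 score-level
replicates for type-I control; these sizes were chosen so the whole suite
runs on a laptop-class single core in minutes while leaving each check
well away from its decision boundary. Duplicate-vertex merge tolerance is
1e-9 mm; quads are fan-triangulated on read. Smoothing maps the spatial
scale σ to `round((σ/mean edge)²)` umbrella iterations; the Taubin pair
is (λ, µ) = (0.5, −0.5) — the common −0.53 inflate weight has pass-band
gain slightly above one at the lowest frequency and measurably inflates a
sphere by 3–4% over many iterations, violating volume preservation, so
the balanced pair is the default and both weights are arguments. Mesh
scalars round-trip bit-exactly through legacy-VTK ASCII (17 significant
digits) and at float32 precision through PLY.

## Known limitations

- The surface metric's vertex-to-vertex minimum makes interspecimen
  distances carry a sampling-density floor at coarse resolutions; it
  cancels almost entirely under double centering but contributes a noise
  plateau to the eigenvalue spectrum. Denser meshes (the realistic
  regime: 10⁵–10⁶ points) make it negligible.
- ICP is local: pose initialization assumes clearly anisotropic shapes
  with informative third-order moments. Near-spherical or highly
  symmetric objects are flagged but not handled specially.
- Prototype sensitivity is quantified (the sweep), not corrected for.
- The stepwise procedures are greedy; agreement with exhaustive search
  is verified on the tested problem class, not guaranteed in general.
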