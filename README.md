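# muscleshape

Landmark-free statistical shape analysis of skeletal-muscle surface
meshes: generalized Procrustes surface analysis (GPSA), principal
coordinates ordination, extreme-shape reconstruction with per-vertex
variation maps, and linear models of shape scores on participant
covariates — together with a synthetic muscle-population generator that
makes the entire pipeline testable with known ground truth.

## Who this is for

Imaging and biomechanics groups who segment individual muscles from MRI
into triangulated surfaces and want to quantify three-dimensional shape
variation across a cohort — without placing anatomical landmarks, which
muscles largely lack. Each specimen is just a closed surface with its own
vertex count; no point correspondence across specimens is assumed.

## The method

**GPSA.** Pick a *prototype* surface (the most "average" specimen: lowest
mean pairwise distance to all others), superimpose every specimen onto it
by iterative closest point (ICP) registration, take for each prototype
vertex the nearest specimen vertex (the *homologized* points), average
those into a new reference, and iterate until the mean surface is stable.
Shape difference between two superimposed surfaces *A*, *B* is the
symmetric, point-weighted Procrustes surface metric

```
d(A,B) = sqrt( 1/2 [ mean_{a in A} min_{b in B} |a-b|^2
               + mean_{b in B} min_{a in A} |b-a|^2 ] )
```

in which each surface carries equal total weight regardless of its vertex
count.

**Ordination.** Classical (Gower) principal coordinates of the k x k
distance matrix: double-center the squared distances, eigendecompose, and
scale eigenvectors by the square roots of the positive eigenvalues. For
Euclidean distances this is exactly PCA of the generating configuration.
Per-vertex regression of the homologized coordinates on an axis's scores
yields theoretical shapes at extreme scores and the displacement
heat map between them.

**Covariate models.** Per axis, ordinary least squares of the scores on
age group, sex, height, log body mass, muscle volume and physical
activity (MET-min/week) plus the age-by-sex interaction; backward
stepwise reduction (AIC or significance criterion, marginality
respected); partial r² per term as t²/(t²+df); Welch t or Mann–Whitney
group comparisons gated by Shapiro–Wilk normality.

## Worked example

```python
import numpy as np
from muscleshape import (PopulationConfig, generate_population,
                         generalized_align, pcoa)

cfg = PopulationConfig(n_young=15, n_older=15, factor_sds=(1, 1, 0),
                       effects={}, vertex_count_range=(800, 1600),
                       vertex_noise_sd=0.1, seed=11)
specimens, covariates, truth = generate_population(cfg)
meshes = [s.mesh for s in specimens]
res = generalized_align(meshes, meshes[0].specimen_id)
ordn = pcoa(res.distances, ids=res.specimen_ids)
print(np.round(ordn.pct_variance[:3], 1))
for f in ("girth", "torsion"):
    r = max(abs(np.corrcoef(truth[f], ordn.scores[:, j])[0, 1])
            for j in range(3))
    print(f, round(r, 3))
```

prints

```
[42.4  9.4  3.1]
girth 0.999
torsion 0.981
```

PC1 carries 42.4% of shape variance and is the girth (width/thickness)
mode; the proximal axial-torsion factor is recovered by one of the first
three axes at |r| = 0.98. The generator planted exactly these two factors,
so the pipeline has recovered the latent structure it was given — the
core claim the test suite checks.

The `examples/` directory has one short script per capability
(simulation, alignment, ordination and extremes, covariate models, full
pipeline); each prints what it computes and what the numbers mean. A thin
CLI mirrors the stages:

```
muscleshape simulate --out pop --seed 1
muscleshape run --config run.yaml --seed 1
```

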