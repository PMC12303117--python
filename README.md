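# wingmorph

Theoretical-morphospace analysis of insect wing planforms: how much of
the geometrically possible space of wing shapes do real wings occupy,
and are the occupied shapes the ones that fly best?

The package quantifies closed 2-D wing outlines, embeds them in a PCA
morphospace, tiles that space with a grid of *theoretical* wings (shapes
no insect need ever have grown), scores every geometrically viable
theoretical wing for three antagonistic flight proxies, ranks the
trade-off with a Pareto approach, and asks how empirical shapes relate
to the resulting optimality landscape, to phylogeny, and to covariates
such as size and climate. It is aimed at evolutionary morphologists
working with outline-based (landmark-free) morphometrics.

## The pipeline

1. **Shape quantification** — each closed outline is standardized,
   resampled to P = 150 boundary points, and decomposed by elliptical
   Fourier analysis (EFA) into H = 9 harmonics of four coefficients
   (aₙ, bₙ, cₙ, dₙ). Normalizing out size, rotation, position and
   starting point pins a₁ = 1, b₁ = 0, c₁ = 0, leaving 4H − 3 = 33 free
   shape descriptors per wing.
2. **Morphospace** — covariance PCA over the coefficient vectors; the
   empirical (PC1, PC2) box, extended by a 20% border on every side, is
   tiled 26 × 19 = 494 ways; each grid point is back-projected to
   coefficients and reconstructed by inverse EFA. Self-intersecting
   reconstructions are flagged non-viable and excluded from all
   functional analyses.
3. **Performance** — per viable cell:
   * aspect ratio `AR = R²/S` (span R, area S) — induced-drag proxy;
   * non-dimensional radius of the second moment of area
     `r̂₂ = sqrt(∫₀¹ ĉ(r̂) r̂² dr̂)` with normalized chord ĉ = cR/S —
     lift-production proxy (tip-heavy wings score higher);
   * median von Mises stress from a thin-plate finite-element model
     (2500 discrete-Kirchhoff triangles, E = 1 GPa, ν = 0.49, four
     clamped base nodes, 0.003 N transverse tip load, shapes
     pre-normalized to equal area and thickness) — breakage proxy.
4. **Optimality** — Goldberg front-peeling gives each viable shape a
   forward rank f (1 = Pareto front of maximize AR, maximize r̂₂,
   minimize VMS) and a reverse rank b under inverted objectives; the
   Pareto rank ratio `(b − 1)/(f + b − 2)` (1 if f = 1) maps every
   shape onto a 0–1 optimality landscape. Pairwise trade-offs are
   available alongside the three-way one.
5. **Comparative analyses** — multivariate phylogenetic signal
   (K_mult, the multivariate Blomberg's K; K = 1 under Brownian
   motion, permutation p over 9999 iterations), a phylomorphospace
   (BM ancestral shape reconstruction projected into PC1/PC2), and
   OLS/PGLS regressions of shape and size on covariates.

Because the analyses are demonstrated on data with known ground truth,
`wingmorph.synth` generates smooth wing-like outlines controlled by two
latent axes (overall breadth; apical-tip vs humeral-base loading),
pure-birth trees, Brownian trait evolution, and covariates with
configurable slopes — every stage is testable against the generator's
truth.

## Worked example

```python
import numpy as np
from wingmorph import (
    SimulationConfig, gen_wing_set, orient_standard,
    resample_equal_arclength, efa_forward, efa_normalize,
    fit_shape_space, build_theoretical_grid,
)
from wingmorph.efa import coeffs_to_vector

outlines, truth = gen_wing_set(SimulationConfig(n_taxa=60, seed=0))
X = np.vstack([
    coeffs_to_vector(efa_normalize(efa_forward(
        resample_equal_arclength(orient_standard(o), 150), 9)))
    for o in outlines
])
space = fit_shape_space(X)
grid = build_theoretical_grid(space)   # 26 x 19 with 20% border
print(f"PC1 {100*space.explained_variance[0]:.1f}%, "
      f"PC2 {100*space.explained_variance[1]:.1f}%; "
      f"{grid.n_cells} theoretical wings, "
      f"{int((~grid.viable).sum())} self-intersecting")
```

prints

```
PC1 85.0%, PC2 14.8%; 494 theoretical wings, 0 self-intersecting
```

i.e. the first axis (wing breadth) carries 85% of synthetic shape
variation, the second (tip-to-base loading) most of the rest, and all
494 back-projected shapes in this gentle synthetic family are simple
polygons. The numbered drivers under `analysis/` continue from here:
`04_performance_landscapes.py` reports AR ranging 2.6–9.2 across the
grid with rank correlation −1.00 against PC1 (near-vertical contour
stripes: breadth alone sets AR), r̂₂ ranging 0.46–0.66 tracking PC2
(ρ = +0.97), and `05_pareto_optimality.py` finds 56 of 494 shapes on
the Pareto front, with the pairwise AR–VMS landscape nearly identical
(ρ = +0.98) to the three-way one.

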