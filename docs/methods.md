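# Methods

This note documents the models, parameter choices and numerical
behaviour of `wingmorph`. Defaults quoted here are the package's study
conditions; every one is overridable through the relevant function or
`RunConfig`.

## Outline conventions

An outline is an ordered closed polygon (no duplicated endpoint) in
continuous coordinates. The standard frame puts the humeral (proximal)
wing base at minimum x, the span along +x, counter-clockwise traversal,
area centroid at the origin, and traversal starting from the minimum-x
vertex. Area uses the shoelace formula; centroid size is the square
root of summed squared vertex distances from the vertex mean and is
computed on the P-point resampled outline so it is comparable across
sources with different raw vertex counts. Self-intersection uses the
GEOS simplicity predicate on the closed ring, which counts proper
crossings, mid-edge touches and collinear overlaps — verified against a
brute-force all-pairs segment test with exact orientation predicates.

Equal-arc-length resampling places P points (default 150) at equal
perimeter intervals starting from the standard start vertex. One pass
is exact for the piecewise-linear boundary; because equal *arc* spacing
along a curved polygon yields slightly unequal *chords*, a second pass
moves points by ~4·10⁻⁴ of span on a 150-point wing and the iteration
contracts geometrically. Downstream code treats a single pass as
canonical.

## Elliptical Fourier analysis

Forward EFA follows the Kuhl–Giardina chord-length parameterization.
Normalization uses the first-harmonic ellipse: the start phase is
shifted to a semi-major-axis crossing, the shape is rotated so that
axis lies on +x, and coefficients are scaled by its magnitude, giving
a₁ = 1, b₁ = 0, c₁ = 0 exactly (33 free values at H = 9). Two genuinely
open choices were resolved as follows:

* **180° ambiguity** — of the two semi-major crossings, we keep the one
  that maps the input curve's parameter-0 point (the wing base under
  the standard frame) to the negative-x side. Anchoring on the input's
  own base keeps the coefficient response *continuous* across families
  of shapes whose broad end migrates from base to tip; anchoring on a
  property of the reconstruction (e.g. which end is pointier) folds
  such families and corrupts PCA axes.
* **Reflection** — never applied; d₁ keeps its sign, so traversal
  handedness (and leading/trailing asymmetry) is preserved. Inputs are
  standardized to counter-clockwise order first.

The inverse transform evaluates the truncated series at P uniform
parameter steps; for normalized coefficients evaluation starts at the
base-side crossing so reconstructions begin at the wing base like every
other outline in the pipeline.

Two idealizations often stated for EFA do not hold exactly and are
tested in their honest form instead. (i) The Fourier fundamental of an
arc-length-parameterized ellipse is *not* the ellipse itself: for
semi-axes (2, 1) the fundamental has axes (1.8284, 1.0730), which the
implementation reproduces to four decimals against an independent
quadrature oracle. (ii) forward∘inverse is not an exact identity,
because re-forwarding reparameterizes by the reconstruction's chord
length; the drift starts at ~4·10⁻³ per coefficient on smooth wings and
contracts on iteration, while the per-point shape error of a single
round trip stays below 0.5% of span — the property that matters for
grid reconstruction.

Harmonic sufficiency is assessed against a high-order reference
decomposition (H_ref = ⌊P/2⌋ − 1 = 74): the cumulative power
(aₙ² + bₙ² + cₙ² + dₙ²)/2 of the first nine harmonics exceeds 99.5% of
the reference total on the synthetic wing family (measured ≈ 99.99%).

## Morphospace and the theoretical grid

PCA is covariance-based (no per-column rescaling; coefficient units are
commensurable, and rescaling would distort reconstructed shapes). The
pinned columns survive as zero-variance directions. The theoretical
grid extends each empirical axis range by 20% *per side* and places
26 × 19 = 494 cell centers inclusive of the extended endpoints. Grid
coefficients are mean + PC1·v₁ + PC2·v₂ with all other scores zero and
the pinned values re-imposed. Viability is exactly the non-self-
intersection of the reconstructed 150-point outline.

On the default synthetic family all 494 cells are viable: the generator
produces gentle shapes whose linear span stays inside the simple-polygon
region. Non-viable regions appear when empirical data place extreme
tip-to-base ratios near the border (as real wing datasets do); the
screening path is exercised in tests with deliberately self-intersecting
reconstructions.

Occupation is reported two ways: the fraction of grid cells whose
half-spacing rectangle contains at least one empirical score, and the
convex-hull area of the scores as a fraction of the bordered box.

## Performance metrics

* **AR = R²/S** on the single wing planform, exactly as defined (no
  wing-pair factor).
* **r̂₂** — the radius of the second moment of area follows the
  standard non-dimensional convention
  r̂₂² = ∫₀¹ ĉ(r̂) r̂² dr̂ with ĉ = cR/S, square root applied; chords
  are vertical-slice y-extents at the midpoints of n = 200 equal
  spanwise intervals (extents summed when a slice is multiply
  connected), integrated by the midpoint rule. Closed forms
  (rectangle √⅓, tip-tapering triangle √⅙, tip-widening triangle √½)
  are matched within 1% and convergence follows the midpoint-rule
  rate.
* **Median VMS** — see below. The mean is exposed as an option because
  either summary may be wanted; the median is primary.

Landscapes are 10 equal-interval bands between the observed min and max
over viable cells.

## Plate finite elements

The wing is idealized as a uniform thin plate of its planform — the
standard membrane idealization for wings without modelled venation.
Meshing: boundary points are placed by subdividing each polygon edge at
roughly the lattice spacing (keeping all original vertices, so summed
element area equals polygon area to machine precision), the interior is
a hexagonal lattice with 0.55h boundary clearance, and scipy's Delaunay
triangulation is culled to centroid-inside triangles. The spacing is
tuned by secant iteration plus removal of evenly strided interior
points (each removal deletes ~2 triangles) until the element count is
within ±2% of the 2500-element target.

Bending uses discrete Kirchhoff triangles (9 DOF: w, θx, θy per node)
with the three-mid-edge quadrature rule, E = 1 GPa, ν = 0.49. Every
shape is rescaled to unit area and given thickness 0.01·√area before
meshing, so absolute stress units are internal by construction and
only the ordering of median stresses feeds the Pareto ranking. Boundary
conditions: all DOF clamped at the boundary node nearest minimum x plus
its three nearest boundary neighbours; a 0.003 N transverse point load
at the maximum-x boundary node. Element von Mises stress comes from
top-surface bending stresses 6M/t² at the element centroid.

Validation: tip deflection of a 20:1 plate clamped along its short edge
matches the Euler–Bernoulli cantilever closed form within 0.5% at 2000
elements; stresses are exactly linear in load and in 1/t²; the median
VMS moves < 5% between 2500 and 5000 elements; and slender equal-area
planforms are stressed more than compact ones, as expected for
base-clamped bending.

## Pareto rank ratio

Dominance is the usual strict Pareto relation under per-metric
directions (defaults: maximize AR, maximize r̂₂, minimize median VMS;
equal weighting is inherent to dominance — nothing is scalarized).
Goldberg ranking peels non-dominated fronts. The rank ratio combines
the forward rank f with the reverse rank b (all directions inverted):
ratio = (b − 1)/(f + b − 2), with f = 1 taking precedence (ratio 1) and
b = 1 otherwise giving 0; a single solution scores 1 and identical
vectors share ranks. The source literature describes the ingredients
but not the arithmetic; this is the minimal formula reproducing the
documented endpoint semantics (Pareto front ⇒ 1, dominated by all ⇒ 0),
and interior values may differ from other implementations.

## Phylogenetic analyses

The Brownian covariance C holds shared root-to-MRCA path lengths.
Ancestral states are GLS estimates: the root is the phylogenetic mean
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y and node k is â + cₖᵀC⁻¹(Y − 1â) with cₖ the
node-tip shared path lengths — O(n³) linear algebra chosen for
transparency over pruning at the tree sizes used here. K_mult is

K = [tr(EᵀE) / tr(EᵀC⁻¹E)] ÷ [(tr C − N/(1ᵀC⁻¹1)) / (N − 1)],  E = Y − 1â,

with the permutation p-value (# K_perm ≥ K_obs + 1)/(iters + 1); at the
default 9999 iterations the attainable floor is 10⁻⁴. K = 1 holds
identically on equal-depth star trees and averages 1 over Brownian
simulations (measured 1.02 over 200 replicates on a 64-tip tree). By
default K_mult runs on the full 33 free coefficients; PC scores can be
passed instead. Phylomorphospace projects tip coefficients and
reconstructed ancestors through the fitted space; taxa missing from the
tree are retained as unconnected points.

## Regressions

Five standard pairings (log centroid size → shape PC1; temperature →
log size; temperature → PC1; rainfall → PC1; rainfall → PC2), fit by
OLS and by PGLS (GLS with Σ ∝ C; statsmodels' whitened-model F and R²).
Centroid size enters logged by default, with a flag. PGLS reduces to
OLS exactly on equal-depth star trees, and on Brownian-correlated
residuals it holds the type-I error near nominal where OLS inflates —
both asserted in tests. Taxa with missing covariates are dropped per
test and per-test n is reported. No multiple-testing correction is
applied by default (a Holm option exists).

## Synthetic data

`gen_wing_outline` builds a closed planform from a half-width envelope
h(s) = ½·span·[(1−s)·base_width_frac + s·tip_width_frac]·sin(πs)^q and
a camber bump m(s) = camber_asym·span·s(1−s); q = 0.6 gives rounded
elliptic-like caps, and h > 0 on (0,1) guarantees simplicity within the
documented parameter bounds. Two latent axes map linearly to the
parameters (breadth: total width; tipness: base-to-tip transfer at
constant total) — linear deliberately, because any curvature in the
latent-to-coefficient response bleeds into spurious PCA axes (the
horseshoe effect). The generator's axes are recovered by the pipeline's
own PCA at |r| ≥ 0.99.

Study conditions for the `analysis/` drivers: 60 taxa, latent SDs
(1.0, 0.5), covariate slopes on the breadth latent of 0.3 (temperature),
0.0 (rainfall — a true null) and 0.3 (log size), residual SD 0.3 —
effects detectable at n = 60 without being deterministic, and a null to
confirm specificity. Trees are pure-birth (rate 1) via dendropy; the
simulation stops at the birth of the n-th tip, so the present is
advanced by an Exp(n·λ) draw to keep pendant branches positive and the
covariance matrix well-conditioned. BM traits are drawn through the
Cholesky factor of rate·C.

What the generator does *not* emulate: venation, real allometric
curvature, clade structure in shape (latents are drawn independently of
the tree, so phylogenetic signal in shape is near zero by construction
— the K_mult calibration uses separately simulated BM traits), outline
digitization noise, and measurement error. Passing tests therefore
demonstrate correctness of the machinery and recoverability of known
effects, not biological realism of any particular landscape.

## Problem sizes and determinism

Default test and driver scales: 150-point outlines, 9 harmonics,
494-cell grids, 2500-element solves for the study drivers (≈ 0.1 s per
cell; the full landscape stage runs in about a minute), smaller
meshes/grids in unit tests. Every stochastic step takes an explicit
integer seed (numpy `default_rng` / `random.Random`); a pipeline run is
bit-reproducible given its config, and the acceptance script derives
all of its randomness from `--seed`.
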