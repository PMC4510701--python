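# Methods

## Model

The tissue is a two-dimensional compressible viscous sheet. Cells are
3D-incompressible, but a monolayer can trade height for area, so in 2D
the pressure is absorbed into an effective constitutive law
`sigma = 2 eta D(v)` with effective shear viscosity `eta` and no
pressure unknown. Inertia is negligible at tissue scales, so the
momentum balance is quasi-static: viscous stresses balance substrate
friction, `div(sigma) = C_f v`. The closure machinery acts only on the
free edge, as a traction `t = (f_L - gamma * kappa) n`:

- `f_L` (nN/um) — lamellipodial crawling force per unit edge length,
  directed into the gap, curvature-independent;
- `gamma` (nN) — purse-string cable tension, acting through the signed
  edge curvature `kappa`;
- `n` — unit normal pointing into the gap (tissue exterior).

Sign conventions are pinned so that the model transcribes without sign
flips anywhere: the level-set field is positive in the gap, so
`n = grad(phi)/|grad(phi)|` is gap-ward and `kappa = div(n)` is `-1/R`
on a circular gap. Tissue protruding into the gap has `kappa > 0`; the
`-gamma*kappa` term then pulls such fingers back while adding
`+gamma/R` to the drive on circular edges, which is exactly the
mechanism-synergy/antagonism picture the model encodes. Both `f_L` and
`gamma` are taken curvature-independent; curvature-dependent
generalizations are deliberately out of scope.

Friction screens edge-driven flow over `l = sqrt(2 eta / C_f)`. The
outer tissue boundary is traction-free and placed a configurable number
of screening lengths from the gap (default 8; a warning is issued below
5). Moving it from 8 l to 12 l changes the edge speed by < 1e-6
relative on the circular benchmark, so the arbitrary enclosure is
immaterial.

Everything is linear in `(f_L, gamma)`: solutions superpose exactly
(used both as a test and to decompose closure into its mechanisms), and
scaling all of `(eta, C_f, f_L, gamma)` by a common factor leaves the
velocity unchanged.

## Axisymmetric closed form

For an annular tissue `a < r < R_out` the radial balance
`2 eta (v'' + v'/r - v/r^2) = C_f v` gives
`v_r = A I1(r/l) + B K1(r/l)`; `(A, B)` follow from
`2 eta v'(a) = f_L + gamma/a` (the applied edge traction, with
`kappa = -1/a`) and a traction-free rim `v'(R_out) = 0` (`R_out = inf`
keeps only `K1`). The implementation verifies this solution by
substituting it into a high-resolution finite-difference form of the
ODE (relative residual <= 1e-6). Closure curves integrate
`da/dt = v_r(a)` with `solve_ivp` at rtol 1e-8, holding `R_out` fixed
(the rim is screened), and report non-closing parameter sets instead of
iterating forever.

## Discretization

**Velocity solve.** Linear (P1) finite elements on a Delaunay
triangulation built from the interface polyline (resampled at the grid
spacing) plus regular-grid points, thinned away from the interface
(full density within ~1.5 l, half to ~4 l, quarter beyond). Grid points
closer than 0.6 cells to the interface are dropped, which makes the
interface segments Gabriel edges and hence actual mesh edges, so the
edge traction is integrated consistently (linear interpolation of
`T n` over boundary edges). The operator
`int 2 eta D(v):D(w) + C_f v.w` is SPD for `C_f > 0` and solved by
sparse LU; `C_f = 0` is rejected naming the rigid-body null space.
Reusing the factorization across load vectors makes the
mechanism decomposition at fixed geometry exact to machine precision.
A fixed-domain (one-fluid) variant that meshes the gap as a very soft
fictitious material and applies the traction as an internal force is
available (`keep_gap=True`); the body-fitted tissue mesh is the default
because it is the more accurate of the two against the Bessel oracle
(0.05% vs 0.13% edge-speed error at h = a/40).

**Level set.** The interface is the zero set of a signed-distance field
on a regular grid. Exact polyline distances (shapely) are used near the
interface and vertex distances far away. Zero crossings from marching
squares are sharpened from linear to cubic sub-cell accuracy along grid
lines; without this the redistancing fixed point drifts at O(h^2 kappa)
and curvature sampling is noisy. Curvature `div(grad phi/|grad phi|)`
is computed by centred differences, reported in a 5-cell band, and
capped at `|kappa| <= 1/(2h)`: discrete curvature at unresolved corners
would inject unbounded traction, and the cap refines away with the
grid. A contour-based estimator (circumcircle through a vertex and the
two vertices nearest to +/-15 um arc distance) mirrors the experimental
analysis; using true vertices rather than interpolated points makes it
exact on sampled circles.

**Transport.** Second-order ENO upwind differences with Heun time
stepping (first-order upwind available), CFL-limited
(`dt <= 0.5 h / max|v|`, adaptive by default; fixed steps are checked
and rejected with the admissible step). The advection band (5 cells)
carries the solved FEM tissue velocity at tissue-side grid points —
important wherever the flow varies along the edge, e.g. the slow region
behind a corner, which a closest-point extension would overwrite with
face values — and a constant extension (nearest interface node) on the
gap side. After each step the field is rebuilt as the exact signed
distance to the extracted contour, densified through a periodic cubic
spline (spacing h/8) on smooth contours and linearly where the contour
has turning angles above 30 degrees (a spline rings at kinks and would
displace the corner every step).

**Time loop.** Per step: extract contour(s) → curvature → solve →
extend → advect → redistance. Termination when the gap area falls below
`area_min` (default `(2h)^2`, sub-resolution) or `t_end`. Multiple
loops (pinch-off) are handled throughout: meshing, traction, area
(even-odd region), and their areas are summed. The loop is
deterministic; identical configurations reproduce traces bit-for-bit.

## Synthetic data

Gap geometry families: circles (vertices emitted exactly on the
circle), moon gaps, multi-lobed shapes `r = r0 + eps cos(m theta)`, and
polygons. The moon gap joins a semicircle (radius R) and a semi-ellipse
(semi-axes R, |h|) on a shared diameter; `h` is signed so that `h > 0`
bulges the tissue *into* the gap, giving pole curvature `+h/R^2`
(exactly `h/R^2` in the limit of fine sampling) and gap area
`pi R^2/2 - pi R h/2`. Sweeping `h` through zero sweeps the pole
curvature from negative through flat to positive, which is what the
curvature–velocity analyses need.

Synthetic micrographs place a stationary low-pass-filtered Gaussian
texture (sd `sigma_tissue`, correlation ~1.5 px) over the tissue and a
near-constant intensity (sd `sigma_gap << sigma_tissue`) in the gap,
plus per-frame sensor noise; generation is a pure, seeded function of
(mask, spec). Time-lapses keep one static texture field across frames —
as in a real movie, where the tissue texture does not decorrelate
between frames — and refresh only the sensor noise. The default
benchmark movie shrinks a 50 um circular gap at 1 um/min sampled every
3 min, so the per-frame edge displacement (3 um) exceeds the ~1 um
boundary-localization noise of the segmentation, matching the
signal-to-noise of experimental closure movies. What these fixtures do
not emulate: phase-contrast optics (halos, shading), individual cell
boundaries, leader-cell protrusions and edge roughness; tests passing
on them therefore validate the pipeline's geometry and kinematics, not
its robustness to real optical artifacts.

## Segmentation

Range filter (windowed max - min, odd window, edge-replicated borders)
→ threshold (Otsu-style maximal between-class variance by default, or a
fixed value) → binary closing (r = 2 px) → hole filling → small-object
removal (< 50 px) → largest component → dilation by `window // 2`. The
final dilation compensates the filter's systematic half-support erosion
of the gap (the response is high wherever any tissue texture lies
within the window); it is what keeps the mask IoU >= 0.95 and stable
(spread < 0.01) across window sizes 7–13 on the seeded fixture. For
movies the automatic threshold is locked from the first frame so the
detected boundary does not drift with the shrinking gap fraction of the
histogram. Mask boundaries are extracted at sub-pixel accuracy (with a
one-pixel pad so gaps touching the frame edge still close) and, for
kinematic analysis, smoothed along arc length (Gaussian, 2–3 um) to
suppress pixel-scale raggedness that would otherwise corrupt normals.

## Edge kinematics

Edge samples carry the signed three-point curvature (15 um arc spacing,
as in the experimental protocol) and the normal velocity, measured as
the displacement to the next contour along the local normal divided by
the frame interval (positive into the gap); rays that miss the next
contour within the search window are dropped and counted. Normals for
velocity measurement are averaged over a +/-5 um arc (8 um for
segmented movies): on ragged contours a two-vertex normal points almost
randomly and the oblique crossing overestimates displacement by
1/cos(error). Sampling is stratified — one seeded draw per stratum — by
curvature (default, covering the whole curvature spread) or by arc
length (`stratify="arc"`), the latter for contours whose curvature
spread is pure noise (a circle), where curvature-extreme vertices are
artifacts and sampling them induces a regression-to-the-mean bias.

The velocity–curvature relation is summarized by a linear fit near zero
curvature (its |slope| is proportional to the cable tension; a paired
comparison of runs at gamma and 2 gamma on the same geometries recovers
the factor 2 exactly) or by the 3-parameter logarithmic decay
`v = a - b ln(kappa - kappa0)` with `kappa0` constrained below the
smallest observed curvature. Landmark (pole) velocities track the
intersections of a symmetry axis with the contour. Shape evolution is
quantified by the isoperimetric ratio `Q = 4 pi A / P^2`.

## Study conditions used by the tests and the acceptance script

Chosen once, as representative of micro-patterned gap assays, and kept
small enough that the full suite runs in minutes on one CPU:

- Bessel benchmark: `a = 20`, `eta = 1`, `C_f = 0.04` (`l ~ 7.1`),
  `f_L = 1`, `gamma = 5`, rim at `a + 8 l`, `h in {a/20, a/40, a/80}`.
- Closure benchmark: `a0 = 30`, purse-string only (`gamma = 10`,
  `l = 5`), `h = 0.5`, circular enclosure at `8 l`.
- Kinematics: moon family `R = 30`, `h in {-20,...,+20}`, balanced
  forces `f_L = 0.5`, `gamma = 15`, `l = 6`, `h_grid = 1`; samples are
  drawn while the gap is still resolved (area > 25% of initial,
  perimeter > 4 arc spacings), since the 15 um three-point estimator is
  meaningless on near-closure loops.
- Shape phenotypes: five-lobed gap (`r0 = 25`, `eps = 8`) under
  purse-string only; 50 um square under crawling only, with `l = 6`
  comparable to the gap size so viscous coupling (not local friction)
  sets the corner dynamics.

## Numerical limitations

- **Sharp corners and cusps.** The per-step area budget
  `|dA + dt * integral(v_n ds)| <= 1% |dA| + h^2` holds along entire
  runs for smooth interfaces (circles, lobed gaps, moons with `h <= 0`).
  At sharp corners (square) and cusps (moon `h > 0`, where the
  semi-ellipse meets the semicircle tangentially) the upwind transport
  erodes the gradient kink at a rate that is first order in `h` and
  independent of `dt` and of the ENO order, so worst steps miss the
  budget by up to ~2% of `|dA|` plus a few `h^2`. All runs, including
  corner geometries, satisfy a `2% |dA| + 4 h^2` budget at `h = 1`.
  Resolving corner budgets to 1% would need adaptive refinement or
  explicit corner tracking, both out of scope.
- **Roundness floor.** The isoperimetric ratio of an extracted n-gon
  cannot exceed that of a polygon; once a purse-string run has rounded
  to `Q ~ 1`, the discrete `Q` decreases again as the shrinking contour
  loses vertices, at the regular-n-gon deficit scale (`~pi^2/(3 n^2)`).
  Monotone smoothing is therefore asserted up to that floor.
- The closure threshold `(2h)^2` means sub-resolution endgames
  (interface thinner than a cell or two) are reported as closed rather
  than resolved; a final step in which the interface vanishes entirely
  is excluded from budget accounting since the model is defined only
  while the gap has area.
- No cell proliferation, no stochastic leader cells, no edge-roughness
  fluctuations, no curvature dependence of `f_L` or `gamma`.
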