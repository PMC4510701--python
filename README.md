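# epigap

Continuum modelling and analysis of epithelial gap closure.

When a gap opens in an epithelial monolayer — a wound, or a void left by
extruded cells — the surrounding tissue closes it by two cooperating
mechanisms: **lamellipodial crawling** of border cells on the substrate,
and constriction of a supracellular actomyosin **purse-string** cable
along the edge. Which mechanism dominates depends on the local geometry
of the edge, and the two leave distinct signatures in the relation
between edge curvature and edge velocity and in how the gap's shape
evolves (crawling sharpens, purse-string smooths).

`epigap` implements a quantitative model of this process and the image
analysis used to confront it with time-lapse microscopy, exercised
entirely on synthetic geometries and synthetic micrographs. It is aimed
at tissue biophysicists who want to simulate gap closure, decompose it
into its mechanisms, or reproduce the curvature–velocity analysis on
their own contour data.

## Model

The monolayer is a compressible 2D viscous sheet (cells adjust height,
so the 3D pressure drops out of the effective law):

```
sigma = 2 eta D(v),      D(v) = (grad v + grad v^T) / 2
```

balanced quasi-statically against substrate friction:

```
div(sigma) = C_f v        in the tissue
```

The free edge carries a traction with the two closure mechanisms:

```
sigma . n = (f_L - gamma * kappa) n      on the gap edge
```

where `n` is the unit normal pointing into the gap, `f_L` the crawling
force per unit edge length (always into the gap), `gamma` the cable
tension, and `kappa` the signed edge curvature — negative around a
circular gap (so both mechanisms add up), positive where tissue
protrudes into the gap (so the purse-string pulls the edge backwards).
Friction screens the flow over the hydrodynamic length
`l = sqrt(2 eta / C_f)`.

The interface is tracked as the zero level-set of a signed-distance
field, advected by the tissue velocity from a finite-element solve of
the momentum balance on a mesh fitted to the current edge. For circular
gaps the whole problem reduces to modified Bessel functions
(`v_r = A I1(r/l) + B K1(r/l)`), which serve as the built-in accuracy
oracle.

Units are um, min and nN throughout; nondimensional parameter sets work
identically.

## Worked example

Close a 15 um circular gap by purse-string only and compare with the
axisymmetric closed form:

```python
import numpy as np
from epigap import (ModelParams, ShapeSpec, make_gap_contour,
                    analytic_radial_velocity, analytic_circular_closure)
from epigap.simulate import RunSchedule, run
from epigap.analysis import area_decay

params = ModelParams(eta=1.0, c_f=0.08, f_l=0.0, gamma=10.0)  # purse-string only
print(f"screening length l = {params.screening_length:.2f} um")

a0 = 15.0
R_out = a0 + 8 * params.screening_length
v0 = analytic_radial_velocity(a0, a0, R_out, params)
print(f"initial edge speed (closed form): {v0:.3f} um/min")

contour = make_gap_contour(ShapeSpec("circle", radius=a0, resolution=0.25))
trace = run(contour, params, RunSchedule(t_end=500.0, store_every=5),
            h=0.5, outer="circle")
oracle = analytic_circular_closure(a0, params, R_out)
t_ref = oracle.time_to_area(RunSchedule().resolve_area_min(0.5))
print(f"simulated closure at t = {trace.final_time:.2f} min "
      f"(ODE oracle: {t_ref:.2f} min)")
fit = area_decay(trace)
print(f"area decay: slope {fit.slope:.1f} um^2/min, R^2 = {fit.r_squared:.3f}")
```

prints

```
screening length l = 5.00 um
initial edge speed (closed form): -1.391 um/min
simulated closure at t = 6.65 min (ODE oracle: 6.45 min)
area decay: slope -109.5 um^2/min, R^2 = 0.992
```

The negative closed-form speed means the edge moves inward; the
level-set run closes within ~3% of the ODE prediction at this
resolution, and the area decays near-linearly (R² = 0.99) as observed
for closing gaps.

Other entry points: `run_decomposed` re-runs one geometry with full,
crawling-only and purse-string-only forces; `sample_edge_points` /
`fit_velocity_curvature` produce the curvature–velocity relation from
any contour time series; `segment_movie` turns a TIFF stack into
contours via range filter → threshold → morphology → boundary
extraction. A `epigap` command-line tool exposes the stages
(`synth`, `simulate`, `decompose`, `analyze`, `segment`, `validate`)
over YAML configs.

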