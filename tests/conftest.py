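"""Shared fixtures; the expensive simulations are session-scoped so the
oracle comparison, kinematic analysis and budget checks reuse one run."""

from __future__ import annotations

import pytest

from epigap.mechanics import ModelParams, analytic_circular_closure
from epigap.segmentation import SegConfig, segment_movie
from epigap.simulate import RunSchedule, run
from epigap.synthetic import (
    ShapeSpec,
    SyntheticImageSpec,
    make_gap_contour,
    make_shrinking_circle_movie,
    make_synthetic_frame,
)

# study conditions reused across tests: screening length 5 um for the
# closure benchmark, 6 um for the shape/kinematics families
PS_PARAMS = ModelParams(eta=1.0, c_f=0.08, f_l=0.0, gamma=10.0)
BAL_PARAMS = ModelParams(eta=1.0, c_f=2.0 / 36.0, f_l=0.5, gamma=15.0)


@pytest.fixture(scope="session")
def closure_benchmark():
    """Purse-string closure of a 30 um circular gap at h = 0.5 um,
    paired with the axisymmetric ODE oracle at the same stopping area."""
    a0, h = 30.0, 0.5
    contour = make_gap_contour(ShapeSpec("circle", radius=a0, resolution=h / 2))
    schedule = RunSchedule(t_end=5000.0, store_every=10)
    trace = run(contour, PS_PARAMS, schedule, h=h, margin_lengths=8.0, outer="circle")
    R_out = a0 + 8.0 * PS_PARAMS.screening_length
    oracle = analytic_circular_closure(a0, PS_PARAMS, R_out)
    return trace, oracle, schedule.resolve_area_min(h)


@pytest.fixture(scope="session")
def moon_family_traces():
    """Balanced (crawling + purse-string) runs of the moon-gap family,
    sweeping the pole curvature from negative through zero to positive."""
    schedule = RunSchedule(t_end=6.0, store_every=1)
    traces = {}
    for h_moon in (-20.0, -10.0, 0.0, 10.0, 20.0):
        c = make_gap_contour(ShapeSpec("moon", radius=30.0, h=h_moon, resolution=0.5))
        traces[h_moon] = run(c, BAL_PARAMS, schedule, h=1.0, margin_lengths=8.0)
    return traces


def resolved_contours(trace, min_area_frac=0.25, min_perimeter=60.0):
    """(t, contour) pairs while the gap is still resolved: curvature at
    15 um spacing needs a perimeter of several spacings, and near-closure
    frames are sub-resolution."""
    if not trace.areas:
        return []
    A0 = trace.areas[0]
    return [
        (r.t, r.loops[0])
        for r in trace.stored
        if r.loops
        and r.loops[0].area > min_area_frac * A0
        and r.loops[0].perimeter > min_perimeter
    ]


@pytest.fixture(scope="session")
def tension_sweep_traces():
    """Purse-string-only moon runs at gamma and 2*gamma (early frames),
    for the slope-proportional-to-tension check."""
    out = {}
    for gamma in (10.0, 20.0):
        traces = []
        for h_moon in (-8.0, 0.0, 8.0):
            c = make_gap_contour(ShapeSpec("moon", radius=30.0, h=h_moon, resolution=0.5))
            p = ModelParams(eta=1.0, c_f=2.0 / 36.0, f_l=0.0, gamma=gamma)
            traces.append(run(c, p, RunSchedule(t_end=3.0, store_every=1), h=1.0))
        out[gamma] = traces
    return out


@pytest.fixture(scope="session")
def lobed_ps_trace():
    """Purse-string-only closure of a five-lobed gap (smoothing phenotype)."""
    c = make_gap_contour(
        ShapeSpec("lobed", radius=25.0, lobe_amplitude=8.0, lobe_count=5, resolution=0.5)
    )
    p = ModelParams(eta=1.0, c_f=2.0 / 36.0, f_l=0.0, gamma=10.0)
    return run(c, p, RunSchedule(t_end=1000.0, store_every=2), h=1.0)


@pytest.fixture(scope="session")
def square_crawl_trace():
    """Crawling-only closure of a square gap (sharpening phenotype)."""
    c = make_gap_contour(
        ShapeSpec(
            "polygon",
            vertices=[(-25, -25), (25, -25), (25, 25), (-25, 25)],
            resolution=0.5,
        )
    )
    p = ModelParams(eta=1.0, c_f=2.0 / 36.0, f_l=0.5, gamma=0.0)
    return run(c, p, RunSchedule(t_end=1000.0, store_every=2), h=1.0)


@pytest.fixture(scope="session")
def seg_fixture():
    """Seeded synthetic frame: 60 um circular gap, 0.5 um/px, seed 1."""
    spec = SyntheticImageSpec(shape_px=(320, 320), pixel_size_um=0.5, seed=1)
    contour = make_gap_contour(
        ShapeSpec("circle", radius=60.0, center=(80.0, 80.0), resolution=0.5)
    )
    image, mask = make_synthetic_frame(contour, spec)
    return image, mask, contour, spec


@pytest.fixture(scope="session")
def movie_fixture():
    """Shrinking-circle time-lapse (1 um/min, 3 min frames) with its
    segmented contour series."""
    spec = SyntheticImageSpec(shape_px=(320, 320), pixel_size_um=0.5, seed=2)
    stack, masks, times = make_shrinking_circle_movie(50.0, 1.0, 6, 3.0, spec)
    contours = segment_movie(
        stack, SegConfig(window=9, pixel_size_um=0.5, contour_smooth_um=3.0), times
    )
    return stack, masks, times, contours
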