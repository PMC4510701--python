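"""Time integration of gap closure: solve -> extend -> advect -> redistance.

Each step solves the quasi-static momentum balance on a mesh fitted to the
current interface, extends the interface velocity onto the regular
level-set grid (constant along normals), transports the level-set field
with an upwind scheme under a CFL-limited step, and rebuilds the signed
distance from the freshly extracted zero contour.  The loop runs until the
gap area falls below ``area_min`` (reported as closed), the time horizon
is reached, or a step fails (the trace then carries the last valid state).

Everything is deterministic: identical configurations reproduce traces
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from ._fem import FactorizedOperator
from .contours import Contour, gap_region
from .geometry import (
    GapClosedError,
    Grid,
    advect,
    extract_contours,
    reinitialize,
    signed_distance,
)
from .mechanics import ModelParams, TissueDomain, solve_velocity


@dataclass
class RunSchedule:
    """Time-stepping policy.

    ``dt = None`` selects CFL-adaptive stepping with ``cfl_safety``;
    a fixed ``dt`` is honoured as long as it passes the CFL check.
    ``area_min`` defaults to (2 h)^2: below that the interface is
    sub-resolution and the gap is reported closed.
    """

    t_end: float = np.inf
    dt: float | None = None
    cfl_safety: float = 0.5
    store_every: int = 1
    area_min: float | None = None
    max_steps: int = 5000

    def resolve_area_min(self, h: float) -> float:
        a = (2 * h) ** 2 if self.area_min is None else self.area_min
        return max(a, h**2)


@dataclass
class StepRecord:
    step: int
    t: float
    loops: list[Contour]
    points: np.ndarray  # interface mesh nodes
    v_n: np.ndarray  # normal speed at nodes, positive toward the gap
    kappa: np.ndarray
    normals: np.ndarray


@dataclass
class SimulationTrace:
    params: ModelParams
    schedule: RunSchedule
    grid: Grid
    times: list = dfield(default_factory=list)  # t at the START of each step
    areas: list = dfield(default_factory=list)  # gap area at the start of each step
    fluxes: list = dfield(default_factory=list)  # closure flux of that step
    dts: list = dfield(default_factory=list)
    max_speed: list = dfield(default_factory=list)
    stored: list = dfield(default_factory=list)  # StepRecords
    termination: str = "running"
    final_area: float = np.nan
    final_time: float = np.nan

    def area_series(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.append(np.asarray(self.times), self.final_time)
        A = np.append(np.asarray(self.areas), self.final_area)
        return t, A

    def area_budget_violations(self, rel: float = 0.01) -> np.ndarray:
        """Per-step defect |dA + dt * flux| - (rel*|dA| + h^2); <= 0 is good.

        ``flux`` is the interface integral of v_n (positive toward the
        gap), so the area should change by -dt*flux per step.  A final
        step in which the interface vanishes entirely is excluded: the
        model is defined only while the gap has area, so the flux does
        not cover that partial step.
        """
        t, A = self.area_series()
        dA = np.diff(A)
        dts = np.asarray(self.dts)
        flux = np.asarray(self.fluxes)
        h = self.grid.spacing
        out = np.abs(dA + dts * flux) - (rel * np.abs(dA) + h**2)
        if self.termination == "closed" and len(out) and self.final_area == 0.0:
            out = out[:-1]
        return out

    def stored_contours(self) -> list[tuple[float, Contour]]:
        return [(r.t, r.loops[0]) for r in self.stored if r.loops]

    def save_npz(self, path) -> None:
        """Versioned flat-array container (numpy .npz)."""
        payload = {
            "format_version": np.array([1]),
            "eta": self.params.eta,
            "c_f": self.params.c_f,
            "f_l": self.params.f_l,
            "gamma": self.params.gamma,
            "grid_origin": np.array(self.grid.origin),
            "grid_spacing": self.grid.spacing,
            "grid_shape": np.array(self.grid.shape),
            "times": np.asarray(self.times),
            "areas": np.asarray(self.areas),
            "fluxes": np.asarray(self.fluxes),
            "dts": np.asarray(self.dts),
            "termination": np.array(self.termination),
            "final": np.array([self.final_time, self.final_area]),
        }
        for r in self.stored:
            tag = f"s{r.step:06d}"
            payload[f"{tag}_t"] = r.t
            payload[f"{tag}_pts"] = r.points
            payload[f"{tag}_vn"] = r.v_n
            payload[f"{tag}_kappa"] = r.kappa
            for i, lp in enumerate(r.loops):
                payload[f"{tag}_loop{i}"] = lp.points
        np.savez_compressed(path, **payload)


def _setup_grid(initial: Contour, params: ModelParams, h: float,
                margin_lengths: float, outer: str):
    ell = params.screening_length
    margin = margin_lengths * ell if np.isfinite(ell) else margin_lengths * 10 * h
    if outer == "circle":
        c = initial.centroid
        R = np.max(np.linalg.norm(initial.points - c, axis=1)) + margin
        lo = (c[0] - R - 6 * h, c[1] - R - 6 * h)
        n = int(np.ceil(2 * (R + 6 * h) / h)) + 1
        grid = Grid((float(lo[0]), float(lo[1])), h, (n, n))
        outer_spec = {"circle": (float(c[0]), float(c[1]), float(R))}
    else:
        grid = Grid.around(initial, h, margin)
        outer_spec = None
    return grid, outer_spec


def run(
    initial: Contour,
    params: ModelParams,
    schedule: RunSchedule,
    h: float = 1.0,
    margin_lengths: float = 8.0,
    outer: str = "rect",
    store_velocity: bool = False,
) -> SimulationTrace:
    """Simulate gap closure from ``initial`` until closure or ``t_end``."""
    initial.validate()
    grid, outer_spec = _setup_grid(initial, params, h, margin_lengths, outer)
    field = signed_distance(initial.upsampled_smooth(h / 8), grid)
    schedule = schedule
    a_min = schedule.resolve_area_min(h)
    trace = SimulationTrace(params, schedule, grid)
    t = 0.0
    for step in range(schedule.max_steps):
        loops = extract_contours(field)
        if not loops:
            trace.termination = "closed"
            break
        area = gap_region(loops).area
        if area < a_min:
            trace.termination = "closed"
            break
        if t >= schedule.t_end:
            trace.termination = "t_end"
            break
        try:
            dom = TissueDomain(field=field, loops=loops, outer=outer_spec)
            sol = solve_velocity(dom, params)
        except Exception as exc:  # solver failure: keep last valid state
            trace.termination = f"solver_error: {exc}"
            break
        vmax = float(np.abs(sol.interface_velocity).max())
        if vmax < 1e-12:
            # static interface: idle to t_end, or report a non-closing run
            if not np.isfinite(schedule.t_end):
                trace.termination = "non-closing"
                trace.final_time, trace.final_area = t, area
                return trace
            dt = schedule.dt if schedule.dt is not None else schedule.t_end - t
            trace.times.append(t)
            trace.areas.append(area)
            trace.fluxes.append(0.0)
            trace.dts.append(dt)
            trace.max_speed.append(0.0)
            if step % schedule.store_every == 0:
                trace.stored.append(
                    StepRecord(
                        step, t, loops, sol.interface_points.copy(),
                        sol.normal_speed.copy(), sol.kappa.copy(),
                        sol.mesh.interface_normals.copy(),
                    )
                )
            t += dt
            continue
        dt_cfl = schedule.cfl_safety * h / vmax
        dt = min(schedule.dt or np.inf, dt_cfl, schedule.t_end - t)
        if schedule.dt is not None and schedule.dt > dt_cfl:
            trace.termination = (
                f"cfl_error: fixed dt={schedule.dt:g} exceeds admissible {dt_cfl:g}"
            )
            break
        vx, vy = sol.extend_to_grid(field)
        trace.times.append(t)
        trace.areas.append(area)
        trace.fluxes.append(sol.boundary_flux())
        trace.dts.append(dt)
        trace.max_speed.append(vmax)
        if step % schedule.store_every == 0:
            trace.stored.append(
                StepRecord(
                    step, t, loops, sol.interface_points.copy(),
                    sol.normal_speed.copy(), sol.kappa.copy(),
                    sol.mesh.interface_normals.copy(),
                )
            )
        field = advect(field, vx, vy, dt)
        t += dt
        try:
            field = reinitialize(field)
        except GapClosedError:  # interface vanished within the step
            trace.termination = "closed"
            trace.final_time, trace.final_area = t, 0.0
            return trace
    else:
        trace.termination = "max_steps"
    loops = extract_contours(field)
    trace.final_time = t
    trace.final_area = gap_region(loops).area if loops else 0.0
    if trace.termination == "running":  # loop exhausted by break conditions only
        trace.termination = "t_end"
    return trace


def instantaneous_decomposition(
    initial: Contour,
    params: ModelParams,
    h: float = 1.0,
    margin_lengths: float = 8.0,
    outer: str = "rect",
) -> dict:
    """Superposition check at fixed geometry: v_full = v_crawl + v_ps.

    The three load cases share one assembled and factorized operator, so
    the comparison isolates the linearity of the boundary data.
    """
    grid, outer_spec = _setup_grid(initial, params, h, margin_lengths, outer)
    field = signed_distance(initial.upsampled_smooth(h / 8), grid)
    loops = extract_contours(field)
    dom = TissueDomain(field=field, loops=loops, outer=outer_spec)
    full = solve_velocity(dom, params)
    op = FactorizedOperator(full.mesh, params.eta, params.c_f)
    crawl = solve_velocity(dom, params.with_(gamma=0.0), operator=op)
    ps = solve_velocity(dom, params.with_(f_l=0.0), operator=op)
    num = np.abs(full.v - crawl.v - ps.v).max()
    den = np.abs(full.v).max()
    return {
        "full": full,
        "crawl": crawl,
        "purse_string": ps,
        "superposition_residual": float(num / den) if den > 0 else 0.0,
    }


def run_decomposed(
    initial: Contour,
    params: ModelParams,
    schedule: RunSchedule,
    h: float = 1.0,
    **kw,
) -> dict:
    """Full, crawling-only and purse-string-only runs from one initial state."""
    out = {
        "t0": instantaneous_decomposition(initial, params, h=h,
                                          **{k: v for k, v in kw.items()
                                             if k in ("margin_lengths", "outer")}),
        "full": run(initial, params, schedule, h=h, **kw),
        "crawl": run(initial, params.with_(gamma=0.0), schedule, h=h, **kw),
        "purse_string": run(initial, params.with_(f_l=0.0), schedule, h=h, **kw),
    }
    return out
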