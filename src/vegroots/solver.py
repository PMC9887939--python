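"""Pseudo-spectral RK4 time stepping and steady-state detection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .model_core import GridSpec, ModelParams, SystemState, rhs
from .nonlocal_operators import KernelApprox

__all__ = ["SolverConfig", "Trajectory", "step", "integrate", "rk4_stability_limit"]


def rk4_stability_limit(params: ModelParams, grid: GridSpec) -> float:
    """Conservative dt bound from the stiffest linear decay rates: diffusion
    at the grid Nyquist wavenumber, evaporation, mortality, and water uptake
    at maximum biomass."""
    k2max = float(np.max(grid.k2()))
    uptake_max = params.Gam1 * params.K1 * params.root_mass(params.K1) + \
        params.Gam2 * params.K2 * (1.0 + params.E2 * params.K2) ** 2
    rate = max(params.DW * k2max, params.N, params.M1, params.M2, uptake_max)
    return 2.785 / rate


@dataclass
class SolverConfig:
    dt: float = 1e-3                 # y
    t_max: float = 100.0             # y
    steady_tol: float = 1e-9         # mean abs per-step change, kg/m^2
    snapshot_every: float = 1.0      # y
    seed: int = 0
    check_every: int = 200           # steps between steadiness checks
    sedge_local_dispersal: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_max <= 0 or self.steady_tol <= 0:
            raise ValueError("dt, t_max, steady_tol must be positive")


@dataclass
class Trajectory:
    times: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)      # SystemState copies
    mean_B1: list = field(default_factory=list)
    mean_B2: list = field(default_factory=list)
    mean_W: list = field(default_factory=list)
    termination: str = "horizon"                       # {steady, horizon, stopped}
    clipped_mass: float = 0.0                          # cumulative, kg
    steps: int = 0
    grid: Optional[GridSpec] = None
    params: Optional[ModelParams] = None

    @property
    def final(self) -> SystemState:
        return self.snapshots[-1]

    def _record(self, state: SystemState) -> None:
        self.times.append(state.T)
        self.snapshots.append(state.copy())
        self.mean_B1.append(float(state.B1.mean()))
        self.mean_B2.append(float(state.B2.mean()))
        self.mean_W.append(float(state.W.mean()))

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "mean_B1": self.mean_B1,
             "mean_B2": self.mean_B2, "mean_W": self.mean_W}
        )

    def to_dataset(self):
        """Snapshots as an xarray Dataset (x [, y], time), parameters as attrs."""
        import xarray as xr

        grid = self.grid
        dims = ("time", "x") if grid.is_1d else ("time", "y", "x")
        coords = {"time": np.asarray(self.times), "x": grid.axes()[0]}
        if not grid.is_1d:
            coords["y"] = grid.axes()[1]
        data = {
            name: (dims, np.stack([getattr(s, name) for s in self.snapshots]))
            for name in ("B1", "B2", "W")
        }
        attrs = {} if self.params is None else self.params.to_dict()
        attrs["termination"] = self.termination
        return xr.Dataset(data, coords=coords, attrs=attrs)

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    def to_csv(self, path) -> None:
        """1D fallback: final snapshot as delimited text."""
        grid = self.grid
        if grid is None or not grid.is_1d:
            raise ValueError("CSV export is the 1D fallback only")
        s = self.final
        pd.DataFrame({"x": grid.axes()[0], "B1": s.B1, "B2": s.B2, "W": s.W}).to_csv(
            path, index=False
        )


def step(state: SystemState, params: ModelParams, grid: GridSpec,
         approx: KernelApprox, dt: float, clip: bool = True,
         sedge_local_dispersal: bool = False):
    """One classical RK4 step.  Returns ``(new_state, clipped_mass)`` where
    the clipped mass is the total negative biomass/water (in kg) zeroed after
    the full step."""
    kw = {"sedge_local_dispersal": sedge_local_dispersal}

    def f(s: SystemState):
        return rhs(s, params, grid, approx, **kw)

    k1 = f(state)
    s2 = SystemState(state.B1 + 0.5 * dt * k1[0], state.B2 + 0.5 * dt * k1[1],
                     state.W + 0.5 * dt * k1[2], state.T + 0.5 * dt)
    k2 = f(s2)
    s3 = SystemState(state.B1 + 0.5 * dt * k2[0], state.B2 + 0.5 * dt * k2[1],
                     state.W + 0.5 * dt * k2[2], state.T + 0.5 * dt)
    k3 = f(s3)
    s4 = SystemState(state.B1 + dt * k3[0], state.B2 + dt * k3[1],
                     state.W + dt * k3[2], state.T + dt)
    k4 = f(s4)

    c = dt / 6.0
    new = SystemState(
        state.B1 + c * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
        state.B2 + c * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
        state.W + c * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
        state.T + dt,
    )
    clipped = 0.0
    if clip:
        for fld in (new.B1, new.B2, new.W):
            neg = fld < 0.0
            if neg.any():
                clipped -= float(fld[neg].sum()) * grid.cell_area
                fld[neg] = 0.0
    if not np.isfinite(new.B1.sum() + new.B2.sum() + new.W.sum()):
        raise FloatingPointError(f"non-finite state after step at T={new.T:.6g}")
    return new, clipped


def integrate(state: SystemState, params: ModelParams, grid: GridSpec,
              approx: KernelApprox, config: SolverConfig,
              stop_condition: Optional[Callable[[SystemState], bool]] = None) -> Trajectory:
    """Advance until ``t_max`` or until the mean absolute per-step change
    ``|dB1| + |dB2| + |dW|`` falls below ``steady_tol``.

    ``stop_condition(state)`` is evaluated at snapshot times and terminates
    the run early with ``termination == 'stopped'`` (used by the invasion
    pipeline for early outcome detection).
    """
    traj = Trajectory(grid=grid, params=params)
    current = state.copy()
    traj._record(current)

    dt = config.dt
    n_steps = int(np.ceil(config.t_max / dt))
    snap_stride = max(1, int(round(config.snapshot_every / dt)))
    check_stride = max(1, config.check_every)

    try:
        for i in range(1, n_steps + 1):
            check = i % check_stride == 0
            prev = current if not check else current.copy()
            current, clipped = step(
                current, params, grid, approx, dt,
                sedge_local_dispersal=config.sedge_local_dispersal,
            )
            traj.clipped_mass += clipped
            traj.steps += 1
            if i % snap_stride == 0 or i == n_steps:
                traj._record(current)
                if stop_condition is not None and stop_condition(current):
                    traj.termination = "stopped"
                    return traj
            if check:
                change = (
                    np.abs(current.B1 - prev.B1).mean()
                    + np.abs(current.B2 - prev.B2).mean()
                    + np.abs(current.W - prev.W).mean()
                )
                if change < config.steady_tol:
                    if traj.times[-1] != current.T:
                        traj._record(current)
                    traj.termination = "steady"
                    return traj
    except FloatingPointError as err:
        raise FloatingPointError(
            f"integration aborted (instability) at step {traj.steps}: {err}"
        ) from err

    if traj.times[-1] != current.T:
        traj._record(current)
    traj.termination = "horizon"
    return traj
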