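"""Parameter presets and synthetic initial conditions.

Every analysis in the package starts from a named parameter preset (plain
YAML shipped with the package) and a synthetic initial state built here with
an explicit seed, so all pipeline stages run without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .model_core import GridSpec, ModelParams, SystemState

__all__ = [
    "list_presets",
    "load_preset",
    "ic_uniform_plus_noise",
    "ic_spots",
    "ic_adjacent_patches",
    "Scenario",
    "SCENARIO_LIBRARY",
    "make_scenario",
]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _preset_dir():
    return resources.files("vegroots.presets")


def list_presets() -> list[str]:
    return sorted(p.name[:-5] for p in _preset_dir().iterdir() if p.name.endswith(".yaml"))


def _read_preset_raw(name: str) -> dict:
    path = _preset_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: {list_presets()}") from None
    raw = yaml.safe_load(text)
    base = raw.pop("base", None)
    values = {k: float(v["value"]) for k, v in raw.items()}
    if base is not None:
        merged = _read_preset_raw(base)
        merged.update(values)
        values = merged
    return values


def load_preset(name: str, **overrides) -> ModelParams:
    """Load a named preset, optionally overriding individual symbols.

    Presets validate against the :class:`ModelParams` invariants at load
    time (construction runs the validator).
    """
    values = _read_preset_raw(name)
    values.update({k: float(v) for k, v in overrides.items()})
    return ModelParams(**values)


# ---------------------------------------------------------------------------
# initial-condition generators
# ---------------------------------------------------------------------------

def ic_uniform_plus_noise(equilibrium, amplitude: float, seed: int,
                          grid: GridSpec) -> SystemState:
    """Uniform state plus independent uniform noise in [-amplitude, amplitude]
    on the biomass fields, clipped at zero.

    Noise is applied to biomass only: soil water relaxes quickly and the
    instabilities of interest are biomass-driven.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    rng = np.random.default_rng(seed)
    state = equilibrium.as_state(grid) if hasattr(equilibrium, "as_state") else equilibrium.copy()
    for fld in (state.B1, state.B2):
        fld += rng.uniform(-amplitude, amplitude, size=grid.shape)
        np.clip(fld, 0.0, None, out=fld)
    return state


def _periodic_r2(grid: GridSpec, center) -> np.ndarray:
    """Squared periodic distance to ``center`` on the grid."""
    if grid.is_1d:
        x = grid.axes()[0]
        dxs = np.abs(x - center[0] % grid.Lx)
        dxs = np.minimum(dxs, grid.Lx - dxs)
        return dxs ** 2
    x, y = grid.axes()
    dxs = np.abs(x[None, :] - center[0] % grid.Lx)
    dxs = np.minimum(dxs, grid.Lx - dxs)
    dys = np.abs(y[:, None] - center[1] % grid.Ly)
    dys = np.minimum(dys, grid.Ly - dys)
    return dxs ** 2 + dys ** 2


def ic_spots(background, centers, radius: float, peak: float,
             grid: GridSpec) -> SystemState:
    """Shrub (B1) Gaussian bumps added onto a uniform background state.

    Each bump has peak ``peak`` and footprint radius ``radius`` (Gaussian
    sigma = radius/2).  Out-of-domain centers wrap periodically; overlapping
    bumps simply sum.
    """
    if radius < 2 * grid.dx:
        raise ValueError("spot radius must be at least 2*dx")
    state = background.as_state(grid) if hasattr(background, "as_state") else background.copy()
    sigma = radius / 2.0
    for c in centers:
        c = (c, 0.0) if np.isscalar(c) else tuple(c)
        state.B1 += peak * np.exp(-_periodic_r2(grid, c) / (2.0 * sigma ** 2))
    return state


def ic_adjacent_patches(left, right, interface_width: float,
                        grid: GridSpec) -> SystemState:
    """Two uniform states blended across vertical interfaces (periodic domain,
    so the right state occupies the middle half of the x-axis).

    ``interface_width -> 0`` recovers a step profile; identical states give
    back the uniform state.
    """
    lv = np.array([left.B1, left.B2, left.W], dtype=float)
    rv = np.array([right.B1, right.B2, right.W], dtype=float)
    x = grid.axes()[0]
    w = max(interface_width, 1e-12)
    blend = 0.5 * (np.tanh((x - 0.25 * grid.Lx) / w) - np.tanh((x - 0.75 * grid.Lx) / w))
    if not grid.is_1d:
        blend = np.broadcast_to(blend[None, :], grid.shape).copy()
    fields = [lvi + (rvi - lvi) * blend for lvi, rvi in zip(lv, rv)]
    return SystemState(*fields)


# ---------------------------------------------------------------------------
# scenario library
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """Fully serializable recipe: preset + grid + generator id/args + seed.

    Rebuilding from the manifest is bit-identical because every stochastic
    ingredient is seeded.
    """

    name: str
    preset: str
    grid: dict                      # Lx, nx [, Ly, ny]
    generator: str                  # one of the ic_* generator ids
    args: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        """Returns ``(params, grid, state)``."""
        from . import stability_bifurcation as sb

        params = load_preset(self.preset, **self.overrides)
        grid = GridSpec(**self.grid)
        if self.generator == "uniform_plus_noise":
            eq = sb.find_branch(params, self.args["branch"])
            if eq is None:
                raise ValueError(f"branch {self.args['branch']} absent at these parameters")
            state = ic_uniform_plus_noise(eq, self.args["amplitude"], self.seed, grid)
        elif self.generator == "spots":
            eq = sb.find_branch(params, self.args.get("branch", "CU"))
            if eq is None:
                raise ValueError("background branch absent at these parameters")
            state = ic_spots(eq, self.args["centers"], self.args["radius"],
                             self.args["peak"], grid)
        elif self.generator == "adjacent_patches":
            left = sb.find_branch(params, self.args["left"])
            right = sb.find_branch(params, self.args["right"])
            if left is None or right is None:
                raise ValueError("patch branches absent at these parameters")
            state = ic_adjacent_patches(left, right, self.args["interface_width"], grid)
        else:
            raise ValueError(f"unknown generator {self.generator!r}")
        return params, grid, state

    def to_manifest(self) -> str:
        return json.dumps(
            {"name": self.name, "preset": self.preset, "grid": self.grid,
             "generator": self.generator, "args": self.args,
             "overrides": self.overrides, "seed": self.seed},
            sort_keys=True)

    @classmethod
    def from_manifest(cls, text: str) -> "Scenario":
        d = json.loads(text)
        return cls(**d)


def _four_spot_centers(Lx: float, Ly: float) -> list:
    """Quarter-point lattice: four spots with spacing Lx/2 in each direction.

    On a periodic domain this keeps every spot (and its images) at least
    Lx/2 apart; tighter placements put the whole domain within the root
    reach of some spot and the sedge is excluded at any precipitation.
    """
    return [[0.25 * Lx, 0.25 * Ly], [0.75 * Lx, 0.25 * Ly],
            [0.25 * Lx, 0.75 * Ly], [0.75 * Lx, 0.75 * Ly]]


def _cluster_centers(Lx: float, Ly: float) -> list:
    """Corners of a square of side 0.3*Lx centered in the domain."""
    cx, cy, h = Lx / 2.0, Ly / 2.0, 0.15 * Lx
    return [[cx - h, cy - h], [cx + h, cy - h], [cx - h, cy + h], [cx + h, cy + h]]


def _lib() -> dict:
    spot = {"radius": 1.0, "peak": 0.35, "branch": "CU"}  # peak = 0.5*K1
    return {
        # converged single shrub spot in a sedge grassland (2D, dry side)
        "single_spot": Scenario(
            name="single_spot", preset="low_altitude",
            grid={"Lx": 32.0, "nx": 128, "Ly": 32.0, "ny": 128},
            generator="spots", args={**spot, "centers": [[16.0, 16.0]]}),
        # noise-seeded periodic shrub pattern (2D, dry side)
        "noisy_pattern": Scenario(
            name="noisy_pattern", preset="low_altitude",
            grid={"Lx": 64.0, "nx": 256, "Ly": 64.0, "ny": 256},
            generator="uniform_plus_noise",
            args={"branch": "GU", "amplitude": 1e-3}, seed=7),
        # shrub-only next to sedge-only patches (high altitude, tristability)
        "adjacent_patches": Scenario(
            name="adjacent_patches", preset="high_altitude",
            grid={"Lx": 64.0, "nx": 256, "Ly": 32.0, "ny": 128},
            generator="adjacent_patches",
            args={"left": "GU", "right": "CU", "interface_width": 1.0}),
        # four-spot invasion, high water stress (incomplete expected)
        "four_spots_dry": Scenario(
            name="four_spots_dry", preset="low_altitude",
            grid={"Lx": 48.0, "nx": 192, "Ly": 48.0, "ny": 192},
            generator="spots",
            args={**spot, "centers": _four_spot_centers(48.0, 48.0)},
            overrides={"P": 1000.0}),
        # four-spot invasion, low water stress (complete expected); compact
        # central cluster so replication into the surrounding grassland has
        # room to occur
        "four_spots_wet": Scenario(
            name="four_spots_wet", preset="low_altitude",
            grid={"Lx": 48.0, "nx": 192, "Ly": 48.0, "ny": 192},
            generator="spots",
            args={**spot, "centers": _cluster_centers(48.0, 48.0)},
            overrides={"P": 1400.0}),
        # same four-spot start under the non-patterning control parameters
        "control_invasion": Scenario(
            name="control_invasion", preset="nonpatterning_control",
            grid={"Lx": 24.0, "nx": 96, "Ly": 24.0, "ny": 96},
            generator="spots",
            args={"radius": 1.0, "peak": 0.875, "branch": "CU",
                  "centers": _four_spot_centers(24.0, 24.0)}),
        # 1D single spot used for the invasion-threshold bisection
        "single_spot_1d": Scenario(
            name="single_spot_1d", preset="low_altitude",
            grid={"Lx": 128.0, "nx": 512},
            generator="spots", args={**spot, "centers": [64.0]}),
    }


SCENARIO_LIBRARY = sorted(_lib().keys())


def make_scenario(name: str, **replacements) -> Scenario:
    """Fetch a library scenario, optionally replacing top-level fields
    (e.g. ``grid={...}``, ``overrides={...}``, ``seed=...``)."""
    lib = _lib()
    if name not in lib:
        raise KeyError(f"unknown scenario {name!r}; available: {SCENARIO_LIBRARY}")
    sc = lib[name]
    for key, val in replacements.items():
        if not hasattr(sc, key):
            raise AttributeError(f"Scenario has no field {key!r}")
        setattr(sc, key, val)
    return sc
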