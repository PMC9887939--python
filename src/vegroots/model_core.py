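"""Core model: parameters, grids, fields, kernels, and the full right-hand side.

The model couples two plant species competing for soil water on a periodic
domain.  Species 1 (a clonal shrub) takes up water through laterally extended
roots whose reach grows with shoot biomass, which makes its growth and uptake
rates *nonlocal*; species 2 (a sedge) has confined roots and purely local
rates.  Both species recruit new shoots at a distance through a fat-tailed
(Cauchy) kernel.  Soil water obeys a balance of rainfall input, evaporation,
uptake, and lateral diffusion.

Units
-----
Biomass fields ``B1``, ``B2`` and soil water ``W`` are in kg/m^2, space in m,
time in years.  Precipitation ``P`` is given in mm/y; 1 mm of rainfall over
1 m^2 weighs 1 kg, so ``P`` enters the water balance unscaled as kg/m^2/y.

Kernel conventions
------------------
The root kernel of species 1 has a *fixed* normalising prefactor but a
biomass-dependent width ``S(B) = SG1*(1 + E1*B)``, so its integral over the
plane equals ``(1 + E1*B)**2`` rather than 1 — larger shoots reach more
water.  In 1D we keep that defining property (mass ``(1+E*B)**2``), so the
spatially-uniform reduction of the model is identical in 1D and 2D.  The
sucker/dispersal kernel is a radially symmetric Cauchy-type density with
unit mass in either dimension; its Fourier transform is ``exp(-SD*|k|)``
in both 1D and 2D.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy import fft as sfft

if TYPE_CHECKING:  # pragma: no cover
    from .nonlocal_operators import KernelApprox

__all__ = [
    "ModelParams",
    "GridSpec",
    "SystemState",
    "root_kernel_value",
    "sucker_kernel_value",
    "gaussian_kernel_ft",
    "cauchy_kernel_ft",
    "local_rates_sedge",
    "sucker_growth",
    "evaporation_rate",
    "rhs",
    "spectral_conv",
    "spectral_laplacian",
]


@dataclass
class ModelParams:
    """Model parameters; defaults are the standard (low-altitude) set.

    Suffix 1 refers to the nonlocal shrub, suffix 2 to the sedge.
    """

    P: float = 1000.0      # precipitation rate, mm/y (1 mm/y == 1 kg/m^2/y)
    E1: float = 16.0       # lateral root augmentation per unit biomass, m^2/kg
    E2: float = 5.0
    K1: float = 0.7        # maximum standing biomass, kg/m^2
    K2: float = 0.35
    M1: float = 7.05       # biomass decay rate, 1/y
    M2: float = 7.05
    N: float = 15.0        # bare-soil evaporation rate, 1/y
    Lam1: float = 0.06     # biomass growth per unit soil water, (1/mm)/y
    Lam2: float = 0.16
    Gam1: float = 15.0     # water uptake per unit biomass, (m^2/kg)/y
    Gam2: float = 5.0
    R1: float = 0.1        # evaporation reduction by shading, dimensionless
    R2: float = 0.1
    Th1: float = 3.125     # potential sucker growth / dispersal rate, 1/y
    Th2: float = 3.125
    DW: float = 0.5        # soil-water diffusion, m^2/y
    SG1: float = 0.5       # seedling lateral root size, m
    SD1: float = 0.5       # sucker-distribution width, m
    SD2: float = 0.01      # sedge dispersal range, m
    Wstar1: float = 0.5    # half-saturation soil water for sucker growth, kg/m^2
    Wstar2: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        strictly_positive = (
            "P K1 K2 M1 M2 N Lam1 Lam2 Gam1 Gam2 Th1 Th2 DW "
            "SG1 SD1 SD2 Wstar1 Wstar2"
        ).split()
        for name in strictly_positive:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {v}")
        for name in ("E1", "E2", "R1", "R2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be nonnegative, got {v}")
        # evaporation must stay positive for B_i <= K_i
        if self.R1 + self.R2 >= 1.0:
            raise ValueError("R1 + R2 must be < 1 so evaporation stays positive")

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in dc_fields(self)}

    # species-indexed accessors -------------------------------------------
    def species(self, i: int) -> dict:
        """Per-species parameter bundle (i in {1, 2})."""
        if i not in (1, 2):
            raise ValueError("species index must be 1 or 2")
        s = str(i)
        return {
            "E": getattr(self, "E" + s),
            "K": getattr(self, "K" + s),
            "M": getattr(self, "M" + s),
            "Lam": getattr(self, "Lam" + s),
            "Gam": getattr(self, "Gam" + s),
            "R": getattr(self, "R" + s),
            "Th": getattr(self, "Th" + s),
            "SD": getattr(self, "SD" + s),
            "Wstar": getattr(self, "Wstar" + s),
        }

    def root_width(self, B) -> np.ndarray | float:
        """Biomass-dependent lateral root-zone size of species 1."""
        return self.SG1 * (1.0 + self.E1 * np.asarray(B, dtype=float))

    def root_mass(self, B) -> np.ndarray | float:
        """Plane integral of the species-1 root kernel at biomass ``B``."""
        return (1.0 + self.E1 * np.asarray(B, dtype=float)) ** 2


@dataclass
class GridSpec:
    """Periodic computational grid; ``ny == 1`` selects 1D mode.

    2D fields are indexed ``[y, x]``; 1D fields have shape ``(nx,)``.
    """

    Lx: float
    nx: int
    Ly: float = 0.0
    ny: int = 1

    def __post_init__(self) -> None:
        if self.Lx <= 0 or self.nx < 2:
            raise ValueError("Lx must be positive and nx >= 2")
        if self.ny < 1:
            raise ValueError("ny must be >= 1")
        if self.ny > 1 and self.Ly <= 0:
            raise ValueError("2D grid requires Ly > 0")
        self._cache: dict = {}

    @property
    def is_1d(self) -> bool:
        return self.ny == 1

    @property
    def dx(self) -> float:
        return self.Lx / self.nx

    @property
    def dy(self) -> float:
        return self.Ly / self.ny if not self.is_1d else self.dx

    @property
    def shape(self) -> tuple:
        return (self.nx,) if self.is_1d else (self.ny, self.nx)

    @property
    def cell_area(self) -> float:
        return self.dx if self.is_1d else self.dx * self.dy

    @property
    def npoints(self) -> int:
        return self.nx * self.ny

    def axes(self) -> tuple:
        x = np.arange(self.nx) * self.dx
        if self.is_1d:
            return (x,)
        y = np.arange(self.ny) * self.dy
        return (x, y)

    def kmag(self) -> np.ndarray:
        """Magnitude of the wavevector on the rfft grid."""
        if "kmag" not in self._cache:
            kx = 2.0 * np.pi * sfft.rfftfreq(self.nx, self.dx)
            if self.is_1d:
                self._cache["kmag"] = kx
            else:
                ky = 2.0 * np.pi * sfft.fftfreq(self.ny, self.dy)
                self._cache["kmag"] = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
        return self._cache["kmag"]

    def k2(self) -> np.ndarray:
        if "k2" not in self._cache:
            self._cache["k2"] = self.kmag() ** 2
        return self._cache["k2"]

    def check_resolves(self, width: float) -> bool:
        """Whether ``dx`` resolves a kernel of the given width (dx <= width/2)."""
        return self.dx <= width / 2.0 + 1e-12

    def cauchy_ft(self, SD: float) -> np.ndarray:
        """Cached Fourier transform of the fat-tailed kernel on this grid."""
        key = ("cauchy", float(SD))
        if key not in self._cache:
            self._cache[key] = np.exp(-SD * self.kmag())
        return self._cache[key]


@dataclass
class SystemState:
    """Fields ``B1``, ``B2`` (biomass) and ``W`` (soil water) at time ``T``."""

    B1: np.ndarray
    B2: np.ndarray
    W: np.ndarray
    T: float = 0.0

    def __post_init__(self) -> None:
        self.B1 = np.asarray(self.B1, dtype=float)
        self.B2 = np.asarray(self.B2, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if not (self.B1.shape == self.B2.shape == self.W.shape):
            raise ValueError("B1, B2, W must share one shape")

    def copy(self) -> "SystemState":
        return SystemState(self.B1.copy(), self.B2.copy(), self.W.copy(), self.T)

    def validate(self) -> None:
        for name in ("B1", "B2", "W"):
            f = getattr(self, name)
            if not np.all(np.isfinite(f)):
                raise FloatingPointError(f"non-finite values in {name}")
            if np.any(f < 0):
                raise ValueError(f"negative values in {name}")

    @classmethod
    def uniform(cls, grid: GridSpec, B1: float, B2: float, W: float,
                T: float = 0.0) -> "SystemState":
        return cls(
            np.full(grid.shape, float(B1)),
            np.full(grid.shape, float(B2)),
            np.full(grid.shape, float(W)),
            T,
        )


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def root_kernel_value(r, B, params: ModelParams, dim: int = 2):
    """Root-kernel density of species 1 at distance ``r`` from a shoot of
    biomass ``B``.

    The prefactor is fixed at the seedling width ``SG1`` while the Gaussian
    width is ``S(B) = SG1*(1 + E1*B)``, so the kernel's integral over the
    plane (2D) or line (1D) is ``(1 + E1*B)**2``.
    """
    r = np.asarray(r, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(r < 0) or np.any(B < 0):
        raise ValueError("r and B must be nonnegative")
    S = params.root_width(B)
    g = np.exp(-(r ** 2) / (2.0 * S ** 2))
    if dim == 2:
        return g / (2.0 * np.pi * params.SG1 ** 2)
    if dim == 1:
        # mass (1+E*B)^2 on the line
        return params.root_mass(B) * g / (np.sqrt(2.0 * np.pi) * S)
    raise ValueError("dim must be 1 or 2")


def sucker_kernel_value(r, SD: float, dim: int = 2):
    """Fat-tailed (Cauchy-type) sucker/dispersal kernel; unit mass.

    2D: ``SD / (2*pi*(r^2+SD^2)^(3/2))``; 1D: ``SD / (pi*(r^2+SD^2))``.
    Both transforms are ``exp(-SD*|k|)``.
    """
    r = np.asarray(r, dtype=float)
    if SD <= 0:
        raise ValueError("SD must be positive")
    if np.any(r < 0):
        raise ValueError("r must be nonnegative")
    if dim == 2:
        return SD / (2.0 * np.pi * (r ** 2 + SD ** 2) ** 1.5)
    if dim == 1:
        return SD / (np.pi * (r ** 2 + SD ** 2))
    raise ValueError("dim must be 1 or 2")


def gaussian_kernel_ft(k, S, mass=1.0):
    """Fourier transform of an isotropic Gaussian kernel of width ``S`` and
    total mass ``mass`` (identical expression in 1D and 2D)."""
    k = np.asarray(k, dtype=float)
    return mass * np.exp(-0.5 * (np.asarray(S, dtype=float) ** 2) * k ** 2)


def cauchy_kernel_ft(k, SD: float):
    """Fourier transform of the unit-mass fat-tailed kernel: ``exp(-SD*|k|)``."""
    return np.exp(-SD * np.abs(np.asarray(k, dtype=float)))


# ---------------------------------------------------------------------------
# spectral helpers
# ---------------------------------------------------------------------------

def _rfft(f: np.ndarray, grid: GridSpec) -> np.ndarray:
    return sfft.rfft(f) if grid.is_1d else sfft.rfft2(f)


def _irfft(fh: np.ndarray, grid: GridSpec) -> np.ndarray:
    if grid.is_1d:
        return sfft.irfft(fh, n=grid.nx)
    return sfft.irfft2(fh, s=grid.shape)


def spectral_conv(f: np.ndarray, kernel_ft: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Periodic convolution of ``f`` with a kernel given by its continuous
    Fourier transform sampled on the grid wavenumbers."""
    return _irfft(_rfft(f, grid) * kernel_ft, grid)


def spectral_laplacian(f: np.ndarray, grid: GridSpec) -> np.ndarray:
    return _irfft(-grid.k2() * _rfft(f, grid), grid)


# ---------------------------------------------------------------------------
# pointwise / nonlocal model terms
# ---------------------------------------------------------------------------

def local_rates_sedge(B2: np.ndarray, W: np.ndarray, params: ModelParams):
    """Local growth and uptake rates of the sedge (confined-root limit).

    Returns ``(growth, uptake)`` with ``growth = Lam2*W*(1+E2*B2)**2`` and
    ``uptake = Gam2*B2*(1+E2*B2)**2``; the uptake enters the water balance
    multiplied by ``W``.
    """
    B2 = np.asarray(B2, dtype=float)
    W = np.asarray(W, dtype=float)
    if B2.shape != W.shape:
        raise ValueError("B2 and W must share one shape")
    aug = (1.0 + params.E2 * B2) ** 2
    return params.Lam2 * W * aug, params.Gam2 * B2 * aug


def sucker_growth(Bi: np.ndarray, W: np.ndarray, species: int,
                  params: ModelParams, grid: GridSpec) -> np.ndarray:
    """Nonlocal recruitment rate: ``Th_i * W/(W+Wstar_i) * (Phi_i (*) B_i)``.

    ``Phi_i`` is the unit-mass fat-tailed kernel of width ``SD_i``; the
    convolution is periodic.  Strictly positive wherever ``W > 0`` provided
    ``B_i`` is positive anywhere.
    """
    if np.any(np.asarray(W) < 0):
        raise ValueError("W must be nonnegative")
    sp = params.species(species)
    conv = spectral_conv(np.asarray(Bi, dtype=float), grid.cauchy_ft(sp["SD"]), grid)
    return sp["Th"] * W / (W + sp["Wstar"]) * conv


def evaporation_rate(B1: np.ndarray, B2: np.ndarray, params: ModelParams):
    """Shading-reduced evaporation rate ``L = N*(1 - R1*B1/K1 - R2*B2/K2)``."""
    return params.N * (
        1.0
        - params.R1 * np.asarray(B1, dtype=float) / params.K1
        - params.R2 * np.asarray(B2, dtype=float) / params.K2
    )


def rhs(state: SystemState, params: ModelParams, grid: GridSpec,
        approx: "KernelApprox", sedge_local_dispersal: bool = False):
    """Full time derivative ``(dB1, dB2, dW)`` of the model.

    ``approx`` supplies the fixed-width convolution approximation of the
    biomass-dependent root kernel (see :mod:`vegroots.nonlocal_operators`).
    If ``sedge_local_dispersal`` is set, the sedge recruitment term uses
    the local limit ``Th2*W/(W+Wstar2)*B2`` instead of its (very narrow)
    dispersal kernel; uniform equilibria are unaffected.
    """
    B1, B2, W = state.B1, state.B2, state.W
    J = approx.J

    # one batched forward transform: W, B1, B2, and the J uptake sources
    w = approx.weights(B1)
    stack = np.concatenate([W[None], B1[None], B2[None], w * B1[None]], axis=0)
    if grid.is_1d:
        Fh = sfft.rfft(stack, axis=-1)
    else:
        Fh = sfft.rfftn(stack, axes=(-2, -1))
    What, B1h, B2h, srcs = Fh[0], Fh[1], Fh[2], Fh[3:]

    # one batched inverse: J growth convolutions, uptake, two recruitment
    # kernels, and the Laplacian
    uptake_hat = np.einsum("j...,j...->...", approx.ghat, srcs)
    inv = np.concatenate([
        approx.ghat * What[None],
        uptake_hat[None],
        (grid.cauchy_ft(params.SD1) * B1h)[None],
        (grid.cauchy_ft(params.SD2) * B2h)[None],
        (-grid.k2() * What)[None],
    ], axis=0)
    if grid.is_1d:
        R = sfft.irfft(inv, n=grid.nx, axis=-1)
    else:
        R = sfft.irfftn(inv, s=grid.shape, axes=(-2, -1))

    growth1 = params.Lam1 * np.einsum("j...,j...->...", w, R[:J])
    uptake1 = params.Gam1 * R[J]
    growth2, uptake2 = local_rates_sedge(B2, W, params)

    d1 = params.Th1 * W / (W + params.Wstar1) * R[J + 1]
    if sedge_local_dispersal:
        d2 = params.Th2 * W / (W + params.Wstar2) * B2
    else:
        d2 = params.Th2 * W / (W + params.Wstar2) * R[J + 2]

    dB1 = growth1 * B1 * (1.0 - B1 / params.K1) - params.M1 * B1 + d1
    dB2 = growth2 * B2 * (1.0 - B2 / params.K2) - params.M2 * B2 + d2

    L = evaporation_rate(B1, B2, params)
    dW = params.P - L * W - W * (uptake1 + uptake2) + params.DW * R[J + 3]

    total = float(dB1.sum() + dB2.sum() + dW.sum())
    if not np.isfinite(total):
        for name, term in (
            ("nonlocal growth (species 1)", growth1),
            ("nonlocal uptake (species 1)", uptake1),
            ("local growth (species 2)", growth2),
            ("local uptake (species 2)", uptake2),
            ("sucker growth (species 1)", d1),
            ("dispersal growth (species 2)", d2),
            ("evaporation", L),
            ("dB1", dB1),
            ("dB2", dB2),
            ("dW", dW),
        ):
            if not np.all(np.isfinite(term)):
                raise FloatingPointError(f"non-finite values in term: {name}")
        raise FloatingPointError("non-finite values in rhs")  # pragma: no cover
    return dB1, dB2, dW
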