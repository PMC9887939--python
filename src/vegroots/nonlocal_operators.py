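"""Biomass-dependent nonlocal growth and uptake via fixed-width convolutions.

The root kernel of species 1 has a width that depends on the local biomass,
so the growth and uptake integrals are not convolutions.  They are
approximated as linear combinations of ``J`` fixed-width Gaussian
convolutions, with biomass-dependent weights chosen so that the kernel-mass
identity ``sum_j w_j(B) * mass_j == (1 + E1*B)**2`` holds exactly for every
``B`` in ``[0, K1]``.  A direct double-sum quadrature oracle is provided for
testing on small grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    GridSpec,
    ModelParams,
    gaussian_kernel_ft,
    _irfft,
    _rfft,
)

__all__ = [
    "KernelApprox",
    "build_kernel_approx",
    "nonlocal_growth",
    "nonlocal_uptake",
    "brute_force_growth",
    "brute_force_uptake",
]

_BRUTE_FORCE_MAX = 96 * 96


@dataclass
class KernelApprox:
    """Fixed-width approximation of the biomass-dependent root kernel.

    ``nodes``  -- J biomass nodes, uniform on [0, K1]
    ``widths`` -- kernel widths SG1*(1 + E1*node)
    ``masses`` -- kernel masses (1 + E1*node)**2
    ``ghat``   -- (J, *kshape) Fourier transforms of the node kernels,
                  mass included
    """

    nodes: np.ndarray
    widths: np.ndarray
    masses: np.ndarray
    ghat: np.ndarray
    grid: GridSpec
    E1: float
    K1: float

    @property
    def J(self) -> int:
        return len(self.nodes)

    def weights(self, B: np.ndarray) -> np.ndarray:
        """Weight fields ``w_j(B)``, shape ``(J, *B.shape)``.

        Piecewise-linear hat interpolation between bracketing nodes,
        rescaled so that ``sum_j w_j(B)*mass_j == (1 + E1*B)**2`` pointwise.
        Biomass outside [0, K1] is clamped for width selection.
        """
        B = np.clip(np.asarray(B, dtype=float), 0.0, self.K1)
        dB = self.nodes[1] - self.nodes[0]
        pos = B / dB
        # clip (not just min) so non-finite biomass degrades to NaN weights
        # instead of wild indices; the rhs finiteness check then reports it
        j0 = np.clip(pos.astype(np.intp), 0, self.J - 2)
        frac = pos - j0
        lo = 1.0 - frac
        interp_mass = self.masses[j0] * lo + self.masses[j0 + 1] * frac
        scale = (1.0 + self.E1 * B) ** 2 / interp_mass
        w = np.zeros((self.J,) + B.shape)
        np.put_along_axis(w, j0[None, ...], (lo * scale)[None, ...], axis=0)
        np.put_along_axis(w, (j0 + 1)[None, ...], (frac * scale)[None, ...], axis=0)
        return w

    def dump_table(self, n: int = 101) -> str:
        """Delimited-text table of weights over biomass, for inspection."""
        bs = np.linspace(0.0, self.K1, n)
        w = self.weights(bs)
        header = "B\t" + "\t".join(f"w{j}" for j in range(self.J))
        lines = [header]
        for i, b in enumerate(bs):
            lines.append("\t".join([f"{b:.6g}"] + [f"{w[j, i]:.6g}" for j in range(self.J)]))
        return "\n".join(lines)


def build_kernel_approx(params: ModelParams, grid: GridSpec, J: int = 5,
                        allow_coarse: bool = False) -> KernelApprox:
    """Place ``J`` width nodes uniformly in biomass over ``[0, K1]`` and
    precompute the node-kernel transforms on the grid.

    ``allow_coarse`` skips the dx <= SG1/2 resolution check (used by
    scaled-down qualitative runs where dx ~ SG1; the seedling kernel's
    spectral truncation at the Nyquist wavenumber is still below 1% there).
    """
    if J < 2:
        raise ValueError("J must be >= 2")
    if not allow_coarse and not grid.check_resolves(params.SG1) \
            and params.SG1 > grid.dx / 2.0:
        # widths far below dx act as delta kernels in the spectral
        # representation (the confined-root limit) and are allowed;
        # partially-resolved widths are a configuration error
        raise ValueError(
            f"grid too coarse for root kernel: dx={grid.dx:.4g} > SG1/2={params.SG1 / 2:.4g}"
        )
    nodes = np.linspace(0.0, params.K1, J)
    widths = params.root_width(nodes)
    masses = params.root_mass(nodes)
    kmag = grid.kmag()
    ghat = np.stack([gaussian_kernel_ft(kmag, S, mass=m) for S, m in zip(widths, masses)])
    return KernelApprox(nodes=nodes, widths=widths, masses=masses, ghat=ghat,
                        grid=grid, E1=params.E1, K1=params.K1)


def nonlocal_growth(W: np.ndarray, B1: np.ndarray, approx: KernelApprox,
                    params: ModelParams, weights: np.ndarray | None = None,
                    What: np.ndarray | None = None) -> np.ndarray:
    """Growth rate ``Lam1 * sum_j w_j(B1(X)) * (G_j (*) W)(X)``.

    The kernel width is taken at the *shoot* location ``X``.  ``weights``
    and ``What`` (precomputed ``approx.weights(B1)`` and ``rfft(W)``) may be
    passed to share work across operators within one rhs evaluation.
    """
    grid = approx.grid
    w = approx.weights(B1) if weights is None else weights
    if What is None:
        What = _rfft(np.asarray(W, dtype=float), grid)
    out = np.zeros(grid.shape)
    for j in range(approx.J):
        wj = w[j]
        if not wj.any():
            continue
        out += wj * _irfft(approx.ghat[j] * What, grid)
    return params.Lam1 * out


def nonlocal_uptake(B1: np.ndarray, approx: KernelApprox,
                    params: ModelParams,
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Uptake rate ``Gam1 * sum_j (G_j (*) [w_j(B1)*B1])(X)``.

    The kernel width is taken at the *plant* location ``X'`` (transposed
    kernel arguments relative to the growth integral), which is what makes
    large plants deplete water far beyond their canopy.
    """
    grid = approx.grid
    B1 = np.asarray(B1, dtype=float)
    w = approx.weights(B1) if weights is None else weights
    acc = np.zeros(approx.ghat[0].shape, dtype=complex)
    for j in range(approx.J):
        src = w[j] * B1
        if not src.any():
            continue
        acc += approx.ghat[j] * _rfft(src, grid)
    return params.Gam1 * _irfft(acc, grid)


# ---------------------------------------------------------------------------
# brute-force quadrature oracle (tests only)
# ---------------------------------------------------------------------------

def _pairwise_kernel_matrix(B1: np.ndarray, params: ModelParams,
                            grid: GridSpec) -> np.ndarray:
    """Dense matrix ``G[a, b] = K(|x_a - x_b|; S(B1[x_a]))`` with periodic
    images summed over the 3 (1D) or 9 (2D) nearest copies."""
    n = grid.npoints
    if n > _BRUTE_FORCE_MAX:
        raise ValueError(
            f"brute-force oracle refused: {n} points > {_BRUTE_FORCE_MAX} (guard against O(n^4) runs)"
        )
    if grid.is_1d:
        x = grid.axes()[0]
        coords = x[:, None]
        lengths = np.array([grid.Lx])
    else:
        x, y = grid.axes()
        X, Y = np.meshgrid(x, y)
        coords = np.column_stack([X.ravel(), Y.ravel()])
        lengths = np.array([grid.Lx, grid.Ly])

    S = params.root_width(np.asarray(B1, dtype=float).ravel())  # width per shoot row
    two_S2 = 2.0 * S[:, None] ** 2
    dim = coords.shape[1]

    shifts = [np.array(s) for s in np.ndindex(*([3] * dim))]
    G = np.zeros((n, n))
    d = coords[:, None, :] - coords[None, :, :]
    for sh in shifts:
        off = (sh - 1) * lengths
        r2 = ((d + off) ** 2).sum(axis=2)
        G += np.exp(-r2 / two_S2)
    if dim == 2:
        G /= 2.0 * np.pi * params.SG1 ** 2
    else:
        mass = params.root_mass(np.asarray(B1, dtype=float).ravel())
        G *= (mass / (np.sqrt(2.0 * np.pi) * S))[:, None]
    return G


def brute_force_growth(W: np.ndarray, B1: np.ndarray, params: ModelParams,
                       grid: GridSpec) -> np.ndarray:
    """Direct quadrature of the growth integral (kernel width at the shoot)."""
    G = _pairwise_kernel_matrix(B1, params, grid)
    out = params.Lam1 * (G @ np.asarray(W, dtype=float).ravel()) * grid.cell_area
    return out.reshape(grid.shape)


def brute_force_uptake(B1: np.ndarray, params: ModelParams,
                       grid: GridSpec) -> np.ndarray:
    """Direct quadrature of the uptake integral (kernel width at the plant)."""
    G = _pairwise_kernel_matrix(B1, params, grid)
    out = params.Gam1 * (G.T @ np.asarray(B1, dtype=float).ravel()) * grid.cell_area
    return out.reshape(grid.shape)
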