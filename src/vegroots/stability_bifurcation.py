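"""Uniform equilibria, linear stability, dispersion relations, and
uniform-branch bifurcation scans.

Spatially uniform stationary states solve (after dividing the biomass
equations by ``B_i``, using kernel masses ``(1+E_i*B_i)**2`` and unit sucker
mass)::

    0 = Lam_i*W*(1+E_i*B_i)**2 * (1 - B_i/K_i) - M_i + Th_i*W/(W+Wstar_i)
    0 = P - L(B1,B2)*W - W * sum_i Gam_i*B_i*(1+E_i*B_i)**2

Four branches are tracked: bare soil (BS), shrub-only (GU), sedge-only (CU),
and mixed (MU).  Perturbations ``(b1, b2, w)*exp(i*k*x)`` about a uniform
state evolve under an exact 3x3 linear operator whose kernel terms enter
through their Fourier transforms; the biomass dependence of the root-kernel
width contributes extra derivative terms, which are implemented in closed
form here and cross-checked in the test suite against directional finite
differences of the discretized right-hand side.  The expressions are
identical in 1D and 2D (``k`` is the radial wavenumber).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import GridSpec, ModelParams, SystemState, rhs

__all__ = [
    "UniformEquilibrium",
    "DispersionCurve",
    "TuringPoint",
    "BifurcationDiagram",
    "uniform_equilibria",
    "find_branch",
    "linear_matrix",
    "dispersion_relation",
    "dispersion_matrix_fd",
    "turing_threshold",
    "scan_branches",
    "bs_growth_eigenvalue",
    "default_k_grid",
]

BRANCHES = ("BS", "GU", "CU", "MU")
_KMIN = 0.05  # 1/m; excludes the uniform mode when maximising over k


@dataclass
class UniformEquilibrium:
    B1: float
    B2: float
    W: float
    label: str
    stable_uniform: bool = False
    stable_nonuniform: bool = False
    residual: float = np.nan

    def as_state(self, grid: GridSpec, T: float = 0.0) -> SystemState:
        return SystemState.uniform(grid, self.B1, self.B2, self.W, T)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.B1, self.B2, self.W])


@dataclass
class DispersionCurve:
    k: np.ndarray
    sigma: np.ndarray       # (len(k), 3) complex eigenvalues
    lam: np.ndarray         # max real part per k

    def max_growth(self, k_min: float = _KMIN):
        sel = self.k >= k_min
        i = int(np.argmax(self.lam[sel]))
        return float(self.k[sel][i]), float(self.lam[sel][i])


@dataclass
class TuringPoint:
    P_c: float
    k_c: float
    branch: str
    lam_at_kc: float
    dlam_dk: float
    d2lam_dk2: float


@dataclass
class BifurcationDiagram:
    table: pd.DataFrame     # columns: P, branch, B1, B2, W, stable_uniform, stable_nonuniform

    def branch(self, label: str) -> pd.DataFrame:
        return self.table[self.table.branch == label].sort_values("P").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# uniform algebra
# ---------------------------------------------------------------------------

def _uniform_residual(v: np.ndarray, params: ModelParams) -> np.ndarray:
    """Residual of the full 3-variable uniform system (biomass equations NOT
    divided by B_i, so it is valid at B_i = 0)."""
    B1, B2, W = v
    m1 = (1.0 + params.E1 * B1) ** 2
    m2 = (1.0 + params.E2 * B2) ** 2
    L = params.N * (1.0 - params.R1 * B1 / params.K1 - params.R2 * B2 / params.K2)
    f1 = (params.Lam1 * W * m1 * (1.0 - B1 / params.K1) - params.M1) * B1 \
        + params.Th1 * W / (W + params.Wstar1) * B1
    f2 = (params.Lam2 * W * m2 * (1.0 - B2 / params.K2) - params.M2) * B2 \
        + params.Th2 * W / (W + params.Wstar2) * B2
    f3 = params.P - L * W - W * (params.Gam1 * B1 * m1 + params.Gam2 * B2 * m2)
    return np.array([f1, f2, f3])


def _solve_branch(params: ModelParams, label: str,
                  start: Optional[np.ndarray] = None) -> list[np.ndarray]:
    """Root-find one branch; returns all distinct (B1, B2, W) roots found
    (a branch may carry several coexisting roots near folds)."""
    Wbs = params.P / params.N

    if label == "BS":
        return [np.array([0.0, 0.0, Wbs])]

    def reduced(u):
        if label == "GU":
            B1, W = u
            B2 = 0.0
        elif label == "CU":
            B2, W = u
            B1 = 0.0
        else:  # MU
            B1, B2, W = u
        m1 = (1.0 + params.E1 * B1) ** 2
        m2 = (1.0 + params.E2 * B2) ** 2
        L = params.N * (1.0 - params.R1 * B1 / params.K1 - params.R2 * B2 / params.K2)
        g1 = params.Lam1 * W * m1 * (1.0 - B1 / params.K1) - params.M1 \
            + params.Th1 * W / (W + params.Wstar1)
        g2 = params.Lam2 * W * m2 * (1.0 - B2 / params.K2) - params.M2 \
            + params.Th2 * W / (W + params.Wstar2)
        g3 = params.P - L * W - W * (params.Gam1 * B1 * m1 + params.Gam2 * B2 * m2)
        if label == "GU":
            return [g1, g3]
        if label == "CU":
            return [g2, g3]
        return [g1, g2, g3]

    K = params.K1 if label in ("GU", "MU") else params.K2
    if start is not None:
        starts = [np.asarray(start, dtype=float)]
    else:
        # fixed 8-point lattice per branch: biomass fractions x water fractions
        bfrac = np.array([0.15, 0.45, 0.7, 0.95])
        wfrac = np.array([0.05, 0.5])
        starts = []
        for wf in wfrac:
            for bf in bfrac:
                if label == "MU":
                    starts.append(np.array([bf * params.K1, bf * params.K2, wf * Wbs]))
                else:
                    starts.append(np.array([bf * K, wf * Wbs]))

    roots: list[np.ndarray] = []
    for s0 in starts:
        sol = optimize.root(reduced, s0, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        u = sol.x
        if label == "GU":
            v = np.array([u[0], 0.0, u[1]])
        elif label == "CU":
            v = np.array([0.0, u[0], u[1]])
        else:
            v = u.copy()
        # reject nonphysical or degenerate (zero-biomass) roots
        if v[2] <= 0 or np.any(v < -1e-12):
            continue
        active = {"GU": [0], "CU": [1], "MU": [0, 1]}[label]
        if any(v[i] < 1e-6 for i in active):
            continue
        if float(np.max(np.abs(_uniform_residual(v, params)))) > 1e-8:
            continue
        if any(np.all(np.abs(v - r) < 1e-8) for r in roots):
            continue
        roots.append(v)
    return roots


def default_k_grid(k_max: float = 8.0, n: int = 481) -> np.ndarray:
    return np.linspace(0.0, k_max, n)


def linear_matrix(eq, params: ModelParams, k: float) -> np.ndarray:
    """Exact 3x3 linear operator on Fourier-mode perturbations at wavenumber
    ``k`` about a uniform state ``eq`` (any object with B1, B2, W)."""
    B1, B2, W = float(eq.B1), float(eq.B2), float(eq.W)
    p = params
    k = float(k)

    a1 = 1.0 + p.E1 * B1
    m1, dm1 = a1 ** 2, 2.0 * p.E1 * a1
    S1 = p.SG1 * a1
    gauss1 = m1 * np.exp(-0.5 * S1 ** 2 * k ** 2)
    phi1 = np.exp(-p.SD1 * k)
    phi2 = np.exp(-p.SD2 * k)
    # d/dB [B * m(B) * exp(-S(B)^2 k^2 / 2)] -- uptake-kernel column
    q1 = np.exp(-0.5 * S1 ** 2 * k ** 2) * (
        m1 + B1 * dm1 - B1 * m1 * k ** 2 * S1 * p.SG1 * p.E1
    )
    a2 = 1.0 + p.E2 * B2
    m2, dm2 = a2 ** 2, 2.0 * p.E2 * a2
    q2 = m2 + B2 * dm2

    L = p.N * (1.0 - p.R1 * B1 / p.K1 - p.R2 * B2 / p.K2)

    M = np.zeros((3, 3))
    M[0, 0] = (
        p.Lam1 * W * (dm1 * B1 * (1.0 - B1 / p.K1) + m1 * (1.0 - 2.0 * B1 / p.K1))
        - p.M1
        + p.Th1 * W / (W + p.Wstar1) * phi1
    )
    M[0, 2] = (
        p.Lam1 * gauss1 * B1 * (1.0 - B1 / p.K1)
        + p.Th1 * B1 * p.Wstar1 / (W + p.Wstar1) ** 2
    )
    M[1, 1] = (
        p.Lam2 * W * (dm2 * B2 * (1.0 - B2 / p.K2) + m2 * (1.0 - 2.0 * B2 / p.K2))
        - p.M2
        + p.Th2 * W / (W + p.Wstar2) * phi2
    )
    M[1, 2] = (
        p.Lam2 * m2 * B2 * (1.0 - B2 / p.K2)
        + p.Th2 * B2 * p.Wstar2 / (W + p.Wstar2) ** 2
    )
    M[2, 0] = p.N * p.R1 / p.K1 * W - p.Gam1 * W * q1
    M[2, 1] = p.N * p.R2 / p.K2 * W - p.Gam2 * W * q2
    M[2, 2] = -L - p.Gam1 * B1 * m1 - p.Gam2 * B2 * m2 - p.DW * k ** 2
    return M


def bs_growth_eigenvalue(params: ModelParams, species: int, k: float = 0.0) -> float:
    """Closed-form growth rate of species ``i`` perturbations about bare
    soil: ``Lam_i*Wbs - M_i + Th_i*Wbs/(Wbs+Wstar_i)*exp(-SD_i*k)``."""
    sp = params.species(species)
    Wbs = params.P / params.N
    return sp["Lam"] * Wbs - sp["M"] + sp["Th"] * Wbs / (Wbs + sp["Wstar"]) * np.exp(-sp["SD"] * k)


def _stability_flags(v: np.ndarray, params: ModelParams,
                     k_grid: Optional[np.ndarray] = None):
    eq = UniformEquilibrium(*v, label="")
    lam0 = np.max(np.real(np.linalg.eigvals(linear_matrix(eq, params, 0.0))))
    if k_grid is None:
        k_grid = default_k_grid()
    lam_k = np.array([
        np.max(np.real(np.linalg.eigvals(linear_matrix(eq, params, k))))
        for k in k_grid[k_grid >= _KMIN]
    ])
    return lam0 < 0.0, float(np.max(lam_k)) < 0.0


def uniform_equilibria(params: ModelParams,
                       k_grid: Optional[np.ndarray] = None,
                       with_stability: bool = True) -> list[UniformEquilibrium]:
    """All uniform stationary states present at the given parameters.

    BS is returned analytically; GU/CU from 2-variable and MU from
    3-variable root finding over a fixed lattice of starts.  Residuals of
    every reported state are below 1e-10; duplicates merged at 1e-8.
    """
    out: list[UniformEquilibrium] = []
    seen: list[np.ndarray] = []
    for label in BRANCHES:
        for v in _solve_branch(params, label):
            if any(np.all(np.abs(v - s) < 1e-8) for s in seen):
                continue
            seen.append(v)
            res = float(np.max(np.abs(_uniform_residual(v, params))))
            su, sn = _stability_flags(v, params, k_grid) if with_stability else (False, False)
            out.append(UniformEquilibrium(*v, label=label, stable_uniform=su,
                                          stable_nonuniform=sn, residual=res))
    return out


def find_branch(params: ModelParams, label: str,
                start: Optional[np.ndarray] = None,
                with_stability: bool = False,
                k_grid: Optional[np.ndarray] = None) -> Optional[UniformEquilibrium]:
    """Locate a single named branch.

    When several roots coexist on a branch, the one nearest the warm start
    is returned, or, without a start, the root with the largest total
    biomass (the upper, ecologically relevant branch).
    """
    roots = _solve_branch(params, label, start=start)
    if not roots:
        return None
    if start is not None and len(roots) > 1:
        tgt = np.asarray(start, dtype=float)
        proj = {"GU": [0, 2], "CU": [1, 2]}.get(label, [0, 1, 2])
        v = min(roots, key=lambda r: float(np.sum((r[proj] - tgt) ** 2)))
    else:
        v = max(roots, key=lambda r: r[0] + r[1])
    res = float(np.max(np.abs(_uniform_residual(v, params))))
    su, sn = _stability_flags(v, params, k_grid) if with_stability else (False, False)
    return UniformEquilibrium(*v, label=label, stable_uniform=su,
                              stable_nonuniform=sn, residual=res)


# ---------------------------------------------------------------------------
# dispersion relation
# ---------------------------------------------------------------------------

def dispersion_relation(eq: UniformEquilibrium, params: ModelParams,
                        k_grid: Optional[np.ndarray] = None) -> DispersionCurve:
    if k_grid is None:
        k_grid = default_k_grid()
    sigma = np.empty((len(k_grid), 3), dtype=complex)
    for i, k in enumerate(k_grid):
        sigma[i] = np.linalg.eigvals(linear_matrix(eq, params, k))
    lam = np.max(np.real(sigma), axis=1)
    return DispersionCurve(k=np.asarray(k_grid, dtype=float), sigma=sigma, lam=lam)


def _rhs_exact_kernels(state: SystemState, params: ModelParams,
                       grid: GridSpec):
    """Right-hand side with the exact biomass-dependent root kernel
    (direct quadrature, no fixed-width approximation); small grids only."""
    from .model_core import (evaporation_rate, local_rates_sedge,
                             spectral_laplacian, sucker_growth)
    from .nonlocal_operators import brute_force_growth, brute_force_uptake

    B1, B2, W = state.B1, state.B2, state.W
    growth1 = brute_force_growth(W, B1, params, grid)
    uptake1 = brute_force_uptake(B1, params, grid)
    growth2, uptake2 = local_rates_sedge(B2, W, params)
    d1 = sucker_growth(B1, W, 1, params, grid)
    d2 = sucker_growth(B2, W, 2, params, grid)
    dB1 = growth1 * B1 * (1.0 - B1 / params.K1) - params.M1 * B1 + d1
    dB2 = growth2 * B2 * (1.0 - B2 / params.K2) - params.M2 * B2 + d2
    L = evaporation_rate(B1, B2, params)
    dW = params.P - L * W - W * (uptake1 + uptake2) \
        + params.DW * spectral_laplacian(W, grid)
    return dB1, dB2, dW


def dispersion_matrix_fd(eq, params: ModelParams, grid: GridSpec, approx,
                         mode: int, eps: float = 1e-7) -> np.ndarray:
    """Numerical linear operator at wavenumber ``k = 2*pi*mode/Lx`` built by
    central directional finite differences of the discretized right-hand
    side along single cosine modes (1D grids).

    Independent of :func:`linear_matrix`; used to validate the closed-form
    kernel-width-derivative terms.  With ``approx=None`` the exact
    (brute-force) kernels are used, removing the fixed-width interpolation
    error from the comparison.
    """
    if not grid.is_1d:
        raise ValueError("finite-difference dispersion check is 1D")
    x = grid.axes()[0]
    c = np.cos(2.0 * np.pi * mode * x / grid.Lx)
    base = np.array([eq.B1, eq.B2, eq.W], dtype=float)

    def f(fields):
        s = SystemState(*fields)
        if approx is None:
            return _rhs_exact_kernels(s, params, grid)
        return rhs(s, params, grid, approx)

    M = np.zeros((3, 3))
    for j in range(3):
        fields_p = [np.full(grid.nx, b) for b in base]
        fields_m = [np.full(grid.nx, b) for b in base]
        fields_p[j] = fields_p[j] + eps * c
        fields_m[j] = fields_m[j] - eps * c
        rp = f(fields_p)
        rm = f(fields_m)
        for i in range(3):
            proj = (rp[i] - rm[i]) / (2.0 * eps)
            if mode == 0:
                M[i, j] = proj.mean()
            else:
                M[i, j] = 2.0 * (proj * c).mean()
    return M


# ---------------------------------------------------------------------------
# Turing threshold
# ---------------------------------------------------------------------------

def turing_threshold(params: ModelParams, branch: str, P_lo: float, P_hi: float,
                     tol: float = 0.5,
                     k_grid: Optional[np.ndarray] = None) -> Optional[TuringPoint]:
    """Bisection in ``P`` for the sign change of ``max_{k>k_min} lam(k)`` on
    the given branch.  Returns ``None`` when the bracket shows no sign
    change or the branch is absent at either end."""
    if k_grid is None:
        k_grid = default_k_grid()
    warm: dict[float, np.ndarray] = {}

    def branch_eq(P: float) -> Optional[UniformEquilibrium]:
        pP = params.replace(P=P)
        start = None
        if warm:
            nearest = min(warm, key=lambda q: abs(q - P))
            start = warm[nearest]
        eq = find_branch(pP, branch, start=start)
        if eq is None and start is not None:
            eq = find_branch(pP, branch)
        if eq is not None:
            v = eq.vector
            warm[P] = {"GU": v[[0, 2]], "CU": v[[1, 2]], "MU": v}.get(branch, v)
        return eq

    def lam_max(P: float) -> Optional[float]:
        eq = branch_eq(P)
        if eq is None:
            return None
        curve = dispersion_relation(eq, params.replace(P=P), k_grid)
        return curve.max_growth()[1]

    f_lo, f_hi = lam_max(P_lo), lam_max(P_hi)
    if f_lo is None or f_hi is None or np.sign(f_lo) == np.sign(f_hi):
        return None
    lo, hi = P_lo, P_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = lam_max(mid)
        if f_mid is None:
            return None
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    P_c = 0.5 * (lo + hi)
    eq = branch_eq(P_c)
    curve = dispersion_relation(eq, params.replace(P=P_c), k_grid)
    k_c, lam_c = curve.max_growth()
    dk = k_grid[1] - k_grid[0]
    p = params.replace(P=P_c)

    def lam_at(k):
        return np.max(np.real(np.linalg.eigvals(linear_matrix(eq, p, k))))

    # polish k_c off the sampling grid before checking the extremum conditions
    try:
        res = optimize.minimize_scalar(lambda k: -lam_at(k),
                                       bracket=(max(k_c - dk, _KMIN), k_c, k_c + dk))
        if res.success:
            k_c, lam_c = float(res.x), float(-res.fun)
    except ValueError:
        pass  # grid argmax is good enough when bracketing fails
    dlam = (lam_at(k_c + dk) - lam_at(k_c - dk)) / (2.0 * dk)
    d2lam = (lam_at(k_c + dk) - 2.0 * lam_c + lam_at(k_c - dk)) / dk ** 2
    return TuringPoint(P_c=P_c, k_c=k_c, branch=branch, lam_at_kc=lam_c,
                       dlam_dk=float(dlam), d2lam_dk2=float(d2lam))


# ---------------------------------------------------------------------------
# bifurcation scan
# ---------------------------------------------------------------------------

def scan_branches(params: ModelParams, P_range: tuple[float, float],
                  dP: float, k_grid: Optional[np.ndarray] = None) -> BifurcationDiagram:
    """Continue each uniform branch over ``P`` by warm-started root finding
    and record uniform/nonuniform stability flags.  Folds terminate a
    branch; no continuation around folds is attempted."""
    if dP <= 0:
        raise ValueError("dP must be positive")
    P_values = np.arange(P_range[0], P_range[1] + 0.5 * dP, dP)
    rows = []
    warm: dict[str, np.ndarray] = {}
    for label in BRANCHES:
        for P in P_values:
            pP = params.replace(P=max(P, 1e-6))
            start = warm.get(label)
            eq = find_branch(pP, label, start=start)
            if eq is None and start is not None:
                eq = find_branch(pP, label)
            if eq is None:
                continue
            su, sn = _stability_flags(eq.vector, pP, k_grid)
            v = eq.vector
            warm[label] = {"GU": v[[0, 2]], "CU": v[[1, 2]], "MU": v}.get(label, v)
            rows.append({"P": P, "branch": label, "B1": eq.B1, "B2": eq.B2,
                         "W": eq.W, "stable_uniform": su, "stable_nonuniform": sn})
    return BifurcationDiagram(table=pd.DataFrame(rows))
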