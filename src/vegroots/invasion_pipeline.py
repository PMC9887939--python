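"""Invasion experiments: spot detection, outcome classification, the
complete/incomplete invasion threshold ``P_inv``, and halo profiles.

A single shrub spot (or a small group of spots) is placed in a uniform sedge
grassland.  Below a precipitation threshold ``P_inv`` the spots converge to
a fixed size and the sedge persists (*incomplete* invasion); above it, spots
trigger the birth of new spots (replication) until the sedge is excluded
(*complete* invasion).  The threshold is located by bisection on the
classified outcome of seeded single-spot runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .model_core import GridSpec, ModelParams, SystemState
from .nonlocal_operators import build_kernel_approx
from .solver import SolverConfig, Trajectory, integrate
from . import scenarios
from . import stability_bifurcation as sb

__all__ = [
    "SpotCensus",
    "InvasionCriteria",
    "InvasionOutcome",
    "PInvResult",
    "HaloProfile",
    "detect_spots",
    "classify_invasion",
    "find_P_inv",
    "halo_profile",
]


@dataclass
class SpotCensus:
    count: int
    centroids: list            # [x] (1D) or [x, y] (2D), periodic-mean convention
    areas: list                # m^2 (2D) or m (1D)
    peaks: list                # kg/m^2
    threshold: float


@dataclass
class InvasionCriteria:
    spot_threshold: float = 0.07       # kg/m^2; default 0.1*K1
    extinction_threshold: float = 1e-4  # domain-mean biomass, kg/m^2
    dwell: float = 5.0                 # y a count excess must persist


@dataclass
class InvasionOutcome:
    label: str                          # {incomplete, complete, retreat}
    times: np.ndarray
    spot_counts: np.ndarray
    mean_B1: np.ndarray
    mean_B2: np.ndarray
    final_state: SystemState
    converged: bool
    criteria: InvasionCriteria
    initial_count: int


@dataclass
class PInvResult:
    p_inv: float
    bracket: tuple
    probes: dict                        # P -> outcome label


@dataclass
class HaloProfile:
    r: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    W: np.ndarray
    core_radius: float
    halo_inner: Optional[float]
    halo_outer: Optional[float]
    w_min_radius: float


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------

def _periodic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components of a boolean mask with periodic wraparound
    (4-connectivity in 2D, 2-connectivity in 1D)."""
    structure = np.ones(3, dtype=int) if mask.ndim == 1 else ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels, 0

    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    def merge_edges(lo, hi):
        both = (lo > 0) & (hi > 0)
        for a, b in zip(np.atleast_1d(lo)[np.atleast_1d(both)],
                        np.atleast_1d(hi)[np.atleast_1d(both)]):
            union(int(a), int(b))

    if mask.ndim == 1:
        merge_edges(labels[0], labels[-1])
    else:
        merge_edges(labels[:, 0], labels[:, -1])
        merge_edges(labels[0, :], labels[-1, :])

    roots = sorted({find(a) for a in range(1, n + 1)})
    remap = np.zeros(n + 1, dtype=int)
    for newid, r in enumerate(roots, start=1):
        for a in range(1, n + 1):
            if find(a) == r:
                remap[a] = newid
    return remap[labels], len(roots)


def _periodic_centroid(positions: np.ndarray, length: float) -> float:
    """Mean position on a circle of circumference ``length``."""
    ang = positions * (2.0 * np.pi / length)
    c = np.cos(ang).mean()
    s = np.sin(ang).mean()
    return float((np.arctan2(s, c) * length / (2.0 * np.pi)) % length)


def detect_spots(B1: np.ndarray, threshold: float, grid: GridSpec) -> SpotCensus:
    """Census of connected components of ``{B1 > threshold}`` with periodic
    wraparound."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    B1 = np.asarray(B1, dtype=float)
    labels, n = _periodic_label(B1 > threshold)
    centroids, areas, peaks = [], [], []
    for lab in range(1, n + 1):
        sel = labels == lab
        idx = np.nonzero(sel)
        if grid.is_1d:
            xs = idx[0] * grid.dx
            centroids.append([_periodic_centroid(xs, grid.Lx)])
        else:
            ys = idx[0] * grid.dy
            xs = idx[1] * grid.dx
            centroids.append([
                _periodic_centroid(xs, grid.Lx),
                _periodic_centroid(ys, grid.Ly),
            ])
        areas.append(float(sel.sum()) * grid.cell_area)
        peaks.append(float(B1[sel].max()))
    return SpotCensus(count=n, centroids=centroids, areas=areas, peaks=peaks,
                      threshold=threshold)


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------

def _sustained_excess(times: np.ndarray, counts: np.ndarray, initial: int,
                      dwell: float) -> bool:
    """True when the spot count exceeds its initial value continuously for at
    least ``dwell`` years at some point of the series (guards against
    transient threshold flicker)."""
    excess = counts > initial
    start = None
    for t, e in zip(times, excess):
        if e and start is None:
            start = t
        elif e and t - start >= dwell:
            return True
        elif not e:
            start = None
    return False


def classify_invasion(traj: Trajectory, criteria: Optional[InvasionCriteria] = None) -> InvasionOutcome:
    """Apply the outcome definitions to a terminated trajectory.

    complete   -- final mean B2 below the extinction threshold, or spot
                  replication sustained for the dwell time (flagged
                  unconverged when the run hit the horizon mid-replication)
    incomplete -- spot count never exceeded its initial value and the sedge
                  persists
    retreat    -- final mean B1 below the extinction threshold
    """
    if criteria is None:
        criteria = InvasionCriteria()
        if traj.params is not None:
            criteria.spot_threshold = 0.1 * traj.params.K1
    times = np.asarray(traj.times)
    counts = np.array([
        detect_spots(s.B1, criteria.spot_threshold, traj.grid).count
        for s in traj.snapshots
    ])
    initial = int(counts[0])
    final_B1 = traj.mean_B1[-1]
    final_B2 = traj.mean_B2[-1]

    replicated = _sustained_excess(times, counts, initial, criteria.dwell)
    if final_B1 < criteria.extinction_threshold:
        label, converged = "retreat", True
    elif final_B2 < criteria.extinction_threshold:
        label, converged = "complete", True
    elif replicated:
        label = "complete"
        # horizon reached while the count is still growing -> complete-in-progress
        converged = traj.termination == "steady"
    else:
        label = "incomplete"
        converged = traj.termination in ("steady", "stopped")
        if traj.termination == "horizon":
            # accept as incomplete only if the count stopped changing
            tail = counts[times >= times[-1] - criteria.dwell]
            converged = bool(np.all(tail == counts[-1]))
    return InvasionOutcome(label=label, times=times, spot_counts=counts,
                           mean_B1=np.asarray(traj.mean_B1),
                           mean_B2=np.asarray(traj.mean_B2),
                           final_state=traj.final, converged=converged,
                           criteria=criteria, initial_count=initial)


# ---------------------------------------------------------------------------
# invasion threshold
# ---------------------------------------------------------------------------

def _single_spot_probe(params: ModelParams, grid: GridSpec,
                       config: SolverConfig,
                       criteria: InvasionCriteria, J: int = 5) -> InvasionOutcome:
    cu = sb.find_branch(params, "CU")
    if cu is None:
        raise ValueError(f"CU background absent at P={params.P}")
    center = [grid.Lx / 2.0] if grid.is_1d else [grid.Lx / 2.0, grid.Ly / 2.0]
    state = scenarios.ic_spots(cu, [center], radius=1.0, peak=0.5 * params.K1,
                               grid=grid)
    approx = build_kernel_approx(params, grid, J=J)

    first_excess = {"t": None}

    def stop(s: SystemState) -> bool:
        census = detect_spots(s.B1, criteria.spot_threshold, grid)
        mean_b1 = float(s.B1.mean())
        if mean_b1 < criteria.extinction_threshold:
            return True  # retreat; no need to continue
        if census.count > 1:
            if first_excess["t"] is None:
                first_excess["t"] = s.T
            return s.T - first_excess["t"] >= criteria.dwell
        first_excess["t"] = None
        return False

    traj = integrate(state, params, grid, approx, config, stop_condition=stop)
    return classify_invasion(traj, criteria)


def find_P_inv(params: ModelParams, P_lo: float, P_hi: float, tol: float,
               dimension: int = 1, grid: Optional[GridSpec] = None,
               config: Optional[SolverConfig] = None,
               criteria: Optional[InvasionCriteria] = None,
               J: int = 5) -> PInvResult:
    """Bisect the complete/incomplete boundary of a single-spot initialization.

    ``P_lo`` must classify incomplete and ``P_hi`` complete (or the reverse);
    otherwise a bracket error is raised.  Returns the midpoint of the final
    bracket (width <= tol) plus the probe audit trail.  ``J`` controls the
    kernel-approximation order of the probe runs (J=5 biases the threshold
    upward by a few percent; J=9 is recommended for quantitative work).
    """
    if grid is None:
        grid = GridSpec(Lx=128.0, nx=512) if dimension == 1 else \
            GridSpec(Lx=32.0, nx=128, Ly=32.0, ny=128)
    if config is None:
        config = SolverConfig(dt=1.5e-3, t_max=150.0, steady_tol=1e-9,
                              snapshot_every=1.0)
    if criteria is None:
        criteria = InvasionCriteria(spot_threshold=0.1 * params.K1)

    probes: dict[float, str] = {}

    def outcome(P: float) -> str:
        label = _single_spot_probe(params.replace(P=P), grid, config, criteria, J=J).label
        probes[P] = label
        return label

    lab_lo, lab_hi = outcome(P_lo), outcome(P_hi)
    if lab_lo == lab_hi:
        raise ValueError(
            f"bracket error: same outcome {lab_lo!r} at P={P_lo} and P={P_hi}")
    lo, hi = P_lo, P_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if outcome(mid) == lab_lo:
            lo = mid
        else:
            hi = mid
    return PInvResult(p_inv=0.5 * (lo + hi), bracket=(lo, hi), probes=probes)


# ---------------------------------------------------------------------------
# halo profiles
# ---------------------------------------------------------------------------

def halo_profile(state: SystemState, center, grid: GridSpec,
                 threshold: float = 0.07) -> HaloProfile:
    """Angle-averaged radial profiles about an isolated spot, plus the
    bare-soil halo annulus (radii where both biomasses sit below the
    threshold between the spot core and the surrounding grassland)."""
    center = [center] if np.isscalar(center) else list(center)
    from .scenarios import _periodic_r2

    r = np.sqrt(_periodic_r2(grid, center))
    r_max = min(grid.Lx, grid.Ly if not grid.is_1d else grid.Lx) / 2.0
    edges = np.arange(0.0, r_max + grid.dx, grid.dx)
    which = np.digitize(r.ravel(), edges) - 1
    nbin = len(edges) - 1

    prof = {}
    for name in ("B1", "B2", "W"):
        vals = getattr(state, name).ravel()
        sums = np.bincount(which, weights=vals, minlength=nbin + 1)[:nbin]
        cnts = np.bincount(which, minlength=nbin + 1)[:nbin]
        good = cnts > 0
        prof[name] = np.where(good, sums / np.maximum(cnts, 1), np.nan)
    rc = 0.5 * (edges[:-1] + edges[1:])

    if prof["B1"][0] < threshold:
        raise ValueError("no spot at the requested center")

    b1, b2 = prof["B1"], prof["B2"]
    core_end = 0
    while core_end < nbin and b1[core_end] >= threshold:
        core_end += 1
    core_radius = rc[core_end - 1]

    halo_inner = halo_outer = None
    i = core_end
    while i < nbin and b2[i] < threshold:
        if b1[i] < threshold and halo_inner is None:
            halo_inner = rc[i]
        i += 1
    if halo_inner is not None:
        halo_outer = rc[i - 1] if i > core_end else None
        if i >= nbin:          # grassland never reached: not a halo, open bare soil
            halo_inner = halo_outer = None

    w_min_radius = float(rc[int(np.nanargmin(prof["W"]))])
    return HaloProfile(r=rc, B1=b1, B2=b2, W=prof["W"],
                       core_radius=float(core_radius),
                       halo_inner=halo_inner, halo_outer=halo_outer,
                       w_min_radius=w_min_radius)
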