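"""Boltzmann free-energy landscapes from class coefficients and counts.

Each 3D class occupies a point in eigenvolume-coefficient space and carries a
particle count. Binning the counts over a chosen coefficient pair gives an
occupancy grid; Boltzmann inversion, E_b = -ln(n_b / n_max) in units of kT,
turns relative occupancies into free energies with the most populated bin as
the zero of energy. Barriers between landscape minima are measured as the
bottleneck of the minimax path: the lowest possible maximal energy along any
8-connected path between the two minima, minus the higher minimum.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "EnergyLandscape",
    "BarrierReport",
    "build_landscape",
    "find_minima_and_barrier",
    "compare_landscapes",
]


@dataclass
class EnergyLandscape:
    """Binned occupancies and free energies over one coefficient pair."""

    components: tuple[int, int]
    edges_x: np.ndarray
    edges_y: np.ndarray
    occupancy: np.ndarray  # raw integer particle counts per bin
    energy: np.ndarray  # kT; NaN on empty bins unless capped
    smoothing_sigma: float
    capped: bool
    reference: str = "max-occupancy bin has energy 0"

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.energy)

    def bin_of(self, cx: float, cy: float) -> tuple[int, int]:
        """Bin indices of a coefficient pair (clipped to the grid)."""
        ix = int(np.clip(np.searchsorted(self.edges_x, cx, side="right") - 1, 0, len(self.edges_x) - 2))
        iy = int(np.clip(np.searchsorted(self.edges_y, cy, side="right") - 1, 0, len(self.edges_y) - 2))
        return ix, iy


@dataclass
class BarrierReport:
    minima: list[tuple[tuple[int, int], float]]
    barrier_height: float | None
    path: list[tuple[int, int]] = field(default_factory=list)
    disconnected: bool = False


def _edges(values: np.ndarray, nbins: int, margin: float = 0.05) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo
    if span <= 0:
        span = max(abs(lo), 1.0)
        lo, hi = lo - 0.5 * span, hi + 0.5 * span
    pad = margin * span
    return np.linspace(lo - pad, hi + pad, nbins + 1)


def build_landscape(
    coefficients: np.ndarray,
    counts: np.ndarray,
    components: tuple[int, int] = (0, 1),
    bins="auto",
    smoothing_sigma: float = 1.0,
    cap_empty: bool = False,
) -> EnergyLandscape:
    """Bin class particle counts over a coefficient pair and invert to energies.

    Each class deposits its full count at its coefficient point. Occupancy may
    be smoothed with a Gaussian kernel (sigma in bins) *before* the logarithm;
    with ``smoothing_sigma=0`` the energy is exactly -ln(n_b/n_max). Empty
    bins are NaN, or capped at (max defined energy + 1) with ``cap_empty``.
    """
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=float))
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() <= 0:
        raise ValueError("at least one class must have a positive count")
    k1, k2 = components
    if k1 == k2 or max(k1, k2) >= coefficients.shape[1] or min(k1, k2) < 0:
        raise ValueError(f"invalid component pair {components} for K={coefficients.shape[1]}")
    if bins == "auto":
        bins = (32, 32)
    elif np.isscalar(bins):
        bins = (int(bins), int(bins))
    cx, cy = coefficients[:, k1], coefficients[:, k2]
    ex = _edges(cx, bins[0])
    ey = _edges(cy, bins[1])
    occ, _, _ = np.histogram2d(cx, cy, bins=(ex, ey), weights=counts.astype(float))
    occupancy = occ.astype(np.int64)
    dens = gaussian_filter(occ, smoothing_sigma) if smoothing_sigma > 0 else occ
    with np.errstate(divide="ignore"):
        energy = -np.log(np.where(dens > 0, dens, np.nan) / dens.max())
    if cap_empty:
        cap = np.nanmax(energy) + 1.0
        energy = np.where(np.isnan(energy), cap, energy)
    return EnergyLandscape(
        components=(k1, k2),
        edges_x=ex,
        edges_y=ey,
        occupancy=occupancy,
        energy=energy,
        smoothing_sigma=float(smoothing_sigma),
        capped=cap_empty,
    )


_NEIGHBORS = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]


def _local_minima(energy: np.ndarray) -> list[tuple[tuple[int, int], float]]:
    defined = np.isfinite(energy)
    minima = []
    nx, ny = energy.shape
    for i in range(nx):
        for j in range(ny):
            if not defined[i, j]:
                continue
            e = energy[i, j]
            ok = True
            for dx, dy in _NEIGHBORS:
                a, b = i + dx, j + dy
                if 0 <= a < nx and 0 <= b < ny and defined[a, b] and energy[a, b] < e - 1e-12:
                    ok = False
                    break
            if ok:
                minima.append(((i, j), float(e)))
    minima.sort(key=lambda m: (m[1], m[0]))
    return minima


def _minimax_path(energy: np.ndarray, start, goal):
    """Path minimizing the maximum energy visited (Dijkstra with max-relaxation)."""
    nx, ny = energy.shape
    best = np.full((nx, ny), np.inf)
    prev = {}
    best[start] = energy[start]
    heap = [(energy[start], start)]
    while heap:
        cost, node = heapq.heappop(heap)
        if node == goal:
            path = [node]
            while node in prev:
                node = prev[node]
                path.append(node)
            return cost, path[::-1]
        if cost > best[node]:
            continue
        i, j = node
        for dx, dy in _NEIGHBORS:
            a, b = i + dx, j + dy
            if not (0 <= a < nx and 0 <= b < ny) or not np.isfinite(energy[a, b]):
                continue
            c = max(cost, energy[a, b])
            if c < best[a, b]:
                best[a, b] = c
                prev[(a, b)] = node
                heapq.heappush(heap, (c, (a, b)))
    return np.inf, []


def find_minima_and_barrier(landscape: EnergyLandscape) -> BarrierReport:
    """Local minima of the landscape and the barrier between the two lowest.

    Minima are non-strict local minima over 8-neighborhoods of defined bins
    (plateau bins all qualify). The barrier is the minimax-path bottleneck
    between the two lowest minima minus the higher minimum's energy; if they
    lie in disconnected defined regions the report is flagged and the barrier
    is infinite.
    """
    minima = _local_minima(landscape.energy)
    if len(minima) == 0:
        raise ValueError("landscape has no defined bins")
    if len(minima) == 1:
        return BarrierReport(minima=minima, barrier_height=None)
    (a, ea), (b, eb) = minima[0], minima[1]
    bottleneck, path = _minimax_path(landscape.energy, a, b)
    if not np.isfinite(bottleneck):
        return BarrierReport(minima=minima, barrier_height=np.inf, disconnected=True)
    return BarrierReport(
        minima=minima,
        barrier_height=float(max(0.0, bottleneck - max(ea, eb))),
        path=path,
    )


def compare_landscapes(a: EnergyLandscape, b: EnergyLandscape):
    """Bin-wise energy difference and occupied-area ratio of two landscapes.

    Requires identical binning. The occupied-area ratio (#defined bins in b) /
    (#defined bins in a) quantifies how much conformational space one
    condition retains relative to the other.
    """
    if (
        a.energy.shape != b.energy.shape
        or not np.allclose(a.edges_x, b.edges_x)
        or not np.allclose(a.edges_y, b.edges_y)
    ):
        raise ValueError("landscapes have incompatible binning; rebin first")
    common = a.defined & b.defined
    diff = np.where(common, b.energy - a.energy, np.nan)
    max_abs = float(np.nanmax(np.abs(diff))) if common.any() else np.nan
    ratio = float(b.defined.sum() / a.defined.sum()) if a.defined.any() else np.nan
    return diff, {"max_abs_delta_energy": max_abs, "occupied_area_ratio": ratio}
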