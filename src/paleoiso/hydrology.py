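"""DEM conditioning and precipitation-weighted flow accumulation.

The upstream half of the environmental conditional model: depressions in the
elevation model are removed by priority-flood filling so that every cell
drains to the grid boundary, each cell's water (its precipitation weight) is
routed to exactly one downslope neighbour — deterministically to the steepest
one (D8) or stochastically between the two neighbours bracketing the aspect
(Rho8, Fairfield & Leymarie) — and accumulated top-down from the highest cell
to the outlets.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterGrid

__all__ = [
    "FlowField",
    "fill_sinks",
    "flow_directions",
    "accumulate",
    "flow_accumulation",
    "largest_stream_component",
    "extract_main_stem",
    "delineate_watershed",
]

# 8-neighbour offsets, index == direction code; distances in cell units.
OFFSETS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
DISTANCES = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])
# Compass angle (radians) of each neighbour direction, measured from the
# +col axis counter-clockwise with rows increasing downwards.
ANGLES = np.arctan2(-OFFSETS[:, 0], OFFSETS[:, 1]) % (2 * np.pi)

OUTLET = -1  # drains off-grid
NOFLOW = -2  # nodata cell


@dataclass
class FlowField:
    """Routing directions plus accumulated weight over one grid.

    ``directions`` holds a neighbour code 0..7 per cell (index into
    :data:`OFFSETS`), ``-1`` for cells draining off-grid and ``-2`` for
    nodata. ``acc`` is the accumulated weight: each cell's own weight plus
    everything routed through it from upstream.
    """

    directions: np.ndarray
    acc: RasterGrid
    algorithm: str = "d8"
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.directions.shape

    def outflow_total(self) -> float:
        """Total weight leaving the grid through off-grid outlets."""
        out = self.directions == OUTLET
        return float(self.acc.values[out].sum())


def fill_sinks(dem: RasterGrid, epsilon: float = 1e-4) -> RasterGrid:
    """Remove closed depressions by priority-flood filling.

    After filling, every valid cell has a non-ascending (strictly descending
    when ``epsilon > 0``) 8-neighbour path to the grid or nodata boundary.
    Cells not inside a depression are returned unchanged; raised cells are
    lifted to the spill elevation plus a tiny ``epsilon`` gradient per step so
    that flats stay drainable.
    """
    valid = dem.valid_mask()
    if not valid.any():
        raise ValueError("cannot fill an all-nodata DEM")
    rows, cols = dem.shape
    z = dem.values.astype(float)
    filled = np.full_like(z, np.inf)
    visited = np.zeros_like(valid)

    heap: list[tuple[float, int, int, int]] = []
    order = 0  # tie-break to keep heap comparisons on floats/ints only
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            edge = r in (0, rows - 1) or c in (0, cols - 1)
            if not edge:
                # nodata neighbours also count as boundary
                for dr, dc in OFFSETS:
                    rr, cc = r + dr, c + dc
                    if not valid[rr, cc]:
                        edge = True
                        break
            if edge:
                filled[r, c] = z[r, c]
                visited[r, c] = True
                heapq.heappush(heap, (z[r, c], order, r, c))
                order += 1

    while heap:
        elev, _, r, c = heapq.heappop(heap)
        for dr, dc in OFFSETS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < rows and 0 <= cc < cols):
                continue
            if visited[rr, cc] or not valid[rr, cc]:
                continue
            filled[rr, cc] = max(z[rr, cc], elev + epsilon)
            visited[rr, cc] = True
            heapq.heappush(heap, (filled[rr, cc], order, rr, cc))
            order += 1

    out = np.where(valid, filled, dem.nodata)
    return dem.with_values(out)


def _downslope_gradients(z: np.ndarray, valid: np.ndarray, r: int, c: int) -> np.ndarray:
    """Slope towards each of the 8 neighbours; -inf for invalid ones."""
    rows, cols = z.shape
    grads = np.full(8, -np.inf)
    for k, (dr, dc) in enumerate(OFFSETS):
        rr, cc = r + dr, c + dc
        if 0 <= rr < rows and 0 <= cc < cols and valid[rr, cc]:
            grads[k] = (z[r, c] - z[rr, cc]) / DISTANCES[k]
    return grads


def flow_directions(
    dem: RasterGrid, algorithm: str = "d8", seed: int = 0
) -> np.ndarray:
    """Assign one downslope neighbour code per cell on a sink-free DEM.

    D8 picks the steepest descent; Rho8 draws, with the given seed, between
    the two neighbour directions bracketing the cell's aspect, weighted by
    angular proximity (falling back to the steeper candidate, then to D8,
    when a candidate is not downslope). Cells with no strictly lower valid
    neighbour must touch the boundary — otherwise the DEM still contains a
    flat or pit and a ``ValueError`` is raised.
    """
    if algorithm not in ("d8", "rho8"):
        raise ValueError(f"unknown routing algorithm {algorithm!r}")
    rng = np.random.default_rng(seed)
    valid = dem.valid_mask()
    z = dem.values.astype(float)
    rows, cols = dem.shape
    dirs = np.full((rows, cols), NOFLOW, dtype=int)

    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            grads = _downslope_gradients(z, valid, r, c)
            best = int(np.argmax(grads))
            edge = (
                r in (0, rows - 1)
                or c in (0, cols - 1)
                or any(
                    not (0 <= r + dr < rows and 0 <= c + dc < cols)
                    or not valid[r + dr, c + dc]
                    for dr, dc in OFFSETS
                )
            )
            if grads[best] <= 0:
                if edge:
                    dirs[r, c] = OUTLET
                    continue
                raise ValueError(
                    f"unresolved flat or pit at cell ({r}, {c}); "
                    "fill sinks with epsilon > 0 first"
                )
            if algorithm == "d8":
                dirs[r, c] = best
            else:
                dirs[r, c] = _rho8_choice(grads, best, rng)
    return dirs


def _rho8_choice(grads: np.ndarray, steepest: int, rng: np.random.Generator) -> int:
    # Aspect from the vector sum of downslope gradients; bracketing
    # neighbour directions are the floor/ceil multiples of 45 degrees.
    down = np.clip(grads, 0, None)
    down[~np.isfinite(down)] = 0.0
    vx = float(np.sum(down * np.cos(ANGLES)))
    vy = float(np.sum(down * np.sin(ANGLES)))
    if vx == 0.0 and vy == 0.0:
        return steepest
    theta = np.arctan2(vy, vx) % (2 * np.pi)
    sector = theta / (np.pi / 4)
    lo = int(np.floor(sector)) % 8
    hi = (lo + 1) % 8
    frac = sector - np.floor(sector)  # 0 -> exactly on lo
    pick, other = (lo, hi) if rng.random() >= frac else (hi, lo)
    # map sector index (angle order) back to direction codes sharing ANGLES
    code_by_sector = np.argsort(ANGLES)
    pick, other = int(code_by_sector[pick]), int(code_by_sector[other])
    for cand in (pick, other):
        if grads[cand] > 0:
            return cand
    return steepest


def accumulate(
    directions: np.ndarray, weights: RasterGrid
) -> RasterGrid:
    """Top-down weighted accumulation along fixed directions.

    Cells are processed in topological order (upstream before downstream);
    each passes its accumulated weight to its single receiving neighbour.
    """
    if directions.shape != weights.shape:
        raise ValueError("directions and weights shapes differ")
    w = weights.values.astype(float)
    valid = directions != NOFLOW
    if np.any(w[weights.valid_mask()] < 0):
        raise ValueError("weights must be non-negative")
    acc = np.where(valid, w, 0.0)

    rows, cols = directions.shape
    # in-degree based topological (Kahn) ordering of the flow forest
    indeg = np.zeros((rows, cols), dtype=int)
    for r in range(rows):
        for c in range(cols):
            d = directions[r, c]
            if d >= 0:
                dr, dc = OFFSETS[d]
                indeg[r + dr, c + dc] += 1
    stack = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if valid[r, c] and indeg[r, c] == 0
    ]
    seen = 0
    while stack:
        r, c = stack.pop()
        seen += 1
        d = directions[r, c]
        if d >= 0:
            rr, cc = r + OFFSETS[d][0], c + OFFSETS[d][1]
            acc[rr, cc] += acc[r, c]
            indeg[rr, cc] -= 1
            if indeg[rr, cc] == 0:
                stack.append((rr, cc))
    if seen != int(valid.sum()):
        raise ValueError("flow directions contain a cycle")
    out = np.where(valid, acc, weights.nodata)
    return weights.with_values(out)


def flow_accumulation(
    dem: RasterGrid,
    weights: RasterGrid,
    algorithm: str = "d8",
    seed: int = 0,
) -> FlowField:
    """Route each cell's weight downslope and sum upstream contributions."""
    if dem.shape != weights.shape:
        raise ValueError("DEM and weight grids have different shapes")
    dirs = flow_directions(dem, algorithm=algorithm, seed=seed)
    acc = accumulate(dirs, weights)
    return FlowField(directions=dirs, acc=acc, algorithm=algorithm, seed=seed)


def largest_stream_component(flow: FlowField, threshold: float) -> RasterGrid:
    """Boolean grid of the largest 8-connected set of cells with acc >= threshold."""
    valid = flow.directions != NOFLOW
    stream = valid & (flow.acc.values >= threshold)
    if not stream.any():
        raise ValueError("threshold exceeds the maximum accumulation: empty stream")
    labels, n = ndimage.label(stream, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(stream, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return flow.acc.with_values(labels == keep)


def extract_main_stem(flow: FlowField, threshold: float) -> RasterGrid:
    """Maximum-accumulation path through the largest stream component.

    Starting from the component's highest-accumulation cell, the stem is
    walked downstream along the routing directions and upstream by always
    stepping to the inflowing neighbour with the largest accumulation,
    staying within the component.
    """
    comp = largest_stream_component(flow, threshold).values.astype(bool)
    acc = flow.acc.values
    stem = np.zeros_like(comp)

    masked = np.where(comp, acc, -np.inf)
    r, c = np.unravel_index(int(np.argmax(masked)), comp.shape)

    # downstream walk
    rr, cc = r, c
    while comp[rr, cc] and not stem[rr, cc]:
        stem[rr, cc] = True
        d = flow.directions[rr, cc]
        if d < 0:
            break
        rr, cc = rr + OFFSETS[d][0], cc + OFFSETS[d][1]
        if not comp[rr, cc]:
            break
    # upstream walk
    rr, cc = r, c
    while True:
        best = None
        for k, (dr, dc) in enumerate(OFFSETS):
            pr, pc = rr + dr, cc + dc
            if not (0 <= pr < comp.shape[0] and 0 <= pc < comp.shape[1]):
                continue
            d = flow.directions[pr, pc]
            if d >= 0 and (pr + OFFSETS[d][0], pc + OFFSETS[d][1]) == (rr, cc):
                if comp[pr, pc] and not stem[pr, pc]:
                    if best is None or acc[pr, pc] > acc[best]:
                        best = (pr, pc)
        if best is None:
            break
        stem[best] = True
        rr, cc = best
    return flow.acc.with_values(stem)


def delineate_watershed(flow: FlowField, pour_point: tuple[int, int]) -> RasterGrid:
    """Mask of every cell whose flow path passes through ``pour_point``."""
    r0, c0 = pour_point
    rows, cols = flow.shape
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError("pour point outside the grid")
    if flow.directions[r0, c0] == NOFLOW:
        raise ValueError("pour point lies on a nodata cell")

    # reverse adjacency: which cells flow into each cell
    inflows: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r in range(rows):
        for c in range(cols):
            d = flow.directions[r, c]
            if d >= 0:
                inflows.setdefault((r + OFFSETS[d][0], c + OFFSETS[d][1]), []).append((r, c))

    mask = np.zeros((rows, cols), dtype=bool)
    stack = [(r0, c0)]
    while stack:
        cell = stack.pop()
        if mask[cell]:
            continue
        mask[cell] = True
        stack.extend(inflows.get(cell, []))
    return flow.acc.with_values(mask)
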