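"""3-D environment: box, uniform-grid spatial index, placement and movement.

Agents are hard spheres; a dedicated overlap check guarantees that every
committed move ends in empty space (centre distance >= sum of radii; touching
spheres are legal).  The box has reflecting walls by default — a step that
crosses a wall is folded back specularly, repeatedly for steps longer than
the box — with periodic wrapping available behind a flag, and a `reject`
policy (out-of-box endpoints count as failed attempts) for sensitivity
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .physics import random_unit_vector


class PackingError(RuntimeError):
    """Collision-free placement could not be achieved."""


@dataclass(frozen=True)
class Box:
    side: float  # Å
    boundary: str = "reflect"  # "reflect" | "periodic"

    def __post_init__(self) -> None:
        if not self.side > 0:
            raise ValueError("box side must be > 0")
        if self.boundary not in ("reflect", "periodic"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def volume_a3(self) -> float:
        return self.side**3


def _fold_reflect(x: np.ndarray, side: float) -> np.ndarray:
    """Specular folding of coordinates into [0, side] (triangle wave)."""
    m = np.mod(x, 2.0 * side)
    return side - np.abs(m - side)


def propose_move(pos: np.ndarray, direction: np.ndarray, length: float,
                 box: Box) -> np.ndarray:
    """Endpoint of a step of modulus ``length`` Å from ``pos`` along
    ``direction``, folded into the box (reflecting) or wrapped (periodic)."""
    target = np.asarray(pos, dtype=float) + length * np.asarray(direction)
    if box.boundary == "periodic":
        return np.mod(target, box.side)
    return _fold_reflect(target, box.side)


class SpatialIndex:
    """Uniform-grid index over live spheres.

    Owns the position/radius arrays of all agents (stable integer ids,
    slots reused after removal).  Queries gather candidate ids from the grid
    cells covering the search ball and filter by exact distance; very wide
    queries fall back to a vectorised scan over all live agents.
    """

    def __init__(self, box: Box, cell_size: float | None = None,
                 capacity: int = 256):
        self.box = box
        if cell_size is None:
            cell_size = box.side / 8.0
        self.cell_size = float(cell_size)
        self.ncells = max(1, int(math.ceil(box.side / self.cell_size)))
        self.pos = np.zeros((capacity, 3))
        self.radius = np.zeros(capacity)
        self.alive = np.zeros(capacity, dtype=bool)
        self._cells: dict[int, set[int]] = {}
        self._cell_of: dict[int, int] = {}
        self._free: list[int] = list(range(capacity - 1, -1, -1))
        self._live_cache: np.ndarray | None = None
        self.max_radius = 0.0

    # -- bookkeeping -------------------------------------------------------

    def _grow(self) -> None:
        old = len(self.alive)
        new = old * 2
        for name in ("pos", "radius", "alive"):
            arr = getattr(self, name)
            grown = np.zeros((new,) + arr.shape[1:], dtype=arr.dtype)
            grown[:old] = arr
            setattr(self, name, grown)
        self._free.extend(range(new - 1, old - 1, -1))

    def _cell_key(self, p: np.ndarray) -> int:
        n = self.ncells
        ix = min(n - 1, max(0, int(p[0] / self.cell_size)))
        iy = min(n - 1, max(0, int(p[1] / self.cell_size)))
        iz = min(n - 1, max(0, int(p[2] / self.cell_size)))
        return (ix * n + iy) * n + iz

    def add(self, pos: np.ndarray, radius: float) -> int:
        if not self._free:
            self._grow()
        aid = self._free.pop()
        self.pos[aid] = pos
        self.radius[aid] = radius
        self.alive[aid] = True
        key = self._cell_key(self.pos[aid])
        self._cells.setdefault(key, set()).add(aid)
        self._cell_of[aid] = key
        self.max_radius = max(self.max_radius, radius)
        self._live_cache = None
        return aid

    def remove(self, aid: int) -> None:
        if not self.alive[aid]:
            raise KeyError(f"agent {aid} not alive")
        self.alive[aid] = False
        self._cells[self._cell_of.pop(aid)].discard(aid)
        self._free.append(aid)
        self._live_cache = None

    def move(self, aid: int, pos: np.ndarray) -> None:
        self.pos[aid] = pos
        key = self._cell_key(self.pos[aid])
        old = self._cell_of[aid]
        if key != old:
            self._cells[old].discard(aid)
            self._cells.setdefault(key, set()).add(aid)
            self._cell_of[aid] = key

    def set_radius(self, aid: int, radius: float) -> None:
        self.radius[aid] = radius
        self.max_radius = max(self.max_radius, radius)

    def live_ids(self) -> np.ndarray:
        if self._live_cache is None:
            self._live_cache = np.flatnonzero(self.alive)
        return self._live_cache

    @property
    def n_live(self) -> int:
        return len(self.live_ids())

    # -- queries -----------------------------------------------------------

    def _displacements(self, ids: np.ndarray, center: np.ndarray) -> np.ndarray:
        d = self.pos[ids] - center
        if self.box.boundary == "periodic":
            side = self.box.side
            d -= side * np.round(d / side)
        return d

    def _candidates(self, center: np.ndarray, radius: float) -> np.ndarray:
        span = int(math.ceil(radius / self.cell_size))
        if (2 * span + 1) ** 3 >= 4 * max(1, len(self._cells)):
            return self.live_ids()
        n = self.ncells
        cx = int(center[0] / self.cell_size)
        cy = int(center[1] / self.cell_size)
        cz = int(center[2] / self.cell_size)
        out: list[int] = []
        periodic = self.box.boundary == "periodic"
        for ix in range(cx - span, cx + span + 1):
            if periodic:
                ix %= n
            elif not 0 <= ix < n:
                continue
            for iy in range(cy - span, cy + span + 1):
                if periodic:
                    iy %= n
                elif not 0 <= iy < n:
                    continue
                base = (ix * n + iy) * n
                for iz in range(cz - span, cz + span + 1):
                    if periodic:
                        iz %= n
                    elif not 0 <= iz < n:
                        continue
                    bucket = self._cells.get(base + iz)
                    if bucket:
                        out.extend(bucket)
        return np.array(sorted(out), dtype=np.intp)

    def _candidate_list(self, cx: float, cy: float, cz: float,
                        radius: float) -> list[int] | None:
        """Unsorted candidate ids near a point; None means 'scan everything'."""
        span = int(math.ceil(radius / self.cell_size))
        if (2 * span + 1) ** 3 >= 4 * max(1, len(self._cells)):
            return None
        n = self.ncells
        cxi = int(cx / self.cell_size)
        cyi = int(cy / self.cell_size)
        czi = int(cz / self.cell_size)
        out: list[int] = []
        periodic = self.box.boundary == "periodic"
        cells = self._cells
        for ix in range(cxi - span, cxi + span + 1):
            if periodic:
                ix %= n
            elif not 0 <= ix < n:
                continue
            for iy in range(cyi - span, cyi + span + 1):
                if periodic:
                    iy %= n
                elif not 0 <= iy < n:
                    continue
                base = (ix * n + iy) * n
                for iz in range(czi - span, czi + span + 1):
                    if periodic:
                        iz %= n
                    elif not 0 <= iz < n:
                        continue
                    bucket = cells.get(base + iz)
                    if bucket:
                        out.extend(bucket)
        return out

    def overlap_free_point(self, cx: float, cy: float, cz: float,
                           radius: float, exclude: int = -1) -> bool:
        """Scalar fast path of :meth:`overlap_free` (identical semantics)."""
        ids = self._candidate_list(cx, cy, cz, radius + self.max_radius)
        if ids is None:
            return self.overlap_free(np.array([cx, cy, cz]), radius,
                                     exclude if exclude >= 0 else None)
        pos = self.pos
        rad = self.radius
        periodic = self.box.boundary == "periodic"
        side = self.box.side
        for j in ids:
            if j == exclude:
                continue
            row = pos[j]
            dx = row[0] - cx
            dy = row[1] - cy
            dz = row[2] - cz
            if periodic:
                dx -= side * round(dx / side)
                dy -= side * round(dy / side)
                dz -= side * round(dz / side)
            rsum = rad[j] + radius
            if dx * dx + dy * dy + dz * dz < rsum * rsum * (1.0 - 1e-12):
                return False
        return True

    def query_sphere(self, center: np.ndarray, radius: float,
                     exclude: int | None = None) -> np.ndarray:
        """Ids of live agents with centre within ``radius`` Å of ``center``
        (closed ball, boundary metric of the box)."""
        if radius < 0:
            raise ValueError("query radius must be >= 0")
        center = np.asarray(center, dtype=float)
        ids = self._candidates(center, radius)
        if len(ids) == 0:
            return ids
        d = self._displacements(ids, center)
        hit = np.einsum("ij,ij->i", d, d) <= radius * radius
        ids = ids[hit]
        if exclude is not None:
            ids = ids[ids != exclude]
        return ids

    def overlap_free(self, center: np.ndarray, radius: float,
                     exclude: int | None = None) -> bool:
        """True if a sphere of ``radius`` at ``center`` overlaps no live agent
        (touching is legal: overlap means centre distance < r_i + r_j)."""
        center = np.asarray(center, dtype=float)
        ids = self._candidates(center, radius + self.max_radius)
        if exclude is not None:
            ids = ids[ids != exclude]
        if len(ids) == 0:
            return True
        d = self._displacements(ids, center)
        d2 = np.einsum("ij,ij->i", d, d)
        rsum = self.radius[ids] + radius
        return not bool(np.any(d2 < rsum * rsum * (1.0 - 1e-12)))


def neighbors_within(index: SpatialIndex, pos: np.ndarray,
                     radius: float) -> np.ndarray:
    """Exactly the live agents whose centre is within ``radius`` Å of ``pos``."""
    return index.query_sphere(pos, radius)


def place_sphere(index: SpatialIndex, radius: float, box: Box,
                 rng: np.random.Generator, tries: int = 200) -> int:
    """Add one sphere at a uniformly random, non-overlapping position fully
    inside the box.  Raises :class:`PackingError` after ``tries`` rejections."""
    lo, hi = radius, box.side - radius
    if hi <= lo:
        raise PackingError(
            f"sphere of radius {radius} Å does not fit in a {box.side} Å box")
    for _ in range(tries):
        p = lo + (hi - lo) * rng.random(3)
        if index.overlap_free(p, radius):
            return index.add(p, radius)
    occupied = 4.0 / 3.0 * math.pi * float(
        np.sum(index.radius[index.live_ids()] ** 3))
    raise PackingError(
        f"no free position for sphere of radius {radius} Å after {tries} "
        f"tries (packing fraction {occupied / box.volume_a3:.3f})")


def place_initial(specs: list[tuple[float, int]], box: Box,
                  rng: np.random.Generator,
                  packing_threshold: float = 0.45,
                  tries: int = 200) -> tuple[SpatialIndex, list[int]]:
    """Place ``count`` spheres of each ``(radius, count)`` spec uniformly at
    random without overlaps.  Returns the populated index and the agent ids in
    placement order."""
    total = sum(4.0 / 3.0 * math.pi * r**3 * n for r, n in specs)
    fraction = total / box.volume_a3
    if fraction > packing_threshold:
        raise PackingError(
            f"requested packing fraction {fraction:.3f} exceeds threshold "
            f"{packing_threshold}")
    index = SpatialIndex(box)
    ids = []
    for radius, count in specs:
        for _ in range(count):
            ids.append(place_sphere(index, radius, box, rng, tries))
    return index, ids


def _fold1(x: float, side: float) -> float:
    m = x % (2.0 * side)
    return side - abs(m - side)


def try_commit_move(index: SpatialIndex, aid: int, direction: np.ndarray,
                    length: float, box: Box, rng: np.random.Generator,
                    retries: int = 5, policy: str = "fold") -> bool:
    """Attempt to move agent ``aid`` by ``length`` Å along ``direction``.

    If the endpoint overlaps another agent (or, under the ``reject`` policy,
    leaves the box), up to ``retries`` fresh random directions are tried; on
    total failure the agent stays put and False is returned.
    """
    if length == 0.0:
        return True
    radius = float(index.radius[aid])
    row = index.pos[aid]
    px, py, pz = float(row[0]), float(row[1]), float(row[2])
    side = box.side
    periodic = box.boundary == "periodic"
    dx, dy, dz = float(direction[0]), float(direction[1]), float(direction[2])
    for attempt in range(retries + 1):
        if attempt > 0:
            d = random_unit_vector(rng)
            dx, dy, dz = float(d[0]), float(d[1]), float(d[2])
        tx, ty, tz = px + length * dx, py + length * dy, pz + length * dz
        if policy == "reject":
            if not (0.0 <= tx <= side and 0.0 <= ty <= side
                    and 0.0 <= tz <= side):
                continue
        elif periodic:
            tx, ty, tz = tx % side, ty % side, tz % side
        else:
            tx, ty, tz = (_fold1(tx, side), _fold1(ty, side),
                          _fold1(tz, side))
        if index.overlap_free_point(tx, ty, tz, radius, exclude=aid):
            index.move(aid, (tx, ty, tz))
            return True
    return False


def assert_no_overlaps(index: SpatialIndex) -> None:
    """Debug check: no two live agents overlap and all centres are in-box."""
    ids = index.live_ids()
    P = index.pos[ids]
    R = index.radius[ids]
    side = index.box.side
    if len(P) and (P.min() < -1e-9 or P.max() > side + 1e-9):
        raise AssertionError("agent centre outside box")
    for k in range(len(ids)):
        d = P[k + 1:] - P[k]
        if index.box.boundary == "periodic":
            d -= side * np.round(d / side)
        d2 = np.einsum("ij,ij->i", d, d)
        rsum = R[k + 1:] + R[k]
        if np.any(d2 < rsum * rsum * (1.0 - 1e-9)):
            j = int(np.flatnonzero(d2 < rsum * rsum)[0])
            raise AssertionError(
                f"agents {ids[k]} and {ids[k + 1 + j]} overlap")
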