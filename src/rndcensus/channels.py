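"""Grid-based channel finding: clearance fields, maximin (widest-path) search,
bottleneck radius and along-channel profiles.

The clearance of a point x is min over atoms of (‖x − atom‖ − r_vdw(atom)),
i.e. the radius of the largest probe sphere centred at x that touches no
atom surface.  A channel from an interior seed to the bulk solvent is the
26-connected grid path maximising the *minimum* clearance along it (the
widest-path / bottleneck objective); its bottleneck radius is that minimum.
This is a deliberately simplified stand-in for Voronoi-based tunnel tools
(MOLE, CAVER): the bottleneck semantics agree, the path geometry and cost
model do not, and numerical agreement with those tools is not promised.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_model import StructureModel, ValidationError

DEFAULT_VDW = 1.70


def load_vdw_table(name: str = "default") -> dict[str, float]:
    """Elemental vdW radii (Å, Bondi-style) from the shipped editable table."""
    if name != "default":
        raise ValidationError(f"unknown radius table {name!r}")
    from importlib.resources import files

    table: dict[str, float] = {}
    text = files("rndcensus.data").joinpath("vdw_radii.tsv").read_text()
    for line in text.splitlines()[1:]:
        if line.strip():
            el, r = line.split("\t")
            table[el.upper()] = float(r)
    return table


#: Elemental van der Waals radii in Å; unknown elements fall back to
#: DEFAULT_VDW with a warning.
VDW_RADII: dict[str, float] = load_vdw_table()

_NEIGHBORS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=int,
)  # 26-connectivity


def vdw_radius(element: str, warn: set[str] | None = None) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        if warn is not None and element not in warn:
            warn.add(element)
            import logging

            logging.getLogger("rndcensus").warning(
                "unknown element %r: using fallback vdW radius %.2f Å",
                element,
                DEFAULT_VDW,
            )
        return DEFAULT_VDW
    return r


@dataclass
class ClearanceGrid:
    """Regular grid of clearance values over a structure's bounding box."""

    origin: np.ndarray          # (3,), Å, position of node (0,0,0)
    spacing: float              # Å
    dims: tuple[int, int, int]
    clearance: np.ndarray       # dims-shaped, Å
    exterior: np.ndarray        # dims-shaped bool

    def node_position(self, idx: tuple[int, int, int] | np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.spacing

    def nearest_node(self, point: np.ndarray) -> tuple[int, int, int]:
        idx = np.round((np.asarray(point, float) - self.origin) / self.spacing)
        idx = np.clip(idx, 0, np.array(self.dims) - 1).astype(int)
        return tuple(idx)

    def contains(self, point: np.ndarray) -> bool:
        rel = (np.asarray(point, float) - self.origin) / self.spacing
        return bool(np.all(rel >= -0.5) and np.all(rel <= np.array(self.dims) - 0.5))


@dataclass
class ChannelResult:
    """A channel path with per-node clearance and its bottleneck radius."""

    path: np.ndarray             # (n, 3) node positions, Å
    clearances: np.ndarray       # (n,), Å
    bottleneck_radius: float     # min of clearances
    seed: np.ndarray
    reached_exterior: bool
    flags: list[str] = field(default_factory=list)


def build_clearance_grid(
    structure: StructureModel,
    spacing: float = 0.8,
    padding: float = 6.0,
    probe_radius: float = 3.0,
    radius_table: dict[str, float] | None = None,
) -> ClearanceGrid:
    """Compute the exact clearance field on a regular grid.

    The box is the atom extent plus ``padding`` on all sides.  Exterior
    nodes are those connected (26-connectivity) to the box boundary through
    nodes of clearance ≥ ``probe_radius``; boundary nodes are always
    exterior.  The clearance values are exact minima over all atoms —
    the KD-tree partitioning below is an acceleration only.
    """
    if not (0.2 < spacing <= 2.0):
        raise ValidationError(f"spacing {spacing} outside (0.2, 2.0] Å")
    coords = structure.coords()
    if len(coords) == 0:
        raise ValidationError("empty structure")
    elements = structure.elements()
    warn: set[str] = set()
    radii = np.array(
        [
            (radius_table or VDW_RADII).get(e.upper(), None) or vdw_radius(e, warn)
            for e in elements
        ]
    )
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    axes = [lo[i] + spacing * np.arange(dims[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    # group atoms by radius: clearance = min over groups of (nn_dist − r)
    clear = np.full(len(nodes), np.inf)
    for r in np.unique(radii):
        tree = cKDTree(coords[radii == r])
        d, _ = tree.query(nodes, k=1)
        np.minimum(clear, d - r, out=clear)
    clearance = clear.reshape(dims)

    # exterior: flood from boundary through clearance ≥ probe_radius
    open_mask = clearance >= probe_radius
    labels, _ = ndimage.label(open_mask, structure=np.ones((3, 3, 3), int))
    boundary_labels = set()
    for ax in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=ax)
            boundary_labels.update(np.unique(face[face > 0]).tolist())
    exterior = np.isin(labels, sorted(boundary_labels)) & open_mask
    # boundary nodes are exterior by definition
    for ax in range(3):
        for sl in (0, -1):
            idx = [slice(None)] * 3
            idx[ax] = sl
            exterior[tuple(idx)] = True
    return ClearanceGrid(lo, spacing, dims, clearance, exterior)


def _maximin_search(
    grid: ClearanceGrid, seed_idx: tuple[int, int, int]
) -> tuple[float, list[tuple[int, int, int]], bool]:
    """Deterministic widest-path Dijkstra from the seed to any exterior node.

    Priority: maximise path bottleneck, then minimise hop count, then
    lexicographic node order.  Returns (bottleneck, path nodes, reached).
    """
    dims = grid.dims
    clearance = grid.clearance
    exterior = grid.exterior
    nx, ny, nz = dims

    def flat(i: int, j: int, k: int) -> int:
        return (i * ny + j) * nz + k

    n_total = nx * ny * nz
    best_bn = np.full(n_total, -np.inf)
    best_hops = np.full(n_total, np.iinfo(np.int64).max, dtype=np.int64)
    prev = np.full(n_total, -1, dtype=np.int64)
    visited = np.zeros(n_total, dtype=bool)

    s = flat(*seed_idx)
    bn0 = float(clearance[seed_idx])
    best_bn[s] = bn0
    best_hops[s] = 0
    # heap entries: (-bottleneck, hops, flat_index)
    heap: list[tuple[float, int, int]] = [(-bn0, 0, s)]
    goal = -1
    while heap:
        negb, hops, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        ui, rem = divmod(u, ny * nz)
        uj, uk = divmod(rem, nz)
        if exterior[ui, uj, uk]:
            goal = u
            break
        b = -negb
        for di, dj, dk in _NEIGHBORS:
            vi, vj, vk = ui + di, uj + dj, uk + dk
            if not (0 <= vi < nx and 0 <= vj < ny and 0 <= vk < nz):
                continue
            v = flat(vi, vj, vk)
            if visited[v]:
                continue
            cv = float(clearance[vi, vj, vk])
            if cv <= 0.0:
                continue  # inside an atom: impassable
            nb = min(b, cv)
            nh = hops + 1
            if (nb > best_bn[v]) or (nb == best_bn[v] and nh < best_hops[v]):
                best_bn[v] = nb
                best_hops[v] = nh
                prev[v] = u
                heapq.heappush(heap, (-nb, nh, v))
    if goal < 0:
        # no exterior reachable: report the best node found anyway (the seed
        # component's best achievable clearance toward the boundary)
        reachable = np.where(visited)[0]
        goal = int(reachable[np.argmax(best_bn[reachable])])
        reached = False
    else:
        reached = True
    path = []
    u = goal
    while u >= 0:
        ui, rem = divmod(u, ny * nz)
        uj, uk = divmod(rem, nz)
        path.append((ui, uj, uk))
        u = int(prev[u])
    path.reverse()
    return float(best_bn[goal]), path, reached


def find_channel(
    grid: ClearanceGrid, seed: np.ndarray, snap_radius: float = 0.0
) -> ChannelResult:
    """Widest (maximin-clearance) 26-connected path from the seed to the exterior.

    Among equal-bottleneck paths the shortest (node count), then the
    lexicographically smallest, is returned — the search is fully
    deterministic.  If no exterior node is reachable with positive clearance
    the best achievable bottleneck is still reported with
    ``reached_exterior=False``.  When ``snap_radius`` > 0 and the seed node
    lies inside an atom, the seed is moved to the best-clearance node within
    that radius (useful when seeding from residue centroids).
    """
    seed = np.asarray(seed, float)
    if not grid.contains(seed):
        raise ValidationError(f"seed {seed} outside grid")
    seed_idx = grid.nearest_node(seed)
    if snap_radius > 0 and grid.clearance[seed_idx] <= 0:
        r = int(np.ceil(snap_radius / grid.spacing))
        lo = np.maximum(np.array(seed_idx) - r, 0)
        hi = np.minimum(np.array(seed_idx) + r + 1, grid.dims)
        sub = grid.clearance[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        best = np.unravel_index(np.argmax(sub), sub.shape)
        seed_idx = tuple(int(l + b) for l, b in zip(lo, best))
    bottleneck, path_idx, reached = _maximin_search(grid, seed_idx)
    positions = np.array([grid.node_position(p) for p in path_idx])
    clears = np.array([grid.clearance[p] for p in path_idx])
    flags = [] if reached else ["no-path"]
    return ChannelResult(
        path=positions,
        clearances=clears,
        bottleneck_radius=float(clears.min()),
        seed=seed,
        reached_exterior=reached,
        flags=flags,
    )


def channel_profile(result: ChannelResult) -> np.ndarray:
    """(arc_length, clearance) pairs along the path; arc length from 0, Å."""
    if len(result.path) == 0:
        raise ValidationError("empty path")
    seg = np.linalg.norm(np.diff(result.path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return np.column_stack([arc, result.clearances])


def brute_force_maximin(
    grid: ClearanceGrid, seed_idx: tuple[int, int, int]
) -> float:
    """Independent oracle: binary search over clearance thresholds + flood fill.

    The maximin path value is the largest threshold t such that the seed is
    connected (26-connectivity) through nodes of clearance ≥ t to an
    exterior node.  Exact because the answer is one of the grid's clearance
    values.  For small grids only.
    """
    values = np.unique(grid.clearance)
    seed_clear = grid.clearance[seed_idx]
    values = values[(values <= seed_clear) & (values > 0)]
    best = -np.inf
    for t in values[::-1]:  # descending; small grids, linear scan is fine
        mask = grid.clearance >= t
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
        if labels[seed_idx] > 0 and np.any(
            (labels == labels[seed_idx]) & grid.exterior
        ):
            best = float(t)
            break
    return best
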