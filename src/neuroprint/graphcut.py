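"""Seeded binary segmentation by minimum s-t cut on the voxel graph.

The energy follows the classic interactive-segmentation formulation: every
voxel is a node, neighbouring voxels are joined by n-links whose weight

    B(p, q) = exp(-(I_p - I_q)^2 / (2 sigma^2)) * 1 / ||p - q||_mm

is large across flat intensity and small across edges (the 1/distance
factor makes the cut respect the physical voxel spacing rather than the
index lattice), and user seeds are tied to the source/sink terminals with a
capacity K no finite cut can afford to sever. The minimum cut therefore
follows the weakest intensity boundary separating foreground from
background seeds. Optional regional t-links score each voxel against
Gaussian intensity models fitted to the seed classes.

The max-flow itself runs on ``scipy.sparse.csgraph.maximum_flow`` with
capacities scaled to integers; the foreground is the source-reachable side
of the residual graph.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from skimage.filters import threshold_otsu

from .errors import BoundsError, EmptyStructureError, IncompleteSeedError, ParameterError
from .seeding import SeedSet
from .volume import ImageVolume

__all__ = [
    "GraphCutParams",
    "EnergyGraph",
    "StructureDescriptor",
    "LabelMap",
    "build_energy_graph",
    "binary_cut",
    "draw_cut",
    "cut_energy",
    "region_grow",
    "threshold_segment",
]

_CAPACITY_SCALE = 2 ** 20  # float weight -> integer capacity quantum

_OFFSETS = {
    6: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    18: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)],
    26: [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
         (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)],
}


@dataclass(frozen=True)
class GraphCutParams:
    """Tunables of the cut energy.

    sigma : intensity scale of the boundary term (default 30 intensity
        units — about the parenchyma/tumor contrast step of a typical
        enhanced T1 after windowing).
    lambda_regional : weight of the regional (seed-likelihood) t-links;
        0 keeps the energy pure boundary + hard seeds.
    connectivity : 6, 18 or 26 neighbours.
    spacing_aware : divide n-links by the physical neighbour distance.
    """

    sigma: float = 30.0
    lambda_regional: float = 0.0
    connectivity: int = 6
    spacing_aware: bool = True

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if self.lambda_regional < 0:
            raise ParameterError("lambda_regional must be >= 0")
        if self.connectivity not in _OFFSETS:
            raise ParameterError("connectivity must be 6, 18 or 26")


@dataclass
class EnergyGraph:
    """Flattened voxel graph: n-link edge list plus terminal capacities."""

    shape: tuple[int, int, int]
    edges_u: np.ndarray  # flat voxel index, one entry per unordered pair
    edges_v: np.ndarray
    edge_weight: np.ndarray
    t_source: np.ndarray  # per-voxel capacity to the source (fg) terminal
    t_sink: np.ndarray
    hard_capacity: float  # K

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class StructureDescriptor:
    """Display/printing metadata for one segmented structure."""

    name: str
    color: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 1.0)
    transparency: float = 0.0
    priority: int = 1

    def __post_init__(self):
        if not (0.0 <= self.transparency <= 1.0):
            raise ParameterError("transparency must lie in [0, 1]")
        if self.priority < 1:
            raise ParameterError("priority must be a positive integer")


@dataclass
class LabelMap:
    """Integer-labeled voxel grid congruent with its source volume."""

    labels: np.ndarray
    structures: dict[int, StructureDescriptor]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("labels must be an integer grid")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.structures)
        if missing:
            raise ParameterError(f"labels without descriptors: {sorted(missing)}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @classmethod
    def from_volume(cls, vol: ImageVolume, labels: np.ndarray,
                    structures: dict[int, StructureDescriptor]) -> "LabelMap":
        return cls(labels=labels, structures=structures, spacing=vol.spacing,
                   origin=vol.origin, direction=vol.direction)


# ---------------------------------------------------------------------------
# Graph construction


def _neighbour_pairs(shape, connectivity):
    """Flat-index (u, v) arrays for each unordered neighbour pair + offsets."""
    nx, ny, nz = shape
    idx = np.arange(nx * ny * nz).reshape(shape)
    us, vs, offs = [], [], []
    for off in _OFFSETS[connectivity]:
        sl_u = tuple(slice(0, s - o) if o > 0 else slice(-o, s) for s, o in zip(shape, off))
        sl_v = tuple(slice(o, s) if o > 0 else slice(0, s + o) for s, o in zip(shape, off))
        u = idx[sl_u].ravel()
        v = idx[sl_v].ravel()
        us.append(u)
        vs.append(v)
        offs.append(np.broadcast_to(np.asarray(off, float), (u.size, 3)))
    return np.concatenate(us), np.concatenate(vs), np.concatenate(offs)


def build_energy_graph(
    vol: ImageVolume, seeds: SeedSet, structure_id: int, params: GraphCutParams | None = None
) -> EnergyGraph:
    """Assemble n-links, hard seed t-links and optional regional t-links."""
    params = params or GraphCutParams()
    fg = seeds.fg_voxels(structure_id)
    bg = seeds.bg_voxels(structure_id)
    if not fg or not bg:
        raise IncompleteSeedError(
            f"structure {structure_id} needs both foreground and background seeds"
        )
    shape = vol.shape
    for vox in list(fg)[:1] + list(bg)[:1]:
        if not all(0 <= vox[a] < shape[a] for a in range(3)):
            raise BoundsError(f"seed voxel {vox} outside grid {shape}")

    flat = vol.data.ravel()
    u, v, offs = _neighbour_pairs(shape, params.connectivity)
    di = flat[u] - flat[v]
    w = np.exp(-(di ** 2) / (2.0 * params.sigma ** 2))
    if params.spacing_aware:
        dist = np.linalg.norm(offs * np.asarray(vol.spacing), axis=1)
        w = w / dist

    incident = np.zeros(flat.size)
    np.add.at(incident, u, w)
    np.add.at(incident, v, w)
    K = 1.0 + float(incident.max())

    t_source = np.zeros(flat.size)
    t_sink = np.zeros(flat.size)
    fg_flat = np.ravel_multi_index(np.asarray(sorted(fg)).T, shape)
    bg_flat = np.ravel_multi_index(np.asarray(sorted(bg)).T, shape)

    if params.lambda_regional > 0:
        fg_int = flat[fg_flat]
        bg_int = flat[bg_flat]
        floor = 1e-6  # variance floor avoids a degenerate likelihood model
        mu_f, var_f = float(fg_int.mean()), max(float(fg_int.var()), floor)
        mu_b, var_b = float(bg_int.mean()), max(float(bg_int.var()), floor)

        def nll(x, mu, var):
            return 0.5 * np.log(2 * np.pi * var) + (x - mu) ** 2 / (2 * var)

        # t-link to source = cost of assigning background, and vice versa
        t_source = np.clip(params.lambda_regional * nll(flat, mu_b, var_b), 0.0, K)
        t_sink = np.clip(params.lambda_regional * nll(flat, mu_f, var_f), 0.0, K)

    t_source[fg_flat] = K
    t_sink[fg_flat] = 0.0
    t_sink[bg_flat] = K
    t_source[bg_flat] = 0.0

    return EnergyGraph(shape=shape, edges_u=u, edges_v=v, edge_weight=w,
                       t_source=t_source, t_sink=t_sink, hard_capacity=K)


def cut_energy(graph: EnergyGraph, fg_mask: np.ndarray) -> float:
    """Energy of a labeling: severed n-links plus severed t-links."""
    lab = np.asarray(fg_mask, bool).ravel()
    if lab.size != graph.n_voxels:
        raise ParameterError("labeling shape does not match graph")
    e = float(graph.edge_weight[lab[graph.edges_u] != lab[graph.edges_v]].sum())
    e += float(graph.t_sink[lab].sum())        # fg voxels cut their sink link
    e += float(graph.t_source[~lab].sum())     # bg voxels cut their source link
    return e


def _min_cut(graph: EnergyGraph) -> np.ndarray:
    """Solve the s-t min cut; returns the source-side (foreground) mask."""
    n = graph.n_voxels
    src, snk = n, n + 1
    cap = np.round(np.concatenate([
        graph.edge_weight, graph.edge_weight,
        graph.t_source, graph.t_sink,
    ]) * _CAPACITY_SCALE).astype(np.int64)
    rows = np.concatenate([
        graph.edges_u, graph.edges_v,
        np.full(n, src), np.arange(n),
    ])
    cols = np.concatenate([
        graph.edges_v, graph.edges_u,
        np.arange(n), np.full(n, snk),
    ])
    keep = cap > 0
    mat = csr_matrix((cap[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2))
    mat.sum_duplicates()
    res = maximum_flow(mat, src, snk)
    residual = mat - res.flow  # reverse residuals appear as +flow on zero caps
    residual.data[residual.data < 0] = 0
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, src, directed=True, return_predecessors=False)
    fg = np.zeros(n, dtype=bool)
    fg[reach[reach < n]] = True
    return fg.reshape(graph.shape)


def binary_cut(
    vol: ImageVolume, seeds: SeedSet, structure_id: int, params: GraphCutParams | None = None
) -> np.ndarray:
    """Single-structure seeded min-cut; returns the foreground mask."""
    graph = build_energy_graph(vol, seeds, structure_id, params)
    return _min_cut(graph)


def draw_cut(
    vol: ImageVolume,
    seeds: SeedSet,
    params: GraphCutParams | None = None,
    structures: dict[int, StructureDescriptor] | None = None,
) -> LabelMap:
    """Segment every seeded structure by an independent binary min cut.

    Structures are cut one at a time against their own background seeds and
    written into a shared label grid in ascending id order (overlaps between
    structures, if any, are resolved later during model assembly).
    """
    labels = np.zeros(vol.shape, dtype=np.int32)
    descs: dict[int, StructureDescriptor] = {}
    for sid in seeds.structure_ids:
        mask = binary_cut(vol, seeds, sid, params)
        labels[mask] = sid
        descs[sid] = (structures or {}).get(sid, StructureDescriptor(name=f"structure_{sid}"))
    return LabelMap.from_volume(vol, labels, descs)


# ---------------------------------------------------------------------------
# Fallback segmenters


def region_grow(
    vol: ImageVolume,
    seed_voxels: set[tuple[int, int, int]],
    tolerance: float,
    connectivity: int = 6,
) -> np.ndarray:
    """Flood fill of voxels within ``tolerance`` of the seed-mean intensity."""
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    if connectivity not in _OFFSETS:
        raise ParameterError("connectivity must be 6, 18 or 26")
    shape = vol.shape
    seeds = sorted(seed_voxels)
    if not seeds:
        raise ParameterError("need at least one seed voxel")
    for vox in seeds:
        if not all(0 <= vox[a] < shape[a] for a in range(3)):
            raise BoundsError(f"seed voxel {vox} outside grid {shape}")
    mean = float(np.mean([vol.data[v] for v in seeds]))
    offsets = []
    for off in _OFFSETS[connectivity]:
        offsets.append(off)
        offsets.append(tuple(-o for o in off))
    mask = np.zeros(shape, dtype=bool)
    queue = deque(seeds)
    for v in seeds:
        mask[v] = True
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in offsets:
            nb = (x + dx, y + dy, z + dz)
            if not all(0 <= nb[a] < shape[a] for a in range(3)):
                continue
            if mask[nb]:
                continue
            if abs(vol.data[nb] - mean) <= tolerance:
                mask[nb] = True
                queue.append(nb)
    return mask


def threshold_segment(
    vol: ImageVolume, method: str = "otsu", level: float | None = None
) -> np.ndarray:
    """Global threshold mask: Otsu on a 256-bin histogram, or a fixed level."""
    if method == "fixed":
        if level is None:
            raise ParameterError("fixed thresholding requires a level")
        return vol.data >= float(level)
    if method == "otsu":
        if np.ptp(vol.data) == 0:
            raise ParameterError("degenerate histogram: constant volume has no Otsu threshold")
        t = threshold_otsu(vol.data, nbins=256)
        return vol.data >= t
    raise ParameterError(f"unknown threshold method {method!r}")
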