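"""Interactive seed strokes → voxel-level foreground/background seed sets.

Three drawing modes mirror how a user marks an ROI on a slice viewer:

* ``sketch`` — a polyline drawn like a pencil stroke, rasterized to a
  26-connected digital line and dilated by a square (Chebyshev) brush;
* ``polygon`` — a closed ring filled by the even-odd rule, boundary
  voxel centers included;
* ``freedraw`` — an explicit pixel set painted by the user.

The rasterized voxels become hard constraints for the graph cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage.draw import line as _digital_line

from .errors import BoundsError, GeometryError, IncompleteSeedError, ParameterError, SeedConflictError

__all__ = ["SeedGeometry", "SeedSet", "rasterize_seed_geometry", "build_seed_set", "load_seed_file", "save_seed_file"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class SeedGeometry:
    """One user stroke on an axis-aligned slice.

    ``vertices`` are 2-D points in voxel-center coordinates of the slice
    plane; the in-plane axes are the two grid axes other than ``axis``, in
    ascending order (e.g. for an axial stroke, axis='z', the 2-D coordinates
    are (x, y)).
    """

    mode: str  # sketch | polygon | freedraw
    axis: str  # x | y | z
    slice_index: int
    vertices: tuple[tuple[float, float], ...]
    role: str  # foreground | background
    structure_id: int
    brush_radius: int = 0

    def __post_init__(self):
        if self.mode not in ("sketch", "polygon", "freedraw"):
            raise ParameterError(f"unknown seed mode {self.mode!r}")
        if self.axis not in _AXES:
            raise ParameterError(f"axis must be one of x/y/z, got {self.axis!r}")
        if self.role not in ("foreground", "background"):
            raise ParameterError(f"role must be foreground/background, got {self.role!r}")
        verts = tuple((float(u), float(v)) for u, v in self.vertices)
        n = len(verts)
        if self.mode == "polygon" and n < 3:
            raise GeometryError("polygon needs >= 3 vertices")
        if self.mode == "sketch" and n < 2:
            raise GeometryError("sketch needs >= 2 vertices")
        if self.mode == "freedraw" and n < 1:
            raise GeometryError("freedraw needs a non-empty pixel set")
        if self.brush_radius < 0:
            raise ParameterError("brush_radius must be >= 0")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "slice_index", int(self.slice_index))
        object.__setattr__(self, "brush_radius", int(self.brush_radius))
        object.__setattr__(self, "structure_id", int(self.structure_id))


@dataclass
class SeedSet:
    """Per-structure foreground/background voxel index sets."""

    fg: dict[int, set[tuple[int, int, int]]] = field(default_factory=dict)
    bg: dict[int, set[tuple[int, int, int]]] = field(default_factory=dict)

    @property
    def structure_ids(self) -> list[int]:
        return sorted(set(self.fg) | set(self.bg))

    def fg_voxels(self, structure_id: int) -> set[tuple[int, int, int]]:
        return self.fg.get(structure_id, set())

    def bg_voxels(self, structure_id: int) -> set[tuple[int, int, int]]:
        return self.bg.get(structure_id, set())


def _polygon_area2(verts: np.ndarray) -> float:
    u, v = verts[:, 0], verts[:, 1]
    return float(np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1)))


def _on_segment(p, a, b, eps=1e-9) -> bool:
    cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    if abs(cross) > eps * max(1.0, abs(b[0] - a[0]) + abs(b[1] - a[1])):
        return False
    dot = (p[0] - a[0]) * (b[0] - a[0]) + (p[1] - a[1]) * (b[1] - a[1])
    return -eps <= dot <= (b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2 + eps


def _fill_polygon(verts: np.ndarray) -> set[tuple[int, int]]:
    """Even-odd interior fill at integer centers, boundary-inclusive."""
    lo = np.floor(verts.min(axis=0)).astype(int)
    hi = np.ceil(verts.max(axis=0)).astype(int)
    out: set[tuple[int, int]] = set()
    n = len(verts)
    for u in range(lo[0], hi[0] + 1):
        for v in range(lo[1], hi[1] + 1):
            p = (float(u), float(v))
            on_edge = any(_on_segment(p, verts[i], verts[(i + 1) % n]) for i in range(n))
            if on_edge:
                out.add((u, v))
                continue
            # even-odd ray cast along +u with half-open edge rule
            inside = False
            for i in range(n):
                a, b = verts[i], verts[(i + 1) % n]
                if (a[1] > p[1]) != (b[1] > p[1]):
                    x_int = a[0] + (p[1] - a[1]) * (b[0] - a[0]) / (b[1] - a[1])
                    if x_int > p[0]:
                        inside = not inside
            if inside:
                out.add((u, v))
    return out


def _trace_polyline(verts: np.ndarray) -> set[tuple[int, int]]:
    """26-connected (8-connected in-plane) digital polyline through rounded vertices."""
    pts = np.round(verts).astype(int)
    out: set[tuple[int, int]] = set()
    for a, b in zip(pts[:-1], pts[1:]):
        rr, cc = _digital_line(a[0], a[1], b[0], b[1])
        out.update(zip(rr.tolist(), cc.tolist()))
    return out


def _dilate_chebyshev(pixels: set[tuple[int, int]], radius: int) -> set[tuple[int, int]]:
    if radius == 0:
        return set(pixels)
    out: set[tuple[int, int]] = set()
    offsets = [(du, dv) for du in range(-radius, radius + 1) for dv in range(-radius, radius + 1)]
    for u, v in pixels:
        out.update((u + du, v + dv) for du, dv in offsets)
    return out


def rasterize_seed_geometry(
    geom: SeedGeometry, grid_shape: tuple[int, int, int]
) -> set[tuple[int, int, int]]:
    """Rasterize one stroke into 3-D voxel indices on its slice."""
    axis = _AXES[geom.axis]
    if not (0 <= geom.slice_index < grid_shape[axis]):
        raise BoundsError(
            f"slice index {geom.slice_index} outside axis {geom.axis} of length {grid_shape[axis]}"
        )
    in_plane = [a for a in range(3) if a != axis]
    bounds = (grid_shape[in_plane[0]], grid_shape[in_plane[1]])
    verts = np.asarray(geom.vertices, dtype=np.float64)

    if geom.mode == "freedraw":
        pixels = {(int(round(u)), int(round(v))) for u, v in verts}
        for u, v in pixels:
            if not (0 <= u < bounds[0] and 0 <= v < bounds[1]):
                raise BoundsError(f"freedraw pixel ({u}, {v}) outside slice bounds {bounds}")
    elif geom.mode == "polygon":
        if abs(_polygon_area2(verts)) < 1e-12:
            raise GeometryError("degenerate polygon (zero area)")
        if (verts.min() < -0.5 or verts[:, 0].max() > bounds[0] - 0.5
                or verts[:, 1].max() > bounds[1] - 0.5):
            raise BoundsError("polygon vertex outside slice bounds")
        pixels = _fill_polygon(verts)
    else:  # sketch
        if (verts.min() < -0.5 or verts[:, 0].max() > bounds[0] - 0.5
                or verts[:, 1].max() > bounds[1] - 0.5):
            raise BoundsError("sketch vertex outside slice bounds")
        pixels = _dilate_chebyshev(_trace_polyline(verts), geom.brush_radius)

    pixels = {(u, v) for u, v in pixels if 0 <= u < bounds[0] and 0 <= v < bounds[1]}
    out: set[tuple[int, int, int]] = set()
    for u, v in pixels:
        idx = [0, 0, 0]
        idx[axis] = geom.slice_index
        idx[in_plane[0]] = u
        idx[in_plane[1]] = v
        out.add(tuple(idx))
    return out


def build_seed_set(
    geoms: Sequence[SeedGeometry], grid_shape: tuple[int, int, int]
) -> SeedSet:
    """Union strokes by role per structure; fg/bg overlap is a hard error."""
    seeds = SeedSet()
    for geom in geoms:
        voxels = rasterize_seed_geometry(geom, grid_shape)
        target = seeds.fg if geom.role == "foreground" else seeds.bg
        target.setdefault(geom.structure_id, set()).update(voxels)
    for sid in seeds.structure_ids:
        clash = seeds.fg_voxels(sid) & seeds.bg_voxels(sid)
        if clash:
            vox = min(clash)
            raise SeedConflictError(
                f"voxel {vox} claimed both foreground and background for structure {sid}"
            )
        if not seeds.fg_voxels(sid):
            raise IncompleteSeedError(f"structure {sid} has no foreground seeds")
    return seeds


# ---------------------------------------------------------------------------
# Seed file I/O (JSON; one object per stroke mirroring SeedGeometry)


def load_seed_file(path) -> list[SeedGeometry]:
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ParameterError("seed file must contain a JSON list of strokes")
    return [
        SeedGeometry(
            mode=obj["mode"],
            axis=obj["axis"],
            slice_index=int(obj["slice_index"]),
            vertices=tuple((float(u), float(v)) for u, v in obj["vertices"]),
            role=obj["role"],
            structure_id=int(obj["structure_id"]),
            brush_radius=int(obj.get("brush_radius", 0)),
        )
        for obj in raw
    ]


def save_seed_file(geoms: Iterable[SeedGeometry], path) -> None:
    objs = [
        {
            "mode": g.mode,
            "axis": g.axis,
            "slice_index": g.slice_index,
            "vertices": [list(v) for v in g.vertices],
            "role": g.role,
            "structure_id": g.structure_id,
            "brush_radius": g.brush_radius,
        }
        for g in geoms
    ]
    Path(path).write_text(json.dumps(objs, indent=2))
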