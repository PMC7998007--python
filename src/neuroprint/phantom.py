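"""Synthetic MR-like phantoms with ground truth.

The phantom emulates the segmentation substrate the pipeline is built for:
a 1-mm-isotropic T1-like volume holding a brain-shaped envelope whose
radius is modulated by a radial sinusoid (gyri-like surface undulation, so
meshing and mold generation face a non-convex surface), a hyperintense
spherical tumor, two ventricle ellipsoids, and one deep nucleus. Class mean
intensities are chosen so adjacent classes differ by at least three noise
standard deviations at the default noise level; the corruption model is
additive Gaussian noise.

It also builds craniotomy-outline pairs with a requested Jaccard overlap
and area change, the fixtures for the planning change-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .graphcut import LabelMap, StructureDescriptor
from .seeding import SeedSet
from .volume import ImageVolume, SequenceBundle

__all__ = ["PhantomSpec", "generate_phantom", "auto_seed_set", "generate_craniotomy_pair",
           "LABEL_PARENCHYMA", "LABEL_TUMOR", "LABEL_VENTRICLES", "LABEL_NUCLEUS"]

LABEL_PARENCHYMA = 1
LABEL_TUMOR = 2
LABEL_VENTRICLES = 3
LABEL_NUCLEUS = 4

# T1-like class means (arbitrary units); adjacent-class contrast >= 30
_T1_MEANS = {0: 10.0, LABEL_PARENCHYMA: 100.0, LABEL_TUMOR: 170.0,
             LABEL_VENTRICLES: 40.0, LABEL_NUCLEUS: 135.0}
# T2/FLAIR remappings (ventricles bright on T2, suppressed on FLAIR)
_T2_MEANS = {0: 10.0, LABEL_PARENCHYMA: 90.0, LABEL_TUMOR: 150.0,
             LABEL_VENTRICLES: 180.0, LABEL_NUCLEUS: 110.0}
_FLAIR_MEANS = {0: 10.0, LABEL_PARENCHYMA: 110.0, LABEL_TUMOR: 180.0,
                LABEL_VENTRICLES: 30.0, LABEL_NUCLEUS: 125.0}

DESCRIPTORS = {
    LABEL_PARENCHYMA: StructureDescriptor(name="parenchyma", color=(0.9, 0.85, 0.8, 0.3),
                                          transparency=0.7, priority=10),
    LABEL_TUMOR: StructureDescriptor(name="tumor", color=(1.0, 0.45, 0.45, 1.0), priority=1),
    LABEL_VENTRICLES: StructureDescriptor(name="ventricles", color=(0.8, 0.8, 0.8, 1.0), priority=2),
    LABEL_NUCLEUS: StructureDescriptor(name="deep_nucleus", color=(0.7, 0.9, 0.4, 1.0), priority=3),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head volume (sizes in voxels/mm)."""

    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sigma: float = 5.0
    brain_radius_mm: float = 26.0
    gyri_amplitude_mm: float = 2.0
    gyri_frequency: int = 6
    tumor_center_offset: tuple[float, float, float] = (9.0, 5.0, 4.0)
    tumor_radius_mm: float = 8.0
    ventricle_semiaxes_mm: tuple[float, float, float] = (3.0, 8.0, 5.0)
    ventricle_offset_mm: float = 5.0
    nucleus_center_offset: tuple[float, float, float] = (-9.0, -6.0, -3.0)
    nucleus_radius_mm: float = 4.5

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if min(self.shape) < 8:
            raise ParameterError("phantom grid too small")
        half_extent = min(s * n / 2 for s, n in zip(self.spacing, self.shape))
        if self.brain_radius_mm + self.gyri_amplitude_mm >= half_extent:
            raise ParameterError("brain envelope exceeds the grid")
        for off, r in ((self.tumor_center_offset, self.tumor_radius_mm),
                       (self.nucleus_center_offset, self.nucleus_radius_mm)):
            if np.linalg.norm(off) + r >= self.brain_radius_mm - self.gyri_amplitude_mm:
                raise ParameterError("internal structure exceeds the brain envelope")


def _truth_labels(spec: PhantomSpec) -> np.ndarray:
    shape = spec.shape
    sp = np.asarray(spec.spacing)
    center = (np.asarray(shape) - 1) * sp / 2.0
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)], indexing="ij")
    pos = np.stack(grids, axis=-1) - center  # mm, brain-centered
    r = np.linalg.norm(pos, axis=-1)
    z_over_r = np.divide(pos[..., 2], r, out=np.zeros_like(r), where=r > 0)
    theta = np.arccos(np.clip(z_over_r, -1, 1))
    phi = np.arctan2(pos[..., 1], pos[..., 0])
    # gyri-like undulation: radial sinusoid in both angles
    envelope = spec.brain_radius_mm + spec.gyri_amplitude_mm * (
        np.sin(spec.gyri_frequency * phi) * np.sin(spec.gyri_frequency * theta))
    labels = np.zeros(shape, dtype=np.int32)
    labels[r <= envelope] = LABEL_PARENCHYMA

    def ball(offset, radius):
        return np.linalg.norm(pos - np.asarray(offset), axis=-1) <= radius

    def ellipsoid(offset, semiaxes):
        q = (pos - np.asarray(offset)) / np.asarray(semiaxes)
        return np.linalg.norm(q, axis=-1) <= 1.0

    tumor = ball(spec.tumor_center_offset, spec.tumor_radius_mm)
    vent_l = ellipsoid((-spec.ventricle_offset_mm, 0.0, 2.0), spec.ventricle_semiaxes_mm)
    vent_r = ellipsoid((spec.ventricle_offset_mm, 0.0, 2.0), spec.ventricle_semiaxes_mm)
    nucleus = ball(spec.nucleus_center_offset, spec.nucleus_radius_mm)
    # later assignments win; internal structures are disjoint by construction,
    # overlaps with the ventricles are ceded to the tumor (the clinical case)
    labels[vent_l | vent_r] = LABEL_VENTRICLES
    labels[nucleus] = LABEL_NUCLEUS
    labels[tumor] = LABEL_TUMOR
    return labels


def _render(labels: np.ndarray, means: dict[int, float], sigma: float,
            rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(labels.shape, dtype=np.float64)
    for label, mean in means.items():
        out[labels == label] = mean
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=labels.shape)
    return out


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[SequenceBundle, LabelMap]:
    """Deterministic phantom: three MR-like sequences plus ground truth."""
    spec = spec or PhantomSpec()
    labels = _truth_labels(spec)
    rng = np.random.default_rng(spec.seed)
    t1 = _render(labels, _T1_MEANS, spec.noise_sigma, rng)
    t2 = _render(labels, _T2_MEANS, spec.noise_sigma, rng)
    flair = _render(labels, _FLAIR_MEANS, spec.noise_sigma, rng)
    mk = lambda data: ImageVolume(data=data, spacing=spec.spacing)
    bundle = SequenceBundle(t1ce=mk(t1), t2=mk(t2), flair=mk(flair))
    labelmap = LabelMap(labels=labels, structures=DESCRIPTORS,
                        spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    return bundle, labelmap


def auto_seed_set(
    labelmap: LabelMap,
    structure_id: int,
    fg_erosion: int = 3,
    bg_gap: int = 3,
    bg_width: int = 2,
) -> SeedSet:
    """Seeds a user would plausibly draw, derived from the ground truth.

    Foreground: the structure mask eroded by ``fg_erosion`` voxels (a
    conservative interior scribble). Background: a shell starting ``bg_gap``
    voxels outside the structure, ``bg_width`` voxels wide.
    """
    mask = labelmap.mask(structure_id)
    if not mask.any():
        raise ParameterError(f"structure {structure_id} empty in ground truth")
    fg = ndimage.binary_erosion(mask, iterations=fg_erosion) if fg_erosion else mask
    if not fg.any():
        fg = mask
    outer = ndimage.binary_dilation(mask, iterations=bg_gap + bg_width)
    inner = ndimage.binary_dilation(mask, iterations=bg_gap)
    bg = outer & ~inner
    fg_set = set(map(tuple, np.argwhere(fg)))
    bg_set = set(map(tuple, np.argwhere(bg)))
    return SeedSet(fg={structure_id: fg_set}, bg={structure_id: bg_set})


def generate_craniotomy_pair(
    seed: int,
    target_overlap: float,
    target_size_change_pct: float,
    raster: tuple[int, int] = (128, 128),
    tolerance: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Two craniotomy outlines with a requested Jaccard and area change.

    Both masks are rectangles on the raster; the second has area
    ``(1 + change/100)`` times the first and is shifted so the Jaccard index
    of the pair hits ``target_overlap``. Achieved values are verified within
    ``tolerance`` (absolute on the Jaccard; ``100*tolerance`` percentage
    points on the size change); an infeasible request raises.
    """
    if not (0.0 < target_overlap <= 1.0):
        raise ParameterError("target_overlap must lie in (0, 1]")
    if target_size_change_pct < 0:
        raise ParameterError("size change must be >= 0")
    rng = np.random.default_rng(seed)
    h = raster[1] // 3
    w = h  # reference square
    area_a = w * h
    area_b = area_a * (1.0 + target_size_change_pct / 100.0)
    wb = int(round(area_b / h))
    area_b_int = wb * h
    # intersection needed for the requested Jaccard
    inter = target_overlap * (area_a + area_b_int) / (1.0 + target_overlap)
    wi = int(round(inter / h))
    if wi > min(w, wb) or wi < 0:
        raise ParameterError("infeasible overlap/size-change combination")
    max_x = raster[0] - (w + wb - wi)
    if max_x < 0:
        raise ParameterError("raster too small for the requested masks")
    x0 = int(rng.integers(0, max_x + 1))
    y0 = int(rng.integers(0, raster[1] - h + 1))
    a = np.zeros(raster, dtype=bool)
    b = np.zeros(raster, dtype=bool)
    a[x0:x0 + w, y0:y0 + h] = True
    bx = x0 + w - wi
    b[bx:bx + wb, y0:y0 + h] = True
    ach_inter = np.count_nonzero(a & b)
    ach_j = ach_inter / np.count_nonzero(a | b)
    ach_change = 100.0 * abs(np.count_nonzero(b) - area_a) / area_a
    if abs(ach_j - target_overlap) > tolerance:
        raise ParameterError(
            f"achieved Jaccard {ach_j:.3f} misses target {target_overlap} on this raster")
    if abs(ach_change - target_size_change_pct) > 100 * tolerance:
        raise ParameterError(
            f"achieved size change {ach_change:.1f}% misses target {target_size_change_pct}%")
    return a, b
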