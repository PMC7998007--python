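"""Surgical-planning quantifications.

Tumors are binned by how far their outer margin sits below the cortical
surface (cortex / < 2 cm / 2-4 cm / > 4 cm), and the difference between an
MR-only craniotomy plan and a model-informed one is summarised by two
ordinal scores: a 0-3 size-change score over the relative craniotomy-area
change, and a 0-2 location-change score over the Jaccard overlap of the two
craniotomy outlines.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .errors import EmptyStructureError, ParameterError
from .graphcut import LabelMap

__all__ = [
    "Posture",
    "ResectionGoal",
    "DepthCategory",
    "CraniotomyPlan",
    "ChangeScore",
    "tumor_depth_mm",
    "categorize_depth",
    "score_size_change",
    "score_location_change",
]

ROTATION_CHOICES = (0, 10, 30, 45, 60, 90, 100)


class Posture(str, Enum):
    SUPINE = "supine"
    PRONE = "prone"
    LATERAL = "lateral"


class ResectionGoal(str, Enum):
    PR = "PR"          # partial resection
    STR = "STR"        # subtotal resection
    GTR = "GTR"        # gross-total resection
    SUPRA_TR = "supra_TR"


class DepthCategory(str, Enum):
    CORTEX = "cortex"
    INTERMEDIATE = "intermediate"  # margin < 2 cm below the surface
    DEEP = "deep"                  # 2-4 cm
    VERY_DEEP = "very_deep"        # > 4 cm


@dataclass(frozen=True)
class CraniotomyPlan:
    """One respondent's plan: patient posture, head rotation, craniotomy
    outline on the fixed skull-projection raster, and the resection goal."""

    posture: Posture
    side: str  # right | left
    rotation_deg: int
    craniotomy_region: np.ndarray  # 2-D bool mask
    resection_goal: ResectionGoal

    def __post_init__(self):
        if self.side not in ("right", "left"):
            raise ParameterError("side must be 'right' or 'left'")
        if self.rotation_deg not in ROTATION_CHOICES:
            raise ParameterError(f"rotation must be one of {ROTATION_CHOICES}")
        region = np.asarray(self.craniotomy_region, bool)
        if region.ndim != 2 or not region.any():
            raise ParameterError("craniotomy region must be a nonempty 2-D mask")
        object.__setattr__(self, "craniotomy_region", region)


@dataclass(frozen=True)
class ChangeScore:
    size_score: int  # 0..3
    location_score: int  # 0..2

    def __post_init__(self):
        if not (0 <= self.size_score <= 3 and 0 <= self.location_score <= 2):
            raise ParameterError("scores out of range")


def tumor_depth_mm(labelmap: LabelMap, tumor_label: int, brain_label: int) -> float:
    """Minimum distance (mm) from the tumor margin to the cortical surface.

    The cortical surface is the outer voxel shell of the brain mask (brain
    voxels with a face neighbour outside the brain); the tumor counts as at
    the surface (depth 0) when it reaches that shell. Distances respect the
    voxel spacing.
    """
    brain = labelmap.mask(brain_label) | (labelmap.labels != 0)  # structures sit inside the brain
    tumor = labelmap.mask(tumor_label)
    if not tumor.any() or not labelmap.mask(brain_label).any():
        raise EmptyStructureError("tumor and brain masks must both be nonempty")
    eroded = ndimage.binary_erosion(brain)
    shell = brain & ~eroded
    if not shell.any():
        raise EmptyStructureError("brain mask has no surface inside the grid")
    dist_to_shell = ndimage.distance_transform_edt(~shell, sampling=labelmap.spacing)
    return float(dist_to_shell[tumor].min())


def categorize_depth(depth_mm: float, touches_surface: bool = False) -> DepthCategory:
    """Bin a depth: cortex / <2 cm / 2-4 cm (inclusive) / >4 cm."""
    if depth_mm < 0:
        raise ParameterError("depth must be >= 0")
    if touches_surface or depth_mm == 0:
        return DepthCategory.CORTEX
    if depth_mm < 20.0:
        return DepthCategory.INTERMEDIATE
    if depth_mm <= 40.0:
        return DepthCategory.DEEP
    return DepthCategory.VERY_DEEP


def score_size_change(area_mr_mm2: float, area_3d_mm2: float) -> int:
    """0-3 ladder over the percent change in craniotomy area.

    Change is measured relative to the MR-based plan; 0: < 25 %,
    1: 25-50 %, 2: 50-75 %, 3: >= 75 % (changes beyond 100 % stay 3).
    """
    if area_mr_mm2 <= 0:
        raise ParameterError("MR-plan area must be > 0")
    if area_3d_mm2 < 0:
        raise ParameterError("area must be >= 0")
    change = 100.0 * abs(area_3d_mm2 - area_mr_mm2) / area_mr_mm2
    if change < 25.0:
        return 0
    if change < 50.0:
        return 1
    if change < 75.0:
        return 2
    return 3


def score_location_change(
    region_mr: np.ndarray, region_3d: np.ndarray, overlap: str = "jaccard"
) -> int:
    """0-2 ladder over the overlap of the two craniotomy outlines.

    Overlap is the Jaccard index by default (``overlap='reference'``
    normalises by the MR-plan area instead); 0: > 90 %, 1: 50-90 %,
    2: <= 50 %.
    """
    a = np.asarray(region_mr, bool)
    b = np.asarray(region_3d, bool)
    if a.shape != b.shape:
        raise ParameterError("craniotomy rasters are not congruent")
    if not a.any() or not b.any():
        raise EmptyStructureError("craniotomy masks must be nonempty")
    inter = float(np.count_nonzero(a & b))
    if overlap == "jaccard":
        denom = float(np.count_nonzero(a | b))
    elif overlap == "reference":
        denom = float(np.count_nonzero(a))
    else:
        raise ParameterError("overlap must be 'jaccard' or 'reference'")
    frac = inter / denom
    if frac > 0.90:
        return 0
    if frac > 0.50:
        return 1
    return 2
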