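"""Landmark- and outline-based forewing morphometrics.

Measurements follow the conventional pierid scheme of 19 labeled
forewing landmarks (vein endpoints; landmark 1 at the wing base,
landmark 13 at the apex, landmarks 13-19 along the outer margin) plus
digitized wing outlines and thorax dimensions.  Derived quantities:
forewing length and width, aspect ratio, outline (shoelace) wing areas,
cylindrical thoracic volume, total wing area, wing loading, and two
shape indices — the outer-edge curvature index (outer-margin polyline
length over its 13-19 chord, >= 1, near 1 for rounded wings) and the
marginal-region index (distance 1-9 over distance 1-13, in (0, 1)).

Landmarks and outlines are stored in millimetres; summary lengths are
reported in centimetres, areas in cm^2 and volumes in cm^3, with a
documented mm-based wing-loading variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from shapely.geometry import Polygon

from pierisflight.exceptions import (
    InvalidOutlineError,
    MissingLandmarkError,
    UndefinedQuantityError,
)

MM_PER_CM = 10.0
N_LANDMARKS = 19
OUTER_EDGE_IDS = (13, 14, 15, 16, 17, 18, 19)


@dataclass
class WingLandmarks:
    """One specimen's wing landmark configuration (left wing, mm).

    ``landmarks`` is a (19, 2) array indexed by landmark number - 1;
    missing landmarks are NaN rows.  A right wing digitized as fallback
    is mirrored at ingest (``mirrored`` flag) so downstream geometry is
    side-agnostic.
    """

    specimen_id: str
    landmarks: np.ndarray
    forewing_outline: np.ndarray
    hindwing_outline: np.ndarray
    thorax_length_mm: float
    thorax_width_mm: float
    scale_mm_per_px: float = 1.0
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (N_LANDMARKS, 2):
            raise ValueError("landmarks must have shape (19, 2)")
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale must be positive")
        self.forewing_outline = np.asarray(self.forewing_outline, dtype=float)
        self.hindwing_outline = np.asarray(self.hindwing_outline, dtype=float)

    def landmark(self, number: int) -> np.ndarray:
        """Landmark point by its 1-based number; raises if missing."""
        pt = self.landmarks[number - 1]
        if not np.all(np.isfinite(pt)):
            raise MissingLandmarkError(
                f"specimen {self.specimen_id}: landmark {number} missing; "
                f"specimen must be excluded")
        return pt

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.landmarks)))


@dataclass
class MorphoSummary:
    """Derived wing and body measurements for one specimen."""

    specimen_id: str
    forewing_length_cm: float
    forewing_width_cm: float
    aspect_ratio: float
    forewing_area_cm2: float
    hindwing_area_cm2: float
    thoracic_volume_cm3: float
    total_wing_area_cm2: float
    wing_loading_cm: float
    wing_loading_mm: float
    outer_edge_index: float
    marginal_region_index: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def forewing_length(lm: WingLandmarks) -> float:
    """Distance from the wing base (landmark 1) to the apex (13), cm."""
    return _dist(lm.landmark(1), lm.landmark(13)) / MM_PER_CM


def forewing_width(lm: WingLandmarks) -> float:
    """Greatest outline extent perpendicular to the 1-13 axis, cm."""
    base, apex = lm.landmark(1), lm.landmark(13)
    axis = apex - base
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise UndefinedQuantityError("coincident landmarks 1 and 13")
    perp = np.array([-axis[1], axis[0]]) / norm
    proj = (lm.forewing_outline - base) @ perp
    return float(proj.max() - proj.min()) / MM_PER_CM


def aspect_ratio(length_cm: float, width_cm: float) -> float:
    """Forewing length over maximum perpendicular width."""
    if width_cm <= 0:
        raise UndefinedQuantityError("zero forewing width")
    return length_cm / width_cm


def polygon_area(outline_mm: np.ndarray) -> float:
    """Shoelace area of a simple outline polygon, cm^2."""
    poly = Polygon(np.asarray(outline_mm, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise InvalidOutlineError("outline polygon is not simple")
    return poly.area / MM_PER_CM ** 2


def thoracic_volume(thorax_length_cm: float, thorax_width_cm: float) -> float:
    """Cylindrical thorax volume (width treated as diameter), cm^3."""
    if thorax_length_cm <= 0 or thorax_width_cm <= 0:
        raise UndefinedQuantityError("thorax dimensions must be positive")
    return math.pi * (thorax_width_cm / 2.0) ** 2 * thorax_length_cm


def total_wing_area(forewing_area_cm2: float,
                    hindwing_area_cm2: float) -> float:
    """Twice the forewing plus twice the hindwing area, cm^2."""
    if forewing_area_cm2 <= 0 or hindwing_area_cm2 <= 0:
        raise UndefinedQuantityError("wing areas must be positive")
    return 2.0 * forewing_area_cm2 + 2.0 * hindwing_area_cm2


def wing_loading(thoracic_volume_cm3: float,
                 total_area_cm2: float) -> float:
    """Thoracic volume over total wing area, cm^3/cm^2 (i.e. cm).

    The mm-based variant (mm^3/mm^2) equals this value times 10.
    """
    if total_area_cm2 <= 0:
        raise UndefinedQuantityError("zero total wing area")
    return thoracic_volume_cm3 / total_area_cm2


def outer_edge_index(lm: WingLandmarks) -> float:
    """Outer-margin polyline length (13..19) over the 13-19 chord."""
    pts = np.stack([lm.landmark(i) for i in OUTER_EDGE_IDS])
    chord = _dist(pts[0], pts[-1])
    if chord == 0:
        raise UndefinedQuantityError("coincident landmarks 13 and 19")
    poly = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return poly / chord


def marginal_region_index(lm: WingLandmarks) -> float:
    """Distance 1-9 over the straight distance 1-13."""
    denom = _dist(lm.landmark(1), lm.landmark(13))
    if denom == 0:
        raise UndefinedQuantityError("coincident landmarks 1 and 13")
    return _dist(lm.landmark(1), lm.landmark(9)) / denom


def summarize_morphology(lm: WingLandmarks) -> MorphoSummary:
    """Compute the full morphometric summary for one specimen."""
    length = forewing_length(lm)
    width = forewing_width(lm)
    fw_area = polygon_area(lm.forewing_outline)
    hw_area = polygon_area(lm.hindwing_outline)
    volume = thoracic_volume(lm.thorax_length_mm / MM_PER_CM,
                             lm.thorax_width_mm / MM_PER_CM)
    total = total_wing_area(fw_area, hw_area)
    wl = wing_loading(volume, total)
    return MorphoSummary(
        specimen_id=lm.specimen_id,
        forewing_length_cm=length,
        forewing_width_cm=width,
        aspect_ratio=aspect_ratio(length, width),
        forewing_area_cm2=fw_area,
        hindwing_area_cm2=hw_area,
        thoracic_volume_cm3=volume,
        total_wing_area_cm2=total,
        wing_loading_cm=wl,
        wing_loading_mm=wl * MM_PER_CM,
        outer_edge_index=outer_edge_index(lm),
        marginal_region_index=marginal_region_index(lm),
    )
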