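"""Domain types and geometric bookkeeping shared by all pipeline stages.

Conventions: arrays are indexed (slice, row, col), 0-based. Contours live in
continuous pixel coordinates (x = col, y = row) where integer values are
pixel centers. A voxel's footprint is pixel_spacing**2 in-plane and
(slice_thickness + slice_gap) through-plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath

from .errors import GeometryError, InputError

MODES = ("IR", "PSIR", "T1w")


@dataclass
class ImageStack:
    """A short-axis LGE stack: 3D intensities plus voxel geometry.

    Parameters
    ----------
    intensities : (n_slices, n_rows, n_cols) float array, all finite.
    pixel_spacing : in-plane spacing in mm (square pixels).
    slice_thickness : slice thickness in mm.
    slice_gap : inter-slice gap in mm (0 for contiguous stacks).
    mode : acquisition mode, one of ``IR``, ``PSIR``, ``T1w``.
    """

    intensities: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    slice_gap: float = 0.0
    mode: str = "IR"

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.shape[0] < 1:
            raise InputError("intensities must be a 3D (slice,row,col) array "
                             "with at least one slice")
        if not np.all(np.isfinite(self.intensities)):
            raise InputError("intensities must all be finite")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise InputError("pixel_spacing and slice_thickness must be > 0")
        if self.slice_gap < 0:
            raise InputError("slice_gap must be >= 0")
        if self.mode not in MODES:
            raise InputError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def geometry(self) -> "VoxelGeometry":
        return VoxelGeometry(self.pixel_spacing, self.slice_thickness,
                             self.slice_gap)

    def with_intensities(self, intensities: np.ndarray) -> "ImageStack":
        return ImageStack(intensities, self.pixel_spacing,
                          self.slice_thickness, self.slice_gap, self.mode)


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel dimensions; the through-plane extent includes any slice gap."""

    pixel_spacing: float
    slice_thickness: float
    slice_gap: float = 0.0

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        v = self.pixel_spacing ** 2 * (self.slice_thickness + self.slice_gap)
        if v <= 0:
            raise InputError("voxel volume must be positive")
        return v


def _close_polygon(poly: np.ndarray) -> np.ndarray:
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise InputError("polygon needs >= 3 (x, y) vertices")
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])
    return poly


def _points_in_polygon(points: np.ndarray, poly: np.ndarray,
                       include_boundary: bool) -> np.ndarray:
    """Pixel-center point-in-polygon test via matplotlib Path.

    ``radius`` nudges the boundary: positive includes points lying exactly on
    the edge, negative excludes them.
    """
    path = _MplPath(_close_polygon(poly))
    r = 1e-9 if include_boundary else -1e-9
    return path.contains_points(points, radius=r)


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area (absolute value) of a closed polygon."""
    p = _close_polygon(poly)
    x, y = p[:-1, 0], p[:-1, 1]
    x2, y2 = p[1:, 0], p[1:, 1]
    return abs(float(np.sum(x * y2 - x2 * y)) / 2.0)


def rasterize_contours(endo: np.ndarray, epi: np.ndarray,
                       grid_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an endo/epi contour pair into a myocardium mask.

    A pixel center belongs to the myocardium when it is inside (or on) the
    epicardial contour and outside-or-on the endocardial contour; points on
    either boundary count as myocardium, which maximizes the myocardial mask
    consistently across slices.

    Parameters
    ----------
    endo, epi : (N, 2) arrays of (x, y) vertices, closed or open (the first
        vertex is reused to close an open ring).
    grid_shape : (n_rows, n_cols) of the target slice.

    Returns
    -------
    (n_rows, n_cols) boolean mask.
    """
    endo = _close_polygon(endo)
    epi = _close_polygon(epi)
    if polygon_area(endo) >= polygon_area(epi):
        raise GeometryError("endocardial contour must be strictly inside "
                            "the epicardial contour")
    # endo must lie inside epi: every endo vertex inside-or-on epi
    if not np.all(_points_in_polygon(endo[:-1], epi, include_boundary=True)):
        raise GeometryError("endocardial contour is not inside the "
                            "epicardial contour")
    nr, nc = grid_shape
    cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    in_epi = _points_in_polygon(pts, epi, include_boundary=True)
    in_endo_strict = _points_in_polygon(pts, endo, include_boundary=False)
    mask = in_epi & ~in_endo_strict
    return mask.reshape(nr, nc)


@dataclass
class LVSegmentation:
    """Per-slice LV contours with the derived myocardial mask.

    ``endo`` / ``epi`` map slice index -> (N, 2) vertex array; slices without
    contours carry no myocardium. ``lv_center`` is the per-slice centroid of
    the endocardial vertices (used as the bulls-eye rotation center).
    """

    endo: dict[int, np.ndarray]
    epi: dict[int, np.ndarray]
    myocardium_mask: np.ndarray
    lv_center: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.myocardium_mask = np.asarray(self.myocardium_mask, dtype=bool)
        if self.myocardium_mask.ndim != 3:
            raise InputError("myocardium_mask must be 3D")
        if not self.myocardium_mask.any():
            raise InputError("myocardial mask is empty")
        if not self.lv_center:
            self.lv_center = {
                s: (float(np.mean(np.asarray(c)[:, 0])),
                    float(np.mean(np.asarray(c)[:, 1])))
                for s, c in self.endo.items()
            }

    @classmethod
    def from_contours(cls, endo: dict[int, np.ndarray],
                      epi: dict[int, np.ndarray],
                      grid_shape: tuple[int, int, int]) -> "LVSegmentation":
        """Build the 3D myocardial mask by rasterizing each contoured slice."""
        mask = np.zeros(grid_shape, dtype=bool)
        for s in sorted(endo):
            if s not in epi:
                raise InputError(f"slice {s} has endo but no epi contour")
            mask[s] = rasterize_contours(endo[s], epi[s], grid_shape[1:])
        return cls(endo=endo, epi=epi, myocardium_mask=mask)

    def endo_interior_mask(self) -> np.ndarray:
        """Pixels strictly inside the endocardial contour (the LV cavity)."""
        shape = self.myocardium_mask.shape
        mask = np.zeros(shape, dtype=bool)
        nr, nc = shape[1:]
        cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
        pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
        for s, c in self.endo.items():
            inside = _points_in_polygon(pts, np.asarray(c),
                                        include_boundary=False)
            mask[s] = inside.reshape(nr, nc)
        return mask

    def blood_pool_mask(self) -> np.ndarray:
        """Endocardial interior eroded by one pixel.

        The erosion keeps partial-volume pixels at the endocardial border out
        of the blood-pool intensity sample used for coil correction.
        """
        from scipy.ndimage import binary_erosion
        interior = self.endo_interior_mask()
        mask = np.zeros_like(interior)
        for s in range(interior.shape[0]):
            mask[s] = binary_erosion(interior[s])
        return mask


def myocardial_volume(seg: LVSegmentation, geom: VoxelGeometry) -> float:
    """Myocardial volume in mm^3 (voxel count times voxel volume).

    LV mass is proportional to this volume; the density constant cancels in
    every %LVM ratio, so volume stands in for mass throughout.
    """
    n = int(np.count_nonzero(seg.myocardium_mask))
    if n == 0:
        raise InputError("myocardial mask is empty")
    return n * geom.voxel_volume


@dataclass
class InfarctResult:
    """Final pipeline output: masks, per-voxel weights and size in %LVM."""

    core_mask: np.ndarray
    mvo_mask: np.ndarray
    weight_map: np.ndarray
    infarct_pct_lvm: float
    core_pct_lvm: float = 0.0
    mvo_volume_ml: float = 0.0
    threshold: float = float("nan")
    em_params: dict | None = None

    def __post_init__(self):
        self.core_mask = np.asarray(self.core_mask, dtype=bool)
        self.mvo_mask = np.asarray(self.mvo_mask, dtype=bool)
        self.weight_map = np.asarray(self.weight_map, dtype=float)
        if not (0.0 <= self.infarct_pct_lvm <= 100.0):
            raise InputError("infarct_pct_lvm must lie in [0, 100]")
        outside = ~(self.core_mask | self.mvo_mask)
        if np.any(self.weight_map[outside] != 0):
            raise InputError("weights must be 0 outside core and MVO")
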