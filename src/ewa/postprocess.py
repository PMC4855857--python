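"""Artifact removal (step 5): culprit-territory filter and size filter."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import label

from .errors import ConsistencyError, InputError
from .core import VoxelGeometry
from .sectors import MaxExtentModel, SectorAssignment

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

SMALL_REGION_MM3 = 1500.0  # 1.5 cm^3
SMALL_REGION_PCT_LVM = 1.0


def filter_culprit(infarct_mask: np.ndarray, assign: SectorAssignment,
                   model: MaxExtentModel | None) -> np.ndarray:
    """Drop infarct voxels outside the culprit artery's maximal territory.

    Bright artifacts (e.g. slow-flow blood, fold-over) land outside the
    perfusion territory of the occluded artery and cannot be true infarct.
    With no model (experimental mode: non-human anatomy, or no culprit
    known) the mask passes through unchanged.
    """
    infarct_mask = np.asarray(infarct_mask, dtype=bool)
    if model is None:
        return infarct_mask.copy()
    if np.any(infarct_mask & ~assign.myocardium_mask):
        raise ConsistencyError("infarct voxels without a sector assignment")
    territory = assign.cell_mask(model.included)
    return infarct_mask & territory


def remove_small_regions(infarct_mask: np.ndarray, geom: VoxelGeometry,
                         lv_volume_mm3: float,
                         min_volume_mm3: float = SMALL_REGION_MM3,
                         max_pct_lvm: float = SMALL_REGION_PCT_LVM
                         ) -> np.ndarray:
    """Drop small isolated infarct components.

    A connected component (3D, 26-connectivity, so transmural regions
    spanning slices stay whole) is removed when its volume is below 1.5 cm^3
    AND it comprises no more than 1% of the LV mass — unless it is the only
    component, which is always kept (a small infarct is still an infarct).
    """
    infarct_mask = np.asarray(infarct_mask, dtype=bool)
    if lv_volume_mm3 <= 0:
        raise InputError("LV volume must be positive")
    if not infarct_mask.any():
        return infarct_mask.copy()
    lbl, n = label(infarct_mask, structure=_STRUCT26)
    if n == 1:
        return infarct_mask.copy()
    keep = np.zeros_like(infarct_mask)
    for k in range(1, n + 1):
        comp = lbl == k
        vol = comp.sum() * geom.voxel_volume
        pct = 100.0 * vol / lv_volume_mm3
        if vol >= min_volume_mm3 or pct > max_pct_lvm:
            keep |= comp
    if not keep.any():
        # every region is small: keep the largest (the only-region clause
        # generalized so a non-empty input never empties entirely)
        sizes = np.bincount(lbl.ravel())[1:]
        keep = lbl == (int(np.argmax(sizes)) + 1)
    return keep
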