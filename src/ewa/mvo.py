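"""Microvascular-obstruction detection (step 4).

MVO is a hypointense core inside acute infarcts where contrast cannot
penetrate; by intensity alone it looks like normal myocardium, so it is
recovered geometrically, slice by slice: a dark (non-core) myocardial
component counts as MVO when every escape route is blocked by infarct or by
the endocardial border (flood fill cannot reach remote myocardium from it).
A morphological closing pass (dilate the core with a 3x3 cross kernel,
re-run the flood fill, then erode back) additionally seals holes whose rim
has 1-pixel gaps.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_dilation, label

from .errors import ConsistencyError, InputError

CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT4 = CROSS  # 4-connectivity for hole components
_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity for core


def _holes_on_slice(core: np.ndarray, myo: np.ndarray,
                    endo_adjacent: np.ndarray) -> np.ndarray:
    """Dark components sealed by core and/or the endocardial border.

    Non-core myocardial voxels are labeled with 4-connectivity. A component
    is a hole when none of its voxels touches (4-adjacency) a non-core
    myocardial voxel outside itself... which cannot happen within one
    label, so the escape test is: the component must not touch the
    epicardial side of the myocardium boundary except through core, i.e.
    every 4-neighbor outside the component is core, outside the myocardium
    only if the voxel is endocardium-adjacent, or outside the image.

    Operationally: flood fill the non-core myocardium; a component is NOT a
    hole when it contains a voxel that borders non-myocardium without being
    endocardium-adjacent (an epicardial or out-of-plane escape).
    """
    dark = myo & ~core
    if not dark.any():
        return np.zeros_like(core)
    lbl, n = label(dark, structure=_STRUCT4)
    holes = np.zeros_like(core)
    # voxels adjacent (4-conn) to outside-the-myocardium positions
    outside = ~myo
    touches_outside = binary_dilation(outside, _STRUCT4) & dark
    # an escape voxel borders the outside but not via the blood pool
    escape = touches_outside & ~endo_adjacent
    for k in range(1, n + 1):
        comp = lbl == k
        if not (comp & escape).any():
            holes |= comp
    return holes


def detect_mvo(core: np.ndarray, myo: np.ndarray,
               endo_adjacent: np.ndarray) -> np.ndarray:
    """Detect MVO on one slice.

    Three passes: (a) flood-fill holes in the raw core; (b) close the core
    (dilate with the 3x3 cross), re-run the flood fill to catch holes whose
    rim had small gaps, erode back; (c) return the union of both hole sets,
    minus the core. ``endo_adjacent`` marks myocardial voxels 4-adjacent to
    the blood pool (the endocardial border); a dark band sealed between the
    border and an infarct arc counts as MVO.
    """
    core = np.asarray(core, dtype=bool)
    myo = np.asarray(myo, dtype=bool)
    endo_adjacent = np.asarray(endo_adjacent, dtype=bool)
    if core.ndim != 2 or core.shape != myo.shape or \
            core.shape != endo_adjacent.shape:
        raise InputError("detect_mvo expects aligned 2D slice masks")
    if not core.any():
        return np.zeros_like(core)

    holes_a = _holes_on_slice(core, myo, endo_adjacent)

    # morphological closing pass: seal 1-pixel gaps in the infarct rim
    dilated = binary_dilation(core, CROSS) & myo
    holes_b = _holes_on_slice(dilated, myo, endo_adjacent)
    # the erosion restores the core; holes found at the dilated stage are
    # kept only where they are dark in the original (not under the dilation)
    holes_b &= ~core

    mvo = (holes_a | holes_b) & ~core & myo
    return mvo


def detect_mvo_stack(core: np.ndarray, myo: np.ndarray,
                     endo_adjacent: np.ndarray) -> np.ndarray:
    """Slice-by-slice MVO detection over a 3D stack (no 3D bridging)."""
    out = np.zeros_like(np.asarray(core, dtype=bool))
    for z in range(out.shape[0]):
        out[z] = detect_mvo(core[z], myo[z], endo_adjacent[z])
    return out


def merge_infarct(core: np.ndarray, mvo: np.ndarray) -> np.ndarray:
    """Union of core and MVO; MVO voxels later receive weight 1.

    The masks must be disjoint (MVO is by construction outside the core).
    """
    core = np.asarray(core, dtype=bool)
    mvo = np.asarray(mvo, dtype=bool)
    if (core & mvo).any():
        raise ConsistencyError("core and MVO masks overlap")
    return core | mvo


def endo_adjacent_mask(myo_mask: np.ndarray,
                       blood_mask: np.ndarray) -> np.ndarray:
    """Myocardial voxels 4-adjacent (in-plane) to the blood pool."""
    out = np.zeros_like(np.asarray(myo_mask, dtype=bool))
    for z in range(out.shape[0]):
        out[z] = binary_dilation(blood_mask[z], _STRUCT4) & myo_mask[z]
    return out
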