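"""Extended bulls-eye sector model and per-artery maximal-extent territories.

The left ventricle is divided into 9 rings (3 basal, 3 mid-ventricular,
3 apical; ring 9 is most apical) and 24 equal 15-degree sectors per slice,
an extension of the AHA 17-segment layout. Sector 1 starts at the anterior
RV insertion angle and indices increase through the septum toward the
inferior insertion, so septal sectors carry low indices. Each culprit
artery (LAD, LCx, RCA, or LM = union of the three) has a maximal-extent
model: the set of (ring, sector) cells its perfusion territory can reach.
Myocardium outside the culprit model is "remote" and serves as the
normal-intensity reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .core import LVSegmentation
from .errors import InputError

N_RINGS = 9
N_SECTORS = 24
ARTERIES = ("LAD", "LCx", "RCA", "LM")


@dataclass(frozen=True)
class InsertionPoints:
    """Anterior and inferior RV insertion points, (x, y) pixel coordinates.

    One pair orients the whole stack; the two points must be distinct.
    """

    anterior: tuple[float, float]
    inferior: tuple[float, float]

    def __post_init__(self):
        if np.allclose(self.anterior, self.inferior):
            raise InputError("insertion points must be distinct")


@dataclass
class SectorAssignment:
    """Per-voxel (ring, sector) labels over the myocardium.

    ``ring`` and ``sector`` are int arrays shaped like the mask, 1-based
    inside the myocardium and 0 outside.
    """

    ring: np.ndarray
    sector: np.ndarray
    myocardium_mask: np.ndarray

    def cell_mask(self, included: np.ndarray) -> np.ndarray:
        """Boolean voxel mask of cells flagged in a (9, 24) inclusion grid."""
        out = np.zeros_like(self.myocardium_mask, dtype=bool)
        m = self.myocardium_mask
        out[m] = included[self.ring[m] - 1, self.sector[m] - 1]
        return out


@dataclass
class MaxExtentModel:
    """Maximal perfusion territory of one culprit artery.

    ``included`` is a (9 rings, 24 sectors) boolean grid; True cells can
    contain infarct for this artery.
    """

    artery: str
    included: np.ndarray

    def __post_init__(self):
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != (N_RINGS, N_SECTORS):
            raise InputError("extent model must be a 9x24 grid")
        if not self.included.any():
            raise InputError("extent model must include at least one sector")
        if self.artery not in ARTERIES:
            raise InputError(f"artery must be one of {ARTERIES}")


def slice_to_ring(n_slices: int) -> np.ndarray:
    """Map slice indices (base first) to rings 1..9, proportionally.

    With 9 slices the map is the identity. Otherwise slice s covers the
    stack fraction [s/n, (s+1)/n) and is assigned the ring whose ninth of
    the long axis contains the slice midpoint: ring = floor(9*(s+0.5)/n)+1.
    Every slice is mapped; stacks shorter than 9 slices merge rings, longer
    stacks share rings among slices.
    """
    if n_slices < 1:
        raise InputError("need at least one slice")
    mid = (np.arange(n_slices) + 0.5) / n_slices
    return np.minimum((mid * N_RINGS).astype(int), N_RINGS - 1) + 1


def assign_sectors(seg: LVSegmentation,
                   ins: InsertionPoints) -> SectorAssignment:
    """Assign every myocardial voxel a (ring, sector) bulls-eye cell.

    Sectors are half-open 15-degree bins starting at the anterior insertion
    angle, advancing in the rotational direction that reaches the inferior
    insertion first (so the septum, between the two insertions, gets the low
    sector indices). Angles are measured per slice around the endocardial
    centroid; a voxel exactly on the anterior insertion angle falls in
    sector 1.
    """
    mask = seg.myocardium_mask
    n_slices = mask.shape[0]
    rings = slice_to_ring(n_slices)
    ring = np.zeros(mask.shape, dtype=int)
    sector = np.zeros(mask.shape, dtype=int)

    for s in range(n_slices):
        if not mask[s].any():
            continue
        cx, cy = seg.lv_center.get(s, _mask_centroid(mask[s]))
        ax, ay = ins.anterior
        ix, iy = ins.inferior
        a0 = np.arctan2(ay - cy, ax - cx)
        a1 = np.arctan2(iy - cy, ix - cx)
        # direction: go from anterior toward inferior along the shorter arc
        delta = (a1 - a0) % (2 * np.pi)
        direction = 1.0 if delta <= np.pi else -1.0

        rr, cc = np.nonzero(mask[s])
        theta = np.arctan2(rr - cy, cc - cx)
        rel = (direction * (theta - a0)) % (2 * np.pi)
        sec = (rel / (2 * np.pi) * N_SECTORS).astype(int)
        sec = np.clip(sec, 0, N_SECTORS - 1) + 1
        sector[s][rr, cc] = sec
        ring[s][rr, cc] = rings[s]

    return SectorAssignment(ring=ring, sector=sector, myocardium_mask=mask)


def _mask_centroid(m2d: np.ndarray) -> tuple[float, float]:
    rr, cc = np.nonzero(m2d)
    return float(cc.mean()), float(rr.mean())


def remote_mask(assign: SectorAssignment,
                model: MaxExtentModel) -> np.ndarray:
    """Myocardial voxels outside the culprit artery's maximal territory."""
    culprit = assign.cell_mask(model.included)
    remote = assign.myocardium_mask & ~culprit
    if not remote.any():
        raise InputError("extent model covers the whole myocardium; "
                         "no remote reference remains")
    return remote


def _grid_from_cells(cells) -> np.ndarray:
    grid = np.zeros((N_RINGS, N_SECTORS), dtype=bool)
    for ring, sec in cells:
        if not (1 <= ring <= N_RINGS and 1 <= sec <= N_SECTORS):
            raise InputError(f"cell ({ring}, {sec}) outside the 9x24 grid")
        grid[ring - 1, sec - 1] = True
    return grid


def _models_from_dict(data: dict) -> dict[str, MaxExtentModel]:
    for artery in ("LAD", "LCx", "RCA"):
        if artery not in data:
            raise InputError(f"extent-model config is missing {artery}")
    models = {
        a: MaxExtentModel(a, _grid_from_cells(data[a]))
        for a in ("LAD", "LCx", "RCA")
    }
    lm_grid = (models["LAD"].included | models["LCx"].included
               | models["RCA"].included)
    if "LM" in data:
        given = _grid_from_cells(data["LM"])
        if not np.array_equal(given, lm_grid):
            raise InputError("LM model must equal the union of LAD, LCx "
                             "and RCA")
    models["LM"] = MaxExtentModel("LM", lm_grid)
    return models


def load_extent_models(path) -> dict[str, MaxExtentModel]:
    """Load per-artery extent models from a YAML config.

    Schema: ``{artery: [[ring, sector], ...]}`` with 1-based indices. LAD,
    LCx and RCA are required; LM, if present, must equal their union and is
    otherwise derived.
    """
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise InputError(f"cannot parse extent-model config: {e}") from e
    if not isinstance(data, dict):
        raise InputError("extent-model config must be a mapping "
                         "{artery: [[ring, sector], ...]}")
    return _models_from_dict(data)


def save_extent_models(models: dict[str, MaxExtentModel], path) -> None:
    data = {
        a: [[int(r) + 1, int(s) + 1]
            for r, s in zip(*np.nonzero(m.included))]
        for a, m in models.items() if a != "LM"
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def default_extent_models() -> dict[str, MaxExtentModel]:
    """Bundled default territories.

    Qualitative layout: LAD covers the anteroseptal and anterior wall and
    dominates the apex; RCA covers the inferoseptal and inferior wall; LCx
    covers the lateral wall. These defaults are replaceable configuration,
    not validated anatomy.
    """
    ref = resources.files("ewa").joinpath("data/extent_models.yaml")
    with resources.as_file(ref) as p:
        return load_extent_models(p)
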