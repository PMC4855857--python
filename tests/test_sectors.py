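import numpy as np
import pytest

import ewa
from ewa.errors import InputError
from ewa.sectors import (N_RINGS, N_SECTORS, default_extent_models,
                         load_extent_models, save_extent_models,
                         slice_to_ring)
from tests.conftest import annulus_segmentation


def make_ins(c=23.5, r=20.0):
    """Anterior at -135 deg, inferior at +135 deg around center (c, c)."""
    return ewa.InsertionPoints(
        anterior=(c + r * np.cos(np.radians(-135)),
                  c + r * np.sin(np.radians(-135))),
        inferior=(c + r * np.cos(np.radians(135)),
                  c + r * np.sin(np.radians(135))),
    )


class TestRingMapping:
    def test_nine_slices_identity(self):
        assert slice_to_ring(9).tolist() == list(range(1, 10))

    def test_six_slices_proportional(self):
        # midpoints at 1/12, 3/12, ... -> rings floor(9*mid)+1
        assert slice_to_ring(6).tolist() == [1, 3, 4, 6, 7, 9]

    def test_every_slice_mapped_for_any_count(self):
        for n in range(1, 30):
            r = slice_to_ring(n)
            assert len(r) == n and r.min() >= 1 and r.max() <= 9
            assert (np.diff(r) >= 0).all()


class TestAssignSectors:
    def test_bin_center_voxels_unique_cells(self):
        # 9 slices, 24 voxels per slice placed at sector bin centers
        grid, c, rad = 48, 23.5, 12.0
        mask = np.zeros((9, grid, grid), dtype=bool)
        ins = make_ins()
        a0 = np.radians(-135)
        # direction -1 (through the septum on the left)
        centers = a0 - (np.arange(24) + 0.5) * np.radians(15)
        rr = np.round(c + rad * np.sin(centers)).astype(int)
        cc = np.round(c + rad * np.cos(centers)).astype(int)
        for s in range(9):
            mask[s, rr, cc] = True
        seg = annulus_segmentation(9, grid)
        seg.myocardium_mask = mask
        seg.lv_center = {s: (c, c) for s in range(9)}
        assign = ewa.assign_sectors(seg, ins)
        cells = set()
        for s in range(9):
            for r_, c_ in zip(rr, cc):
                cells.add((assign.ring[s, r_, c_], assign.sector[s, r_, c_]))
        assert len(cells) == 9 * 24

    def test_anterior_insertion_angle_is_sector_1(self):
        grid, c = 48, 23.5
        mask = np.zeros((1, grid, grid), dtype=bool)
        ins = make_ins()
        # voxel exactly along the anterior insertion direction
        r_, c_ = 12, 12  # (x-c, y-c) = (-11.5, -11.5): angle -135 deg
        mask[0, r_, c_] = True
        seg = annulus_segmentation(1, grid)
        seg.myocardium_mask = mask
        seg.lv_center = {0: (c, c)}
        assign = ewa.assign_sectors(seg, ins)
        assert assign.sector[0, r_, c_] == 1

    def test_rotation_equivariance_90deg(self, small_seg):
        ins = make_ins()
        a1 = ewa.assign_sectors(small_seg, ins)
        # rotate the grid by 90 deg: (r, c) -> (c, N-1-r); x' = N-1-y, y' = x
        n = small_seg.myocardium_mask.shape[1]
        rot_mask = np.stack([np.rot90(small_seg.myocardium_mask[s], -1)
                             for s in range(3)])
        seg2 = annulus_segmentation()
        seg2.myocardium_mask = rot_mask
        c = (n - 1) / 2
        seg2.lv_center = {s: (c, c) for s in range(3)}

        def rot_pt(p):
            return (n - 1 - p[1], p[0])

        ins2 = ewa.InsertionPoints(rot_pt(ins.anterior), rot_pt(ins.inferior))
        a2 = ewa.assign_sectors(seg2, ins2)
        for s in range(3):
            sec1 = a1.sector[s]
            sec2 = a2.sector[s]
            rr, cc = np.nonzero(small_seg.myocardium_mask[s])
            # skip voxels within numerical reach of a 15-degree bin edge
            cx, cy = (n - 1) / 2, (n - 1) / 2
            th = (np.degrees(np.arctan2(rr - cy, cc - cx)) + 135.0) % 15.0
            ok = (np.minimum(th, 15.0 - th) > 1e-6)
            v1 = sec1[rr[ok], cc[ok]]
            v2 = sec2[cc[ok], n - 1 - rr[ok]]
            assert (v1 == v2).all()

    def test_coincident_insertions_rejected(self):
        with pytest.raises(InputError):
            ewa.InsertionPoints((1.0, 2.0), (1.0, 2.0))


class TestRemoteMask:
    def test_half_annulus_model(self, small_seg):
        assign = ewa.assign_sectors(small_seg, make_ins())
        grid = np.zeros((N_RINGS, N_SECTORS), dtype=bool)
        grid[:, :12] = True
        model = ewa.MaxExtentModel("LAD", grid)
        remote = ewa.remote_mask(assign, model)
        n_myo = small_seg.myocardium_mask.sum()
        assert abs(remote.sum() / n_myo - 0.5) < 0.05

    def test_partition_property(self, small_seg):
        assign = ewa.assign_sectors(small_seg, make_ins())
        model = default_extent_models()["LAD"]
        remote = ewa.remote_mask(assign, model)
        culprit = assign.cell_mask(model.included)
        assert not (remote & culprit).any()
        assert ((remote | culprit) == small_seg.myocardium_mask).all()

    def test_lm_remote_subset_of_lad_remote(self, small_seg):
        assign = ewa.assign_sectors(small_seg, make_ins())
        models = default_extent_models()
        rem_lm = ewa.remote_mask(assign, models["LM"])
        rem_lad = ewa.remote_mask(assign, models["LAD"])
        assert (rem_lm <= rem_lad).all()

    def test_full_model_rejected(self, small_seg):
        assign = ewa.assign_sectors(small_seg, make_ins())
        full = ewa.MaxExtentModel("LAD", np.ones((9, 24), dtype=bool))
        with pytest.raises(InputError):
            ewa.remote_mask(assign, full)


class TestExtentModels:
    def test_defaults_valid_and_lm_is_union(self):
        models = default_extent_models()
        assert set(models) == {"LAD", "LCx", "RCA", "LM"}
        union = (models["LAD"].included | models["LCx"].included
                 | models["RCA"].included)
        assert (models["LM"].included == union).all()

    def test_missing_artery_rejected(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text("LAD: [[1, 1]]\nLCx: [[1, 2]]\n")
        with pytest.raises(InputError):
            load_extent_models(p)

    def test_roundtrip(self, tmp_path):
        models = default_extent_models()
        p = tmp_path / "m.yaml"
        save_extent_models(models, p)
        again = load_extent_models(p)
        for a in models:
            assert (models[a].included == again[a].included).all()
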