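import numpy as np
import pytest

import ewa
from ewa.comparators import (threshold_em_pure, threshold_fwhm_min,
                             threshold_fwhm_remote, threshold_nsd,
                             threshold_otsu)
from ewa.errors import DegenerateInputError


def gaussian_stack(mu=50.0, sd=5.0, shape=(2, 30, 30), seed=0):
    rng = np.random.default_rng(seed)
    img = rng.normal(mu, sd, shape)
    myo = np.ones(shape, dtype=bool)
    return img, myo


class TestNSD:
    def test_gaussian_tail_fractions(self):
        img, myo = gaussian_stack(seed=1)
        r2 = threshold_nsd(img, myo, myo, 2)
        r3 = threshold_nsd(img, myo, myo, 3)
        # theoretical upper tails: 2.3% and 0.13%
        assert r2.pct_lvm == pytest.approx(2.3, abs=1.0)
        assert r3.pct_lvm == pytest.approx(0.13, abs=0.3)

    def test_nested_masks(self):
        img, myo = gaussian_stack(seed=2)
        masks = [threshold_nsd(img, myo, myo, n).mask for n in (2, 3, 5)]
        assert (masks[2] <= masks[1]).all()
        assert (masks[1] <= masks[0]).all()

    def test_constant_remote_rejected(self):
        img = np.ones((1, 10, 10))
        myo = np.ones_like(img, dtype=bool)
        with pytest.raises(DegenerateInputError):
            threshold_nsd(img, myo, myo, 2)


class TestFWHM:
    def test_min_variant_halfway_threshold(self):
        img = np.linspace(0, 100, 100).reshape(1, 10, 10)
        myo = np.ones_like(img, dtype=bool)
        r = threshold_fwhm_min(img, myo)
        assert r.threshold == pytest.approx(50.0)

    def test_min_variant_affine_invariant_mask(self):
        img, myo = gaussian_stack(seed=3)
        m1 = threshold_fwhm_min(img, myo).mask
        m2 = threshold_fwhm_min(4.0 * img - 11.0, myo).mask
        assert np.array_equal(m1, m2)

    def test_remote_variant_threshold(self):
        img = np.zeros((1, 10, 10))
        img[0, 0, 0] = 100.0
        myo = np.ones_like(img, dtype=bool)
        remote = np.ones_like(img, dtype=bool)
        remote[0, 0, 0] = False
        r = threshold_fwhm_remote(img, myo, remote)
        assert r.threshold == pytest.approx(50.0)

    def test_remote_variant_degenerate_rejected(self):
        img = np.full((1, 10, 10), 7.0)
        myo = np.ones_like(img, dtype=bool)
        with pytest.raises(DegenerateInputError):
            threshold_fwhm_remote(img, myo, myo)

    def test_remote_variant_warns_on_ir(self):
        img = np.zeros((1, 10, 10))
        img[0, 0, 0] = 100.0
        myo = np.ones_like(img, dtype=bool)
        with pytest.warns(UserWarning, match="PSIR"):
            threshold_fwhm_remote(img, myo, myo, mode="IR")


class TestOtsu:
    def test_two_clusters_separated_exactly(self):
        img = np.zeros((1, 10, 10))
        img[0, 5:, :] = 100.0
        myo = np.ones_like(img, dtype=bool)
        r = threshold_otsu(img, myo)
        assert 0 < r.threshold < 100
        assert r.mask.sum() == 50

    def test_matches_brute_force_between_class_variance(self):
        img, myo = gaussian_stack(seed=4)
        img[0] += 30.0  # bimodal-ish
        r = threshold_otsu(img, myo)
        vals = img[myo]
        # exhaustive search over the same 256-bin boundaries
        hist, edges = np.histogram(vals, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best, best_t = -1.0, None
        csum = np.cumsum(hist)
        cmean = np.cumsum(hist * centers)
        total, grand = csum[-1], cmean[-1]
        for k in range(1, 256):
            w0, w1 = csum[k - 1], total - csum[k - 1]
            if w0 == 0 or w1 == 0:
                continue
            m0, m1 = cmean[k - 1] / w0, (grand - cmean[k - 1]) / w1
            bc = w0 * w1 * (m0 - m1) ** 2
            if bc > best:
                best, best_t = bc, centers[k - 1:k + 1].mean()
        assert abs(r.threshold - best_t) <= (edges[1] - edges[0])

    def test_constant_rejected(self):
        img = np.ones((1, 10, 10))
        with pytest.raises(DegenerateInputError):
            threshold_otsu(img, np.ones_like(img, dtype=bool))


class TestEMPure:
    def test_mask_is_cut_at_tstar(self, default_phantom):
        img, seg, ins, truth = default_phantom
        myo = seg.myocardium_mask
        r = threshold_em_pure(img.intensities, myo)
        assert np.array_equal(r.mask, myo & (img.intensities > r.threshold))

    def test_equals_pipeline_core_with_zero_smoothing(self, default_phantom):
        # the plain EM cut is the pipeline's core before MVO/post-processing
        # when the level set runs without curvature smoothing
        img, seg, ins, truth = default_phantom
        myo = seg.myocardium_mask
        r = threshold_em_pure(img.intensities, myo)
        pair = ewa.em_fit(img.intensities[myo])
        sp = ewa.build_speed(img.intensities, myo, pair.threshold)
        core = ewa.segment_core(sp, smoothing=0.0)
        assert np.array_equal(core, r.mask)

    def test_pure_noise_yields_nonzero_mask(self):
        img, myo = gaussian_stack(seed=5)
        r = threshold_em_pure(img, myo)
        assert r.mask.sum() > 0  # documented comparator behavior
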