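"""Reference infarct-threshold methods for benchmarking.

The classical alternatives to the EM pipeline: n-SD from remote (infarct =
intensity above remote mean + n standard deviations), FWHM from the
myocardial minimum or from the remote mean (half-way to the maximum), Otsu's
histogram threshold, and the plain EM cut (the EM threshold without level
set, MVO or weighting). All comparator sizes are unweighted binary %LVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu as _skimage_otsu

from .em import EMConstraints, em_fit
from .errors import DegenerateInputError, InputError


@dataclass
class ThresholdResult:
    """A comparator's binary mask, threshold and unweighted size."""

    method: str
    threshold: float
    mask: np.ndarray
    pct_lvm: float


def _finish(method: str, t: float, intensities, myo_mask) -> ThresholdResult:
    myo_mask = np.asarray(myo_mask, dtype=bool)
    mask = np.zeros(myo_mask.shape, dtype=bool)
    mask[myo_mask] = np.asarray(intensities, dtype=float)[myo_mask] > t
    pct = 100.0 * mask.sum() / myo_mask.sum()
    return ThresholdResult(method, float(t), mask, float(pct))


def threshold_nsd(intensities: np.ndarray, myo_mask: np.ndarray,
                  remote_mask: np.ndarray, n: float) -> ThresholdResult:
    """Infarct = intensity above remote mean + n * remote SD.

    On purely Gaussian remote intensities the expected flagged fraction is
    the upper-tail mass: ~2.3% at n=2 and ~0.13% at n=3.
    """
    remote_mask = np.asarray(remote_mask, dtype=bool)
    if not remote_mask.any():
        raise InputError("remote mask is empty")
    vals = np.asarray(intensities, dtype=float)[remote_mask]
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sd == 0:
        raise DegenerateInputError("remote intensities have zero spread")
    t = float(vals.mean()) + n * sd
    return _finish(f"{n:g}sd", t, intensities, myo_mask)


def threshold_fwhm_min(intensities: np.ndarray,
                       myo_mask: np.ndarray) -> ThresholdResult:
    """FWHM threshold anchored at the myocardial minimum.

    t = I_min + (I_max - I_min)/2 over the myocardium; invariant to affine
    intensity rescaling. This global-extrema reading is simpler than the
    original region-growing formulation and is flagged as an approximation.
    """
    myo_mask = np.asarray(myo_mask, dtype=bool)
    vals = np.asarray(intensities, dtype=float)[myo_mask]
    if np.ptp(vals) == 0:
        raise DegenerateInputError("constant myocardial intensities")
    t = float(vals.min() + 0.5 * (vals.max() - vals.min()))
    return _finish("fwhm-min", t, intensities, myo_mask)


def threshold_fwhm_remote(intensities: np.ndarray, myo_mask: np.ndarray,
                          remote_mask: np.ndarray,
                          mode: str = "PSIR") -> ThresholdResult:
    """FWHM threshold anchored at the remote mean.

    t = mu_remote + (I_max - mu_remote)/2. Designed for PSIR images, where
    remote myocardium keeps a meaningful signed mean; on magnitude IR images
    the nulled-remote mean is noise-dominated, so a warning is issued.
    """
    remote_mask = np.asarray(remote_mask, dtype=bool)
    myo_mask = np.asarray(myo_mask, dtype=bool)
    if not remote_mask.any():
        raise InputError("remote mask is empty")
    mu_r = float(np.asarray(intensities, dtype=float)[remote_mask].mean())
    i_max = float(np.asarray(intensities, dtype=float)[myo_mask].max())
    if i_max <= mu_r:
        raise DegenerateInputError("maximal myocardial intensity does not "
                                   "exceed the remote mean")
    if mode == "IR":
        warnings.warn("FWHM-from-remote was designed for PSIR images; "
                      "IR-mode results may be unreliable", stacklevel=2)
    t = mu_r + 0.5 * (i_max - mu_r)
    return _finish("fwhm-remote", t, intensities, myo_mask)


def threshold_otsu(intensities: np.ndarray,
                   myo_mask: np.ndarray) -> ThresholdResult:
    """Otsu's threshold: maximal between-class variance on a 256-bin
    histogram of the myocardial intensities."""
    myo_mask = np.asarray(myo_mask, dtype=bool)
    vals = np.asarray(intensities, dtype=float)[myo_mask]
    if np.unique(vals).size < 2:
        raise DegenerateInputError("need >= 2 distinct intensities")
    t = float(_skimage_otsu(vals, nbins=256))
    return _finish("otsu", t, intensities, myo_mask)


def threshold_em_pure(intensities: np.ndarray, myo_mask: np.ndarray,
                      constraints: EMConstraints = EMConstraints()
                      ) -> ThresholdResult:
    """Plain EM threshold: binary cut at t*, no level set/MVO/weighting."""
    myo_mask = np.asarray(myo_mask, dtype=bool)
    pair = em_fit(np.asarray(intensities, dtype=float)[myo_mask], constraints)
    return _finish("em", pair.threshold, intensities, myo_mask)
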