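"""End-to-end orchestration of the six-step quantification pipeline.

Order: coil correction (needs a culprit extent model; skipped without one)
-> EM threshold -> level-set core growth -> MVO detection -> post-processing
(culprit filter, small-region filter) -> partial-volume weighted summation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coil import apply_correction, fit_correction, identity_field
from .core import ImageStack, InfarctResult, LVSegmentation, myocardial_volume
from .em import EMConstraints, em_fit
from .errors import InputError
from .levelset import build_speed, segment_core
from .metrics import dice
from .mvo import detect_mvo_stack, endo_adjacent_mask, merge_infarct
from .postprocess import filter_culprit, remove_small_regions
from .quantify import infarct_size, weight_map
from .sectors import (InsertionPoints, assign_sectors, default_extent_models,
                      remote_mask)

log = logging.getLogger(__name__)

COMPARATOR_NAMES = ("ewa", "em", "2sd", "3sd", "5sd", "fwhm-min",
                    "fwhm-remote", "otsu")


@dataclass
class EWAConfig:
    """All pipeline tunables in one place.

    Percentile constraints (5/95/90) and the post-processing thresholds
    (1.5 cm^3, 1 %LVM) are the algorithm's stated values; the level-set
    smoothing weight and iteration cap fill in parameters the method
    delegates to its segmentation backend.
    """

    em: EMConstraints = field(default_factory=EMConstraints)
    smoothing: float = 0.1
    max_iter: int = 200
    coil_correction: bool = True
    small_region_mm3: float = 1500.0
    small_region_pct: float = 1.0

    def as_dict(self) -> dict:
        return {
            "em_p_lo": self.em.p_lo, "em_p_hi": self.em.p_hi,
            "em_p_init": self.em.p_init, "smoothing": self.smoothing,
            "max_iter": self.max_iter,
            "coil_correction": self.coil_correction,
            "small_region_mm3": self.small_region_mm3,
            "small_region_pct": self.small_region_pct,
        }


def run_ewa(img: ImageStack, seg: LVSegmentation,
            culprit: str | None = None,
            insertions: InsertionPoints | None = None,
            extent_models: dict | None = None,
            config: EWAConfig | None = None) -> InfarctResult:
    """Run the full six-step pipeline on one stack.

    With a culprit artery (and the insertion points that orient the
    bulls-eye) the maximal extent model drives coil correction, the remote
    reference and the culprit filter. Without one — the experimental mode
    used when no coronary anatomy is available — correction and the culprit
    filter are skipped and the EM normal-component mean replaces the remote
    mean in the weighting.
    """
    config = config or EWAConfig()
    geom = img.geometry
    myo = seg.myocardium_mask

    remote = None
    assign = None
    model = None
    if culprit is not None:
        if insertions is None:
            raise InputError("a culprit artery requires insertion points "
                             "to orient the sector model")
        models = extent_models or default_extent_models()
        if culprit not in models:
            raise InputError(f"unknown culprit artery {culprit!r}")
        model = models[culprit]
        assign = assign_sectors(seg, insertions)
        remote = remote_mask(assign, model)

    # step 1 — surface-coil intensity correction
    if model is not None and config.coil_correction:
        fld = fit_correction(img, seg.blood_pool_mask(), remote)
        corrected = apply_correction(img, fld, myo)
    else:
        fld = identity_field(img)
        corrected = img
    intens = corrected.intensities

    # step 2 — EM classification and optimal threshold
    pair = em_fit(intens[myo], config.em)
    log.info("EM threshold t*=%.3f (mu_n=%.2f mu_i=%.2f, %d iter)",
             pair.threshold, pair.mu_n, pair.mu_i, pair.n_iter)

    # step 3 — level-set growth of the infarct core
    speed = build_speed(intens, myo, pair.threshold)
    core = segment_core(speed, config.smoothing, config.max_iter)

    # step 4 — microvascular obstruction
    endo_adj = endo_adjacent_mask(myo, seg.endo_interior_mask())
    mvo = detect_mvo_stack(core, myo, endo_adj)
    infarct = merge_infarct(core, mvo)

    # step 5 — post-processing
    if model is not None:
        infarct = filter_culprit(infarct, assign, model)
    lv_vol = myocardial_volume(seg, geom)
    infarct = remove_small_regions(infarct, geom, lv_vol,
                                   config.small_region_mm3,
                                   config.small_region_pct)
    core = infarct & core
    mvo = infarct & mvo

    # step 6 — partial-volume weighted size
    if not infarct.any():
        return InfarctResult(core, mvo, np.zeros(myo.shape), 0.0, 0.0, 0.0,
                             pair.threshold, pair.as_dict())
    if remote is not None:
        mu_r = float(intens[remote].mean())
    else:
        mu_r = pair.mu_n  # no remote reference: EM normal-component mean
    weights = weight_map(intens, infarct, mvo, mu_r)
    pct = infarct_size(weights, seg, geom)
    core_pct = 100.0 * infarct.sum() / myo.sum()
    mvo_ml = mvo.sum() * geom.voxel_volume / 1000.0

    return InfarctResult(core_mask=core, mvo_mask=mvo, weight_map=weights,
                         infarct_pct_lvm=pct, core_pct_lvm=float(core_pct),
                         mvo_volume_ml=float(mvo_ml),
                         threshold=pair.threshold, em_params=pair.as_dict())


def run_compare(img: ImageStack, seg: LVSegmentation,
                methods: list[str] | None = None,
                culprit: str | None = None,
                insertions: InsertionPoints | None = None,
                reference_mask: np.ndarray | None = None,
                config: EWAConfig | None = None) -> list[dict]:
    """Run the pipeline and the reference thresholds on one input.

    Returns one row per method: method name, threshold (where defined),
    %LVM, and Dice against ``reference_mask`` when given. The n-SD and
    FWHM-remote methods need a remote reference and are reported as
    unavailable without a culprit model.
    """
    from . import comparators as cmp

    methods = list(methods or COMPARATOR_NAMES)
    unknown = [m for m in methods if m not in COMPARATOR_NAMES]
    if unknown:
        raise InputError(f"unknown methods {unknown}; "
                         f"valid: {list(COMPARATOR_NAMES)}")
    config = config or EWAConfig()
    myo = seg.myocardium_mask
    intens = img.intensities

    remote = None
    if culprit is not None and insertions is not None:
        models = default_extent_models()
        assign = assign_sectors(seg, insertions)
        remote = remote_mask(assign, models[culprit])

    rows = []

    def add(method, threshold, mask, pct):
        row = {"method": method, "threshold": threshold, "pct_lvm": pct}
        if reference_mask is not None:
            row["dice"] = dice(mask, reference_mask)
        rows.append(row)

    for m in methods:
        try:
            if m == "ewa":
                res = run_ewa(img, seg, culprit, insertions, config=config)
                add(m, res.threshold, res.core_mask | res.mvo_mask,
                    res.infarct_pct_lvm)
            elif m == "em":
                r = cmp.threshold_em_pure(intens, myo, config.em)
                add(m, r.threshold, r.mask, r.pct_lvm)
            elif m.endswith("sd"):
                if remote is None:
                    raise InputError("n-SD thresholds need a remote "
                                     "reference (culprit + insertions)")
                r = cmp.threshold_nsd(intens, myo, remote, float(m[:-2]))
                add(m, r.threshold, r.mask, r.pct_lvm)
            elif m == "fwhm-min":
                r = cmp.threshold_fwhm_min(intens, myo)
                add(m, r.threshold, r.mask, r.pct_lvm)
            elif m == "fwhm-remote":
                if remote is None:
                    raise InputError("FWHM-remote needs a remote reference")
                r = cmp.threshold_fwhm_remote(intens, myo, remote, img.mode)
                add(m, r.threshold, r.mask, r.pct_lvm)
            elif m == "otsu":
                r = cmp.threshold_otsu(intens, myo)
                add(m, r.threshold, r.mask, r.pct_lvm)
        except InputError as e:
            rows.append({"method": m, "threshold": float("nan"),
                         "pct_lvm": float("nan"), "error": str(e)})
    return rows
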