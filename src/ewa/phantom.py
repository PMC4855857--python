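"""Synthetic LGE phantoms with voxel-level ground truth.

The phantom emulates a short-axis LGE stack: an annular myocardium (circular
endo/epi contours) around a bright blood pool, with a hyperenhanced infarct
wedge of configurable angular span and transmurality, optional hypointense
MVO core, partial-volume blurred infarct borders, a smooth multiplicative
coil-intensity gradient and Gaussian noise. Magnitude-IR mode folds the
signed signal (|.|), so a nulled remote exhibits folded noise; PSIR and T1w
keep signed values.

Partial volume is modeled by blurring the binary infarct wedge into a
continuous per-voxel infarct fraction BEFORE noise: the fraction field is
exactly the quantity the weighted summation claims to estimate, and it is
stored as ground truth. The blur is a normalized (mask-aware) Gaussian
convolution confined to the myocardium, which conserves the total infarct
fraction and acts like reflecting boundaries at the endo/epicardial borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ImageStack, LVSegmentation
from .errors import InputError
from .sectors import InsertionPoints


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters; the defaults mirror a typical acquisition
    (1.5 x 1.5 x 8.0 mm voxels, 9 contiguous short-axis slices).

    Contrast defaults give a contrast-to-noise ratio of 10 between infarct
    and remote myocardium, with a near-nulled remote so IR-mode folding is
    visible. The infarct is a transmural-from-endo wedge centered on the
    septum (inside the default LAD territory).
    """

    grid_size: int = 96
    n_slices: int = 9
    pixel_spacing: float = 1.5
    slice_thickness: float = 8.0
    slice_gap: float = 0.0
    endo_radius_mm: float = 30.0
    epi_radius_mm: float = 45.0
    wedge_center_deg: float = 180.0
    wedge_span_deg: float = 90.0
    transmurality: float = 1.0
    slice_range: tuple[int, int] | None = None  # inclusive; None = all
    mvo: bool = False
    mvo_span_deg: float = 30.0
    mvo_thickness_frac: float = 0.4
    remote_mean: float = 10.0
    infarct_mean: float = 100.0
    blood_mean: float = 120.0
    noise_sd: float = 9.0
    psf_sd_mm: float = 1.5
    coil_coeffs: tuple[float, ...] = (1.0, 0.15, -0.1, 0.08, 0.0, 0.05)
    mode: str = "IR"
    seed: int = 0

    def __post_init__(self):
        if not (self.infarct_mean > self.remote_mean):
            raise InputError("infarct mean must exceed remote mean")
        if self.noise_sd < 0:
            raise InputError("noise SD must be >= 0")
        if not (0 < self.transmurality <= 1):
            raise InputError("transmurality must lie in (0, 1]")
        if not (0 < self.endo_radius_mm < self.epi_radius_mm):
            raise InputError("need 0 < endo radius < epi radius")
        if self.epi_radius_mm / self.pixel_spacing >= self.grid_size / 2:
            raise InputError("epicardium does not fit on the grid")


@dataclass
class PhantomTruth:
    """Ground truth: per-voxel infarct fraction and derived quantities."""

    fraction: np.ndarray          # continuous in [0,1], post-blur, pre-noise
    pct_lvm: float                # 100 * sum(fraction) / myocardial count
    mvo_mask: np.ndarray
    core_binary: np.ndarray       # pre-blur wedge (binary truth)
    coil_field: np.ndarray = field(default=None)  # type: ignore[assignment]


def _circle(cx: float, cy: float, r_px: float, n: int = 96) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r_px * np.cos(th), cy + r_px * np.sin(th)])


def _coil_field(spec: PhantomSpec) -> np.ndarray:
    n = spec.grid_size
    c = (n - 1) / 2
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    x = (cols - c) / c
    y = (rows - c) / c
    a = spec.coil_coeffs
    f2d = (a[0] + a[1] * x + a[2] * y + a[3] * x * x + a[4] * x * y
           + a[5] * y * y)
    if np.any(f2d <= 0):
        raise InputError("coil field must stay positive on the grid")
    return np.broadcast_to(f2d, (spec.n_slices, n, n)).copy()


def _masked_blur(binary: np.ndarray, mask: np.ndarray,
                 sigma_px: float) -> np.ndarray:
    """Normalized Gaussian blur confined to ``mask`` (2D, per slice).

    f = G*(binary) / G*(mask) on mask voxels: mass cannot leak out of the
    myocardium, mimicking reflected boundaries, and the total fraction is
    conserved up to discretization.
    """
    if sigma_px <= 0:
        return binary.astype(float) * mask
    out = np.zeros(binary.shape, dtype=float)
    for z in range(binary.shape[0]):
        num = gaussian_filter(binary[z].astype(float), sigma_px,
                              mode="constant")
        den = gaussian_filter(mask[z].astype(float), sigma_px,
                              mode="constant")
        m = mask[z]
        out[z][m] = np.clip(num[m] / np.maximum(den[m], 1e-12), 0.0, 1.0)
        # renormalize to conserve total fraction exactly
        tot_in, tot_out = binary[z].sum(), out[z].sum()
        if tot_out > 0:
            out[z] *= tot_in / tot_out
            out[z] = np.clip(out[z], 0.0, 1.0)
    return out


def generate(spec: PhantomSpec
             ) -> tuple[ImageStack, LVSegmentation, InsertionPoints,
                        PhantomTruth]:
    """Generate one phantom stack with ground truth.

    Pipeline: rasterize circular contours -> binary infarct wedge in the
    annulus -> normalized Gaussian blur (continuous infarct fraction) ->
    compose intensity = remote + fraction * (infarct - remote), blood pool
    at its own level -> carve MVO (intensity dropped to the remote level,
    truth fraction kept at 1) -> multiply by the coil field -> add Gaussian
    noise -> magnitude folding in IR mode. Fixed seed gives bit-identical
    output.
    """
    n = spec.grid_size
    c = (n - 1) / 2
    px = spec.pixel_spacing
    endo_r = spec.endo_radius_mm / px
    epi_r = spec.epi_radius_mm / px

    endo = {s: _circle(c, c, endo_r) for s in range(spec.n_slices)}
    epi = {s: _circle(c, c, epi_r) for s in range(spec.n_slices)}
    seg = LVSegmentation.from_contours(endo, epi, (spec.n_slices, n, n))
    myo = seg.myocardium_mask
    blood = seg.endo_interior_mask()

    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    radius = np.hypot(rows - c, cols - c)
    theta = np.degrees(np.arctan2(rows - c, cols - c))  # (-180, 180]

    def in_span(center_deg: float, span_deg: float) -> np.ndarray:
        d = (theta - center_deg + 180.0) % 360.0 - 180.0
        return np.abs(d) <= span_deg / 2.0

    wall = epi_r - endo_r
    r_outer = endo_r + spec.transmurality * wall
    wedge2d = (in_span(spec.wedge_center_deg, spec.wedge_span_deg)
               & (radius >= endo_r) & (radius <= r_outer))

    lo, hi = (0, spec.n_slices - 1) if spec.slice_range is None \
        else spec.slice_range
    if not (0 <= lo <= hi < spec.n_slices):
        raise InputError("slice_range outside the stack")

    core_binary = np.zeros(myo.shape, dtype=bool)
    for s in range(lo, hi + 1):
        core_binary[s] = wedge2d & myo[s]
    if not core_binary.any():
        raise InputError("infarct wedge misses the myocardium")

    fraction = _masked_blur(core_binary, myo, spec.psf_sd_mm / px)

    mvo_mask = np.zeros(myo.shape, dtype=bool)
    if spec.mvo:
        mvo2d = (in_span(spec.wedge_center_deg, spec.mvo_span_deg)
                 & (radius >= endo_r + 1)
                 & (radius <= endo_r + spec.mvo_thickness_frac * wall))
        for s in range(lo, hi + 1):
            mvo_mask[s] = mvo2d & myo[s] & core_binary[s]

    contrast = spec.infarct_mean - spec.remote_mean
    signal = np.zeros(myo.shape, dtype=float)
    signal[myo] = spec.remote_mean + fraction[myo] * contrast
    signal[blood] = spec.blood_mean
    signal[mvo_mask] = spec.remote_mean  # MVO: dark despite full infarction

    coil = _coil_field(spec)
    signal *= coil

    rng = np.random.default_rng(spec.seed)
    noisy = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    if spec.mode == "IR":
        noisy = np.abs(noisy)

    img = ImageStack(noisy, spec.pixel_spacing, spec.slice_thickness,
                     spec.slice_gap, spec.mode)

    n_myo = int(myo.sum())
    truth = PhantomTruth(
        fraction=fraction,
        pct_lvm=float(100.0 * fraction[myo].sum() / n_myo),
        mvo_mask=mvo_mask,
        core_binary=core_binary,
        coil_field=coil,
    )

    # anterior RV insertion up-left, inferior down-left: septum on the left,
    # matching the default wedge center of 180 degrees
    rr = epi_r + 3
    ins = InsertionPoints(
        anterior=(c + rr * np.cos(np.radians(-135.0)),
                  c + rr * np.sin(np.radians(-135.0))),
        inferior=(c + rr * np.cos(np.radians(135.0)),
                  c + rr * np.sin(np.radians(135.0))),
    )
    return img, seg, ins, truth


def generate_paired(spec: PhantomSpec
                    ) -> tuple[ImageStack, ImageStack, LVSegmentation,
                               InsertionPoints, PhantomTruth]:
    """Paired IR and PSIR stacks sharing one geometry and truth.

    The two stacks differ only in their noise realizations (independent
    draws from sub-seeds derived from ``spec.seed``) and in the IR magnitude
    folding.
    """
    ss = np.random.SeedSequence(spec.seed)
    seed_ir, seed_psir = (int(s.generate_state(1)[0] % (2 ** 31))
                          for s in ss.spawn(2))
    img_ir, seg, ins, truth = generate(
        replace(spec, mode="IR", seed=seed_ir))
    img_psir, _, _, _ = generate(
        replace(spec, mode="PSIR", seed=seed_psir))
    return img_ir, img_psir, seg, ins, truth
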