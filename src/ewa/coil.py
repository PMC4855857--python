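"""Surface-coil intensity correction (pipeline step 1).

Surface coils impose a smooth multiplicative intensity gradient that falls
off roughly with the squared distance to the coil. A second-order
polynomial surface (linear in its 6 coefficients: 1, x, y, x^2, xy, y^2)
is least-squares fitted per slice to class-normalized intensities sampled
in the blood pool and remote myocardium — two tissues whose true intensity
is spatially constant — and the image is divided by the fitted field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ImageStack
from .errors import FitError, InputError

log = logging.getLogger(__name__)

_MIN_SAMPLES = 6  # one per polynomial coefficient


def _design(x: np.ndarray, y: np.ndarray, order: int = 2) -> np.ndarray:
    """Polynomial design matrix on normalized coordinates."""
    cols = [np.ones_like(x)]
    if order >= 1:
        cols += [x, y]
    if order >= 2:
        cols += [x * x, x * y, y * y]
    return np.column_stack(cols)


@dataclass
class CorrectionField:
    """Fitted multiplicative field: per-slice polynomial coefficients.

    Coefficients are in normalized coordinates (x, y scaled to [-1, 1] by
    the grid half-size) and the field is normalized to mean 1 over the fit
    samples. ``orders`` records the polynomial order actually used per slice
    (lower on rank-deficient slices).
    """

    coefficients: dict[int, np.ndarray]
    grid_shape: tuple[int, int]
    orders: dict[int, int] = field(default_factory=dict)

    def evaluate(self, slice_index: int) -> np.ndarray:
        """Field values over one full slice grid."""
        nr, nc = self.grid_shape
        cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
        x = (cols - (nc - 1) / 2) / max((nc - 1) / 2, 1)
        y = (rows - (nr - 1) / 2) / max((nr - 1) / 2, 1)
        coef = self.coefficients[slice_index]
        order = self.orders.get(slice_index, 2)
        A = _design(x.ravel(), y.ravel(), order)
        return (A @ coef).reshape(nr, nc)

    def evaluate_stack(self, n_slices: int) -> np.ndarray:
        return np.stack([self.evaluate(s) for s in range(n_slices)])


def identity_field(img: ImageStack) -> CorrectionField:
    """A field of constant 1 (no correction)."""
    n = img.n_slices
    coef = np.zeros(6)
    coef[0] = 1.0
    return CorrectionField({s: coef.copy() for s in range(n)},
                           img.intensities.shape[1:],
                           orders={s: 2 for s in range(n)})


def fit_correction(img: ImageStack, blood_mask: np.ndarray,
                   remote_mask: np.ndarray) -> CorrectionField:
    """Fit the coil field from blood-pool and remote-myocardium samples.

    Each sample contributes its intensity divided by the mean of its tissue
    class, so both classes target the same relative level of 1 and the fit
    sees only the spatial gradient. The least squares is
    reliability-weighted: a class's samples carry weight proportional to its
    squared inverse relative spread (mean/SD)^2, so a nulled, noise-dominated
    class (remote myocardium on magnitude-IR images) cannot tilt the fitted
    surface while a clean bright class (the blood pool) anchors it. Slices
    with fewer than 6 samples fall back to a pooled 3D fit (one coefficient
    set reused for all such slices); if the pooled sample is also too small
    the fit fails.
    """
    blood_mask = np.asarray(blood_mask, dtype=bool)
    remote_mask = np.asarray(remote_mask, dtype=bool)
    if blood_mask.shape != img.intensities.shape or \
            remote_mask.shape != img.intensities.shape:
        raise InputError("masks must match the image shape")
    if not blood_mask.any() or not remote_mask.any():
        raise InputError("blood and remote masks must be non-empty")

    nr, nc = img.intensities.shape[1:]

    def norm_xy(rr, cc):
        x = (cc - (nc - 1) / 2) / max((nc - 1) / 2, 1)
        y = (rr - (nr - 1) / 2) / max((nr - 1) / 2, 1)
        return x, y

    def samples_on(s=None):
        """Intensity samples with class ids, coordinates and weights."""
        vals_l, x_l, y_l, w_l, cls_l = [], [], [], [], []
        for ci, cls_mask in enumerate((blood_mask, remote_mask)):
            m = cls_mask if s is None else cls_mask[s]
            vals_all = img.intensities if s is None else img.intensities[s]
            if s is None:
                ss, rr, cc = np.nonzero(m)
            else:
                rr, cc = np.nonzero(m)
            if rr.size == 0:
                continue
            vals = vals_all[(ss, rr, cc) if s is None else (rr, cc)]
            mean = vals.mean()
            if abs(mean) < 1e-12:
                continue  # a nulled class carries no gradient information
            sd = vals.std()
            # reliability weight: squared inverse relative spread, capped so
            # a noise-free class cannot dominate numerically
            w_cls = min((mean / sd) ** 2, 1e6) if sd > 0 else 1e6
            x, y = norm_xy(rr, cc)
            vals_l.append(vals)
            x_l.append(x)
            y_l.append(y)
            w_l.append(np.full(vals.size, w_cls))
            cls_l.append(np.full(vals.size, ci))
        if not vals_l:
            return (np.empty(0),) * 5
        return tuple(np.concatenate(a)
                     for a in (vals_l, x_l, y_l, w_l, cls_l))

    def solve(vals, x, y, w, cls):
        """Joint fit of the field and the per-class levels.

        Model: I_j = c_{class(j)} * f(x_j). Alternating weighted least
        squares — given f, the class level is mean(I/f) over the class;
        given the levels, f is a WLS polynomial fit to I/c, iterated to
        convergence (the first pass equals the plain class-normalized fit).
        Without the alternation the two classes would target inconsistently
        scaled copies of the field.
        """
        sw = np.sqrt(w / w.max())
        for order in (2, 1, 0):
            A = _design(x, y, order)
            if vals.size < A.shape[1]:
                continue
            field_at = np.ones_like(vals)
            coef = None
            for _ in range(50):
                # class level = mean of field-corrected intensities
                levels = np.ones(2)
                for ci in (0, 1):
                    m = cls == ci
                    if m.any():
                        levels[ci] = float((vals[m] / field_at[m]).mean())
                rel = vals / levels[cls.astype(int)]
                new_coef, _, rank, _ = np.linalg.lstsq(
                    A * sw[:, None], rel * sw, rcond=None)
                if rank < A.shape[1]:
                    coef = None  # rank deficient: drop to a lower order
                    break
                field_at = A @ new_coef
                if np.any(field_at <= 0):
                    raise FitError("fitted coil field non-positive over "
                                   "samples")
                done = coef is not None and \
                    np.max(np.abs(new_coef - coef)) < 1e-10
                coef = new_coef
                if done:
                    break
            if coef is None:
                continue
            if order < 2:
                log.warning("coil fit rank-deficient; using order %d", order)
            full = np.zeros(6)
            full[:coef.size] = coef
            full /= float(np.mean(field_at))  # mean-1 normalization
            return full, order
        raise FitError("coil-field fit underdetermined")

    pooled = None
    coefs: dict[int, np.ndarray] = {}
    orders: dict[int, int] = {}
    for s in range(img.n_slices):
        vals, x, y, w, cls = samples_on(s)
        if vals.size >= _MIN_SAMPLES:
            coefs[s], orders[s] = solve(vals, x, y, w, cls)
        else:
            if pooled is None:
                v3, x3, y3, w3, c3 = samples_on(None)
                if v3.size < _MIN_SAMPLES:
                    raise FitError(
                        f"slice {s}: {vals.size} samples and pooled fit also "
                        "underdetermined")
                pooled = solve(v3, x3, y3, w3, c3)
            coefs[s], orders[s] = pooled

    return CorrectionField(coefs, (nr, nc), orders=orders)


def apply_correction(img: ImageStack, fld: CorrectionField,
                     myo_mask: np.ndarray | None = None) -> ImageStack:
    """Divide the image by the fitted field; acquisition mode is preserved.

    The field must be positive over the myocardium (and is clamped to a
    small positive floor elsewhere, where the extrapolated polynomial may
    dip below zero without affecting any analysed voxel).
    """
    field_stack = fld.evaluate_stack(img.n_slices)
    if myo_mask is not None and np.any(field_stack[myo_mask] <= 0):
        raise FitError("correction field non-positive inside the myocardium")
    safe = np.where(field_stack > 1e-6, field_stack, 1e-6)
    return img.with_intensities(img.intensities / safe)
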