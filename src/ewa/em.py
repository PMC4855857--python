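"""Constrained EM classification of myocardial intensities (step 2).

A two-component Gaussian mixture — normal (nulled) myocardium versus
hyperenhanced infarct — is fitted to the myocardial intensity histogram by
Expectation-Maximization. Two constraints stabilize the fit and keep the
components separated: intensities below the 5th percentile are clamped to
the normal class and intensities above the 95th percentile to the infarct
class (responsibilities overwritten every E-step). The initial labeling
assumes a small infarct: the top 10% of intensities (above the 90th
percentile) start as infarct.

The optimal threshold t* is the intensity at which a voxel is equally
likely to be normal or infarcted under the fitted mixture:
pi_n N(t; mu_n, sigma_n) = pi_i N(t; mu_i, sigma_i), a quadratic in t
solved in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegenerateInputError, FitError, ThresholdError

_MIN_SAMPLES = 20


@dataclass(frozen=True)
class EMConstraints:
    """Percentile constraints of the EM fit.

    p_lo / p_hi: intensities below/above these percentiles are clamped to
    the normal / infarct class each E-step. p_init: initial infarct label
    boundary (top 10% of the histogram starts as infarct).
    """

    p_lo: float = 5.0
    p_hi: float = 95.0
    p_init: float = 90.0

    def __post_init__(self):
        if not (0 < self.p_lo < self.p_init < 100):
            raise ValueError("require 0 < p_lo < p_init < 100")
        if not (self.p_lo < self.p_hi):
            raise ValueError("require p_lo < p_hi")


@dataclass
class GaussianPair:
    """Fitted two-Gaussian mixture and its optimal threshold.

    Component n is normal myocardium, component i is infarct (the
    larger-mean component after fitting). ``threshold`` is the
    equal-posterior intensity t*.
    """

    mu_n: float
    sigma_n: float
    mu_i: float
    sigma_i: float
    pi_n: float
    pi_i: float
    threshold: float = float("nan")
    n_iter: int = 0
    converged: bool = False

    def validate(self) -> None:
        if not (self.sigma_n > 0 and self.sigma_i > 0):
            raise FitError("component SDs must be positive")
        if not (0 < self.pi_n < 1 and 0 < self.pi_i < 1):
            raise FitError("mixing weights must lie in (0, 1)")
        if abs(self.pi_n + self.pi_i - 1.0) > 1e-9:
            raise FitError("mixing weights must sum to 1")
        if not self.mu_i > self.mu_n:
            raise FitError("infarct mean must exceed normal mean")

    def as_dict(self) -> dict:
        return {
            "mu_normal": self.mu_n, "sigma_normal": self.sigma_n,
            "mu_infarct": self.mu_i, "sigma_infarct": self.sigma_i,
            "pi_normal": self.pi_n, "pi_infarct": self.pi_i,
            "threshold": self.threshold, "n_iter": self.n_iter,
            "converged": self.converged,
        }


def _percentile(values: np.ndarray, q: float) -> float:
    """Percentile by linear interpolation between order statistics.

    The constraint boundaries depend on the estimator, so it is pinned here:
    numpy's default 'linear' interpolation.
    """
    return float(np.percentile(values, q))


def initialize_labels(intensities: np.ndarray,
                      p_init: float = 90.0) -> np.ndarray:
    """Initial infarct labeling: strictly above the ``p_init`` percentile.

    Models a small infarct of ~10% of the myocardium. Ties at the percentile
    break toward normal (strict inequality).
    """
    v = np.asarray(intensities, dtype=float).ravel()
    if v.size < _MIN_SAMPLES:
        raise DegenerateInputError(
            f"need >= {_MIN_SAMPLES} samples, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateInputError("constant intensities cannot be "
                                   "classified")
    return v > _percentile(v, p_init)


def _weighted_moments(v, w):
    wsum = w.sum()
    mu = float((w * v).sum() / wsum)
    var = float((w * (v - mu) ** 2).sum() / wsum)
    return mu, var, wsum


def em_fit(intensities: np.ndarray,
           constraints: EMConstraints = EMConstraints(),
           tol: float = 1e-6, max_iter: int = 500) -> GaussianPair:
    """Constrained EM fit of the normal/infarct Gaussian mixture.

    E-step: posterior responsibilities under the current parameters, then
    clamped — responsibility(infarct) = 0 below the p_lo percentile and
    = 1 above the p_hi percentile of the sample. M-step: weighted means,
    SDs and mixing weights. Convergence: max absolute parameter change
    < ``tol`` (intensities are internally standardized, so the tolerance is
    scale-free); cap ``max_iter`` iterations. The larger-mean component is
    labeled infarct.
    """
    v = np.asarray(intensities, dtype=float).ravel()
    if v.size < _MIN_SAMPLES:
        raise DegenerateInputError(
            f"need >= {_MIN_SAMPLES} samples, got {v.size}")
    vrange = float(np.ptp(v))
    if vrange == 0:
        raise DegenerateInputError("constant intensities")

    # standardize for scale-free tolerances; undone at the end
    loc, scale = float(v.mean()), float(v.std())
    z = (v - loc) / scale

    lo = _percentile(z, constraints.p_lo)
    hi = _percentile(z, constraints.p_hi)
    labels = initialize_labels(z, constraints.p_init)
    if labels.all() or not labels.any():
        raise FitError("initial labeling produced a single class; intensity "
                       "histogram too degenerate for a two-component fit")

    # initial parameters from the hard labels
    def from_labels(lbl):
        a, b = z[~lbl], z[lbl]
        return np.array([
            a.mean(), max(a.std(), 1e-6),
            b.mean(), max(b.std(), 1e-6),
            lbl.mean(),
        ])

    params = from_labels(labels)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        mu_n, sd_n, mu_i, sd_i, pi_i = params
        pi_n = 1.0 - pi_i
        # E-step
        log_n = norm.logpdf(z, mu_n, sd_n) + np.log(max(pi_n, 1e-300))
        log_i = norm.logpdf(z, mu_i, sd_i) + np.log(max(pi_i, 1e-300))
        m = np.maximum(log_n, log_i)
        r_i = np.exp(log_i - m) / (np.exp(log_n - m) + np.exp(log_i - m))
        # constraint clamp
        r_i[z < lo] = 0.0
        r_i[z > hi] = 1.0
        # M-step
        w_i = r_i
        w_n = 1.0 - r_i
        if w_i.sum() < 1e-6 * v.size or w_n.sum() < 1e-6 * v.size:
            raise FitError("a mixture component collapsed "
                           f"(weights {w_n.sum():.3g}/{w_i.sum():.3g})")
        mu_n, var_n, s_n = _weighted_moments(z, w_n)
        mu_i, var_i, s_i = _weighted_moments(z, w_i)
        sd_n = np.sqrt(max(var_n, 0.0))
        sd_i = np.sqrt(max(var_i, 0.0))
        if sd_n < 1e-9 * np.ptp(z) or sd_i < 1e-9 * np.ptp(z):
            raise FitError("a component SD collapsed toward zero")
        new = np.array([mu_n, sd_n, mu_i, sd_i, s_i / z.size])
        if np.max(np.abs(new - params)) < tol:
            params = new
            converged = True
            break
        params = new

    mu_n, sd_n, mu_i, sd_i, pi_i = params
    # the larger-mean component is the infarct
    if mu_n > mu_i:
        mu_n, mu_i = mu_i, mu_n
        sd_n, sd_i = sd_i, sd_n
        pi_i = 1.0 - pi_i

    pair = GaussianPair(
        mu_n=loc + scale * mu_n, sigma_n=scale * sd_n,
        mu_i=loc + scale * mu_i, sigma_i=scale * sd_i,
        pi_n=1.0 - pi_i, pi_i=pi_i,
        n_iter=n_iter, converged=converged,
    )
    pair.validate()
    pair.threshold = optimal_threshold(pair)
    return pair


def em_loglik(intensities: np.ndarray, pair: GaussianPair,
              constraints: EMConstraints = EMConstraints()) -> float:
    """Observed-data log-likelihood with the clamped-sample convention.

    Clamped samples contribute their assigned component's weighted density;
    free samples contribute the full mixture. Used to verify EM monotonicity.
    """
    v = np.asarray(intensities, dtype=float).ravel()
    lo = _percentile(v, constraints.p_lo)
    hi = _percentile(v, constraints.p_hi)
    dn = pair.pi_n * norm.pdf(v, pair.mu_n, pair.sigma_n)
    di = pair.pi_i * norm.pdf(v, pair.mu_i, pair.sigma_i)
    contrib = np.where(v < lo, dn, np.where(v > hi, di, dn + di))
    return float(np.sum(np.log(np.maximum(contrib, 1e-300))))


def optimal_threshold(pair: GaussianPair, weighted: bool = True) -> float:
    """Equal-probability intensity between the two fitted Gaussians.

    Solves pi_n N(t; mu_n, sigma_n) = pi_i N(t; mu_i, sigma_i) — a quadratic
    in t. Of its real roots, the one inside (mu_n, mu_i) is returned; if
    neither root lands in the interval (possible with extreme weight or SD
    ratios), the root closest to the interval is used. Equal SDs reduce the
    quadratic to a linear equation.

    With ``weighted=False`` the mixing weights are ignored and the
    class-conditional densities are equated instead.
    """
    pair.validate()
    mu1, s1 = pair.mu_n, pair.sigma_n
    mu2, s2 = pair.mu_i, pair.sigma_i
    w1 = pair.pi_n if weighted else 0.5
    w2 = pair.pi_i if weighted else 0.5

    # log w1 - log s1 - (t-mu1)^2/(2 s1^2) = log w2 - log s2 - (t-mu2)^2/(2 s2^2)
    a = 1.0 / (2 * s2 ** 2) - 1.0 / (2 * s1 ** 2)
    b = mu1 / s1 ** 2 - mu2 / s2 ** 2
    c = (mu2 ** 2 / (2 * s2 ** 2) - mu1 ** 2 / (2 * s1 ** 2)
         + np.log(w1 / w2) + np.log(s2 / s1))

    if abs(a) < 1e-15:  # equal variances: linear equation
        if abs(b) < 1e-15:
            raise ThresholdError("degenerate pair: no crossing point")
        roots = np.array([-c / b])
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ThresholdError("no real crossing between the components")
        sq = np.sqrt(disc)
        roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])

    inside = roots[(roots > mu1) & (roots < mu2)]
    if inside.size:
        return float(inside[0])
    # fall back to the root nearest the (mu_n, mu_i) interval
    dist = np.where(roots < mu1, mu1 - roots,
                    np.where(roots > mu2, roots - mu2, 0.0))
    return float(roots[np.argmin(dist)])
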