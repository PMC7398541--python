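"""Neurogram similarity (NSIM), correct-score mapping, and current-spread factor.

NSIM is an SSIM variant without the contrast term: the product of a local
luminance term l and a structure term s, evaluated in a 3x3
Gaussian-weighted window sliding over the two neurograms, then averaged::

    l = (2*mu_a*mu_b + C1) / (mu_a^2 + mu_b^2 + C1)
    s = (sigma_ab + C2) / (sigma_a*sigma_b + C2)
    NSIM(a, b) = mean( l^alpha * s^gamma )

Neurogram intensities are normalized from the display range 0–360 spikes/s
to 0–255 before comparison (fixed anchor, not per-neurogram max).

The correct score maps NSIM onto percent correct in a spectral-ripple
discrimination task through a sigmoid with slope S and discrimination
threshold D_thr.  A *smaller* NSIM (more discriminable neurograms) yields
a *higher* score; the decreasing orientation is the default (see
:func:`correct_score`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate


def _gaussian_kernel_3x3(sigma: float) -> np.ndarray:
    ax = np.array([-1.0, 0.0, 1.0])
    g1 = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g1, g1)
    return k / k.sum()


@dataclass(frozen=True)
class NsimConfig:
    """NSIM constants.

    L is the intensity range after normalization (255); C1 = (0.01 L)^2 and
    C2 = (0.05 L)^2 are the usual SSIM stabilizers; alpha/gamma the term
    exponents; sigma the Gaussian width of the 3x3 window (in pixels);
    input_max the neurogram intensity (spikes/s) mapped onto L.
    """

    L: float = 255.0
    alpha: float = 1.0
    gamma: float = 1.0
    sigma: float = 0.5
    input_max: float = 360.0

    @property
    def C1(self) -> float:
        return (0.01 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (0.05 * self.L) ** 2

    @property
    def window(self) -> np.ndarray:
        return _gaussian_kernel_3x3(self.sigma)


def nsim(a, b, cfg: NsimConfig = NsimConfig(), *, return_map: bool = False):
    """NSIM between two equal-shape neurogram matrices (rates in spikes/s).

    Both inputs are scaled by ``cfg.L / cfg.input_max`` (fixed 0–360 →
    0–255 anchor; values above the anchor are retained, not clipped).
    Local means, standard deviations and covariance use the 3x3 Gaussian
    window with symmetric border padding.  Returns the map mean, or
    ``(mean, map)`` if ``return_map``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    scale = cfg.L / cfg.input_max
    a = a * scale
    b = b * scale
    w = cfg.window

    def local(img):
        return correlate(img, w, mode="reflect")

    mu_a, mu_b = local(a), local(b)
    # windowed (biased) second moments
    var_a = local(a * a) - mu_a ** 2
    var_b = local(b * b) - mu_b ** 2
    cov = local(a * b) - mu_a * mu_b
    # product of the two SDs, computed as sqrt(var_a*var_b) so that the
    # a == b case gives s = 1 exactly
    sd_prod = np.sqrt(np.maximum(var_a, 0.0) * np.maximum(var_b, 0.0))
    l = (2.0 * mu_a * mu_b + cfg.C1) / (mu_a ** 2 + mu_b ** 2 + cfg.C1)
    s = (cov + cfg.C2) / (sd_prod + cfg.C2)
    nsim_map = np.sign(l) * np.abs(l) ** cfg.alpha * np.sign(s) * np.abs(s) ** cfg.gamma
    value = float(nsim_map.mean())
    return (value, nsim_map) if return_map else value


@dataclass(frozen=True)
class ScoreFunction:
    """Sigmoid mapping NSIM to percent correct.

    ``slope`` (S) and ``threshold`` (D_thr) were fitted against human CI
    percent-correct data; defaults 21 and 0.61.  ``increasing=False`` is
    the default orientation: smaller NSIM (easier discrimination) maps to
    a higher score.  Set ``increasing=True`` for the literal increasing
    sigmoid form.
    """

    slope: float = 21.0
    threshold: float = 0.61
    increasing: bool = False

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def correct_score(nsim_value: float, fn: ScoreFunction = ScoreFunction()) -> float:
    """Percent-correct score for a given NSIM value.

    Default (decreasing) orientation::

        score = 100 / (1 + exp(S * (NSIM - D_thr)))

    which is 50% at NSIM = D_thr, approaches 100% as NSIM -> 0 and 0% as
    NSIM -> 1.  With ``fn.increasing`` the sign of the exponent flips.
    """
    sign = -1.0 if fn.increasing else 1.0
    return float(100.0 / (1.0 + np.exp(sign * fn.slope * (nsim_value - fn.threshold))))


def current_spread_factor(spikes_with: float, spikes_without: float) -> float:
    """Relative change in spike count caused by neighboring-channel current.

    ``(with - without) / without``: negative values indicate inhibition by
    the spread current, positive values facilitation, zero no effect.
    Undefined when the no-spread baseline has no spikes.
    """
    if spikes_without <= 0:
        raise ZeroDivisionError(
            f"current-spread factor undefined: baseline spike count is "
            f"{spikes_without} (raw with-spread count: {spikes_with})")
    return (spikes_with - spikes_without) / spikes_without
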