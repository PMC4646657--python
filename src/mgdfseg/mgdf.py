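"""Multi-feature local Gaussian distribution fitting (MGDF) data model.

Each pixel x carries a Gaussian-windowed neighborhood; within it, the
intensities I(y) and the vesselness values V(y) of the region inside
(i = 1) and outside (i = 2) the contour are modeled as Gaussians with
spatially varying means u_i(x) and standard deviations sigma_i(x),
estimated per feature channel.  The data energy is the windowed negative
log-likelihood of both channels, weighted by lambda_i per channel; its
first variation with respect to phi yields the data force used by the
level-set update.

With both vesselness weights set to zero the model reduces exactly to
single-feature local Gaussian distribution fitting (LGDF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .config import RunConfig
from .level_set import EnergyBreakdown, heaviside_eps

__all__ = [
    "SIGMA_FLOOR",
    "truncation_half_width",
    "make_window_kernel",
    "window_filter",
    "LocalGaussianStats",
    "ModelWeights",
    "update_local_stats",
    "data_force",
    "total_energy",
    "MGDFModel",
]

# Constant of the windowed -log density terms, kept as the flow equations
# state it (log(2*pi), not half of it); it is phi-independent per pixel and
# nearly cancels between the inside and outside terms.
LOG_2PI = math.log(2.0 * math.pi)

#: lower bound on every local standard deviation (0-255 intensity scale and
#: vesselness channel alike); prevents log(sigma) -> -inf on locally
#: constant regions.
SIGMA_FLOOR = 1e-2

_DENOM_FLOOR = 1e-10


def truncation_half_width(sigma: float) -> int:
    """Smallest odd integer >= 2*sigma (half-width tau of the window mask)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    tau = int(math.ceil(2.0 * sigma))
    if tau % 2 == 0:
        tau += 1
    return tau


def _window_1d(sigma: float) -> np.ndarray:
    tau = truncation_half_width(sigma)
    k = np.arange(-tau, tau + 1, dtype=float)
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    return w / w.sum()


def make_window_kernel(sigma: float) -> np.ndarray:
    """Truncated Gaussian window of scale ``sigma``.

    Returns the (2*tau+1) x (2*tau+1) mask with tau the smallest odd
    integer >= 2*sigma, renormalized to sum to 1.  sigma = 3 gives the
    customary 15 x 15 window.
    """
    w = _window_1d(sigma)
    return np.outer(w, w)


def window_filter(arr: np.ndarray, sigma: float) -> np.ndarray:
    """Correlate ``arr`` with the window kernel (separably, edge-mirrored)."""
    w = _window_1d(sigma)
    out = correlate1d(np.asarray(arr, float), w, axis=0, mode="reflect")
    return correlate1d(out, w, axis=1, mode="reflect")


@dataclass
class LocalGaussianStats:
    """Local means/stds per feature (I intensity, V vesselness) and region
    (1 inside, 2 outside), each a full-size 2-D grid."""

    u1I: np.ndarray
    u2I: np.ndarray
    u1V: np.ndarray
    u2V: np.ndarray
    s1I: np.ndarray
    s2I: np.ndarray
    s1V: np.ndarray
    s2V: np.ndarray


@dataclass
class ModelWeights:
    """Data-term weights per region and feature channel."""

    lambda1_intensity: float = 1.05
    lambda2_intensity: float = 1.0
    lambda1_vesselness: float = 1.05
    lambda2_vesselness: float = 1.0

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "ModelWeights":
        return cls(
            cfg.lambda1_intensity,
            cfg.lambda2_intensity,
            cfg.lambda1_vesselness,
            cfg.lambda2_vesselness,
        )


def _region_stats(
    feature: np.ndarray, H: np.ndarray, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean and (floored) std of ``feature`` weighted by ``H``."""
    m0 = window_filter(H, sigma) + _DENOM_FLOOR
    m1 = window_filter(feature * H, sigma)
    m2 = window_filter(feature * feature * H, sigma)
    u = m1 / m0
    var = np.maximum(m2 / m0 - u * u, SIGMA_FLOOR**2)
    return u, np.sqrt(var)


def update_local_stats(
    image: np.ndarray,
    vesselness: np.ndarray,
    phi: np.ndarray,
    sigma: float,
    eps: float,
) -> LocalGaussianStats:
    """Closed-form minimizers of the data energy for fixed phi.

    u_i^F(x) = [w * (F H_i)] / [w * H_i] and
    sigma_i^F(x)^2 = [w * (F^2 H_i)] / [w * H_i] - u_i^F(x)^2,
    with H_1 the regularized Heaviside of phi and H_2 = 1 - H_1.
    Denominators are floored by 1e-10 (inert: those means are multiplied by
    the vanishing H_i wherever the floor engages) and stds by SIGMA_FLOOR.
    """
    image = np.asarray(image, float)
    vesselness = np.asarray(vesselness, float)
    phi = np.asarray(phi, float)
    if not (image.shape == vesselness.shape == phi.shape):
        raise ValueError(
            f"shape mismatch: image {image.shape}, vesselness "
            f"{vesselness.shape}, phi {phi.shape}"
        )
    H1 = heaviside_eps(-phi, eps)  # interior weight (phi < 0 inside)
    H2 = 1.0 - H1
    u1I, s1I = _region_stats(image, H1, sigma)
    u2I, s2I = _region_stats(image, H2, sigma)
    u1V, s1V = _region_stats(vesselness, H1, sigma)
    u2V, s2V = _region_stats(vesselness, H2, sigma)
    return LocalGaussianStats(u1I, u2I, u1V, u2V, s1I, s2I, s1V, s2V)


def _e_term(feature: np.ndarray, u: np.ndarray, s: np.ndarray, sigma: float) -> np.ndarray:
    """Windowed -log Gaussian density term

        e_i(x) = int w(x-y) [ log(2 pi) + log sigma_i(y)
                              + (u_i(y) - F(x))^2 / (2 sigma_i(y)^2) ] dy:

    the feature value is fixed at the output pixel x while the local
    statistics vary over the surrounding window centers y.  This is the
    form the first variation of the region energy produces (each pixel is
    judged by every neighborhood containing it), so delta * (l1 e1 - l2 e2)
    is the exact descent direction of the data energy; expanded into three
    correlations around the fixed F(x).
    """
    inv2 = 0.5 / (s * s)
    a0 = window_filter(np.log(s), sigma)
    a1 = window_filter(inv2, sigma)
    a2 = window_filter(u * inv2, sigma)
    a3 = window_filter(u * u * inv2, sigma)
    return LOG_2PI + a0 + feature * feature * a1 - 2.0 * feature * a2 + a3


def _all_e_terms(
    image: np.ndarray,
    vesselness: np.ndarray,
    stats: LocalGaussianStats,
    sigma: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    e1I = _e_term(image, stats.u1I, stats.s1I, sigma)
    e2I = _e_term(image, stats.u2I, stats.s2I, sigma)
    e1V = _e_term(vesselness, stats.u1V, stats.s1V, sigma)
    e2V = _e_term(vesselness, stats.u2V, stats.s2V, sigma)
    return e1I, e2I, e1V, e2V


def data_force(
    image: np.ndarray,
    vesselness: np.ndarray,
    stats: LocalGaussianStats,
    sigma: float,
    weights: ModelWeights,
) -> np.ndarray:
    """Per-pixel data force

        F(x) = l1I e1I - l2I e2I + l1V e1V - l2V e2V

    with region 1 the interior (phi < 0).  The evolution applies
    ``dirac(phi) * F``: positive F pushes phi up (pixel toward the
    background), negative F pulls it into the interior.
    """
    e1I, e2I, e1V, e2V = _all_e_terms(image, vesselness, stats, sigma)
    return (
        weights.lambda1_intensity * e1I
        - weights.lambda2_intensity * e2I
        + weights.lambda1_vesselness * e1V
        - weights.lambda2_vesselness * e2V
    )


def total_energy(
    image: np.ndarray,
    vesselness: np.ndarray,
    phi: np.ndarray,
    stats: LocalGaussianStats,
    cfg: RunConfig,
) -> EnergyBreakdown:
    """Full MGDF energy of the current phi (data + all regularizers)."""
    from .level_set import distance_integral, gamma_integral, length_integral

    if not (image.shape == vesselness.shape == phi.shape):
        raise ValueError("shape mismatch between image, vesselness and phi")
    w = ModelWeights.from_config(cfg)
    e1I, e2I, e1V, e2V = _all_e_terms(image, vesselness, stats, cfg.sigma)
    H1 = heaviside_eps(-phi, cfg.epsilon)
    H2 = 1.0 - H1
    data_i = float(
        (w.lambda1_intensity * e1I * H1 + w.lambda2_intensity * e2I * H2).sum()
    )
    data_v = float(
        (w.lambda1_vesselness * e1V * H1 + w.lambda2_vesselness * e2V * H2).sum()
    )
    return EnergyBreakdown(
        data_intensity=data_i,
        data_vesselness=data_v,
        length_term=cfg.nu * length_integral(phi, cfg.epsilon),
        distance_term=cfg.mu * distance_integral(phi),
        gamma_term=cfg.eta * gamma_integral(phi, cfg.gamma, cfg.kappa),
    )


class MGDFModel:
    """Two-feature data model plugged into the shared evolution loop."""

    name = "mgdf"
    use_mu = True
    use_gamma = True

    def __init__(self, image: np.ndarray, vesselness: np.ndarray, cfg: RunConfig):
        image = np.asarray(image, float)
        vesselness = np.asarray(vesselness, float)
        if image.shape != vesselness.shape:
            raise ValueError(
                f"image shape {image.shape} != vesselness shape {vesselness.shape}"
            )
        if image.ndim != 2 or min(image.shape) < 3:
            raise ValueError("image must be a 2-D grid of at least 3x3")
        self.image = image
        self.vesselness = vesselness
        self.cfg = cfg
        self.weights = ModelWeights.from_config(cfg)
        self.shape = image.shape
        self.stats: LocalGaussianStats | None = None

    def data_terms(self, phi: np.ndarray) -> tuple[np.ndarray, float, float]:
        cfg = self.cfg
        w = self.weights
        self.stats = update_local_stats(
            self.image, self.vesselness, phi, cfg.sigma, cfg.epsilon
        )
        e1I, e2I, e1V, e2V = _all_e_terms(self.image, self.vesselness, self.stats, cfg.sigma)
        force = (
            w.lambda1_intensity * e1I
            - w.lambda2_intensity * e2I
            + w.lambda1_vesselness * e1V
            - w.lambda2_vesselness * e2V
        )
        H1 = heaviside_eps(-phi, cfg.epsilon)
        H2 = 1.0 - H1
        data_i = float(
            (w.lambda1_intensity * e1I * H1 + w.lambda2_intensity * e2I * H2).sum()
        )
        data_v = float(
            (w.lambda1_vesselness * e1V * H1 + w.lambda2_vesselness * e2V * H2).sum()
        )
        return force, data_i, data_v
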