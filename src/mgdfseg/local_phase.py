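"""Local-phase vesselness enhancement.

A bank of oriented quadrature pairs (even line filter, odd edge filter,
90 degrees out of phase) is realized as log-Gabor filters built in the
frequency domain and cropped to small spatial kernels.  Per scale, the
orientation-summed complex response carries the even energy in its real
part and the summed |odd| energy in its imaginary part; scales are merged
by a magnitude-weighted mean and the real (line) part is squashed into
(-1, 1) to give the bounded vesselness map: positive inside bright
tubular structures, near zero at their edges, negative in the
background.  (On fundus green channels, where vessels are dark, negate
the input or the map.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .config import RunConfig

__all__ = [
    "FilterBank",
    "build_filter_bank",
    "scale_responses",
    "combine_scales",
    "normalize_vesselness",
    "enhance",
]

# Frequency-domain construction grid; odd so the lattice is closed under
# 90-degree rotations (makes orientation symmetries exact).
_FREQ_GRID = 63


@dataclass
class FilterBank:
    """Spatial quadrature kernels, indexed [scale][orientation].

    ``even[m][j]`` is point-symmetric (line filter), ``odd[m][j]``
    antisymmetric (edge filter, zero DC).  ``center_frequencies[m]`` is the
    radial center frequency of scale m in radians/pixel; ``angles[j]`` the
    orientation in radians.
    """

    even: list[list[np.ndarray]]
    odd: list[list[np.ndarray]]
    center_frequencies: np.ndarray
    angles: np.ndarray

    @property
    def n_scales(self) -> int:
        return len(self.even)

    @property
    def n_orientations(self) -> int:
        return len(self.angles)


def _log_gabor_pair(
    f0: float, sigma_on_f: float, theta: float, sigma_theta: float, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """One even/odd kernel pair from a single-sided log-Gabor spectrum."""
    n = max(_FREQ_GRID, 2 * size + 1)
    if n % 2 == 0:
        n += 1
    f = np.fft.fftfreq(n) * 2.0 * np.pi
    fy, fx = np.meshgrid(f, f, indexing="ij")
    r = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        radial = np.exp(-(np.log(np.where(r > 0, r, 1.0) / f0) ** 2) / (2.0 * np.log(sigma_on_f) ** 2))
    radial[r == 0] = 0.0
    ang = np.arctan2(fx, fy)  # direction of the frequency vector
    dtheta = np.angle(np.exp(1j * (ang - theta)))
    angular = np.exp(-(dtheta**2) / (2.0 * sigma_theta**2))
    spectrum = radial * angular  # single half-plane -> complex spatial kernel
    kernel = np.fft.fftshift(np.fft.ifft2(spectrum))
    c = n // 2
    h = size // 2
    kernel = kernel[c - h : c + h + 1, c - h : c + h + 1]
    even = kernel.real
    odd = kernel.imag
    # enforce exact (anti)symmetry lost to cropping, and restore the zero
    # DC response (a line filter must not respond to constants)
    even = 0.5 * (even + even[::-1, ::-1])
    even -= even.mean()
    odd = 0.5 * (odd - odd[::-1, ::-1])
    return even, odd


def build_filter_bank(cfg: RunConfig) -> FilterBank:
    """Quadrature bank: M scales (center frequency halving per scale from
    ``cfg.center_frequency``), J orientations evenly spaced over [0, pi),
    each cropped to ``filter_size`` x ``filter_size``."""
    cfg.validate()
    sigma_on_f = np.exp(-cfg.bandwidth_octaves / (2.0 * np.sqrt(2.0 / np.log(2.0))))
    sigma_theta = (np.pi / cfg.n_orientations) / 1.5
    freqs = cfg.center_frequency / (2.0 ** np.arange(cfg.n_scales))
    angles = np.arange(cfg.n_orientations) * np.pi / cfg.n_orientations
    even: list[list[np.ndarray]] = []
    odd: list[list[np.ndarray]] = []
    for f0 in freqs:
        row_e, row_o = [], []
        for theta in angles:
            e, o = _log_gabor_pair(f0, sigma_on_f, theta, sigma_theta, cfg.filter_size)
            row_e.append(e)
            row_o.append(o)
        even.append(row_e)
        odd.append(row_o)
    return FilterBank(even=even, odd=odd, center_frequencies=freqs, angles=angles)


def scale_responses(image: np.ndarray, bank: FilterBank) -> list[np.ndarray]:
    """Orientation-summed complex response per scale.

    q_m = sum_j (I * E_m^j) + |I * O_m^j| * 1j, convolution with
    edge-mirrored boundaries.  Taking |odd| before summing makes the edge
    energy orientation-invariant; the imaginary part is therefore >= 0.
    """
    image = np.asarray(image, float)
    ksize = bank.even[0][0].shape[0]
    if image.ndim != 2 or min(image.shape) < ksize:
        raise ValueError(
            f"image shape {image.shape} smaller than kernel ({ksize}x{ksize})"
        )
    out = []
    for m in range(bank.n_scales):
        e_sum = np.zeros_like(image)
        o_sum = np.zeros_like(image)
        for j in range(bank.n_orientations):
            e_sum += convolve(image, bank.even[m][j], mode="reflect")
            o_sum += np.abs(convolve(image, bank.odd[m][j], mode="reflect"))
        out.append(e_sum + 1j * o_sum)
    return out


def combine_scales(responses: list[np.ndarray], beta: float) -> np.ndarray:
    """Magnitude-weighted merge of per-scale responses.

    P = Re[ sum_m q_m |q_m|^beta / sum_m |q_m|^beta ]; pixels where every
    scale responds with zero magnitude yield P = 0.
    """
    if beta < 1.0:
        raise ValueError(f"beta must be >= 1, got {beta}")
    if not responses:
        raise ValueError("no scale responses given")
    shape = responses[0].shape
    if any(r.shape != shape for r in responses):
        raise ValueError("scale responses have mismatched shapes")
    num = np.zeros(shape, complex)
    den = np.zeros(shape, float)
    for q in responses:
        w = np.abs(q) ** beta
        num += q * w
        den += w
    with np.errstate(invalid="ignore", divide="ignore"):
        merged = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return merged.real


def normalize_vesselness(P: np.ndarray, alpha: float) -> np.ndarray:
    """Bounded vesselness LP = P * |P| / (P^2 + alpha^2), strictly in (-1, 1).

    Preserves the sign of P, vanishes where P does, and saturates toward
    +/-1 for |P| >> alpha.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    P = np.asarray(P, float)
    return P * np.abs(P) / (P * P + alpha * alpha)


def enhance(image: np.ndarray, cfg: RunConfig | None = None) -> np.ndarray:
    """Full enhancement: filter bank -> per-scale responses -> scale merge
    -> bounded normalization.  ``cfg.alpha = None`` resolves to
    0.1 * max|P| of this image (falls back to 1.0 on a structureless
    image, where LP is identically zero anyway)."""
    cfg = cfg or RunConfig()
    bank = build_filter_bank(cfg)
    responses = scale_responses(image, bank)
    P = combine_scales(responses, cfg.beta)
    alpha = cfg.alpha
    if alpha is None:
        # absolute floor keeps a structureless image from saturating pure
        # round-off noise (the 0.1 * max|P| rule alone is scale-free)
        alpha = max(0.1 * float(np.abs(P).max()), 1e-6)
    return normalize_vesselness(P, alpha)
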