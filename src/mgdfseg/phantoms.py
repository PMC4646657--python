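"""Seeded synthetic fixtures: vessel phantoms and two-phase test images.

The phantoms emulate the structure the segmentation model assumes:
curvilinear bright tubes of varying width (1-10 px) on a darker
background, a smooth multiplicative bias field (intensity
inhomogeneity), and additive Gaussian sensor noise applied after the
bias.  Ground truth is captured from the geometry alone, before bias and
noise.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

__all__ = [
    "TubeSpec",
    "PhantomSpec",
    "PhantomPair",
    "generate_vessel_phantom",
    "add_bias_field",
    "add_gaussian_noise",
    "two_phase_fixture",
    "default_phantom_spec",
    "default_phantom",
]


@dataclass(frozen=True)
class TubeSpec:
    """One tube: a smooth centerline through control points (row, col),
    a width in pixels and an additive contrast against the background."""

    control_points: tuple[tuple[float, float], ...]
    width: float
    contrast: float

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError(f"tube width must be >= 1 px, got {self.width}")
        if self.contrast == 0:
            raise ValueError("tube contrast must be nonzero")
        if len(self.control_points) < 2:
            raise ValueError("a tube needs at least two control points")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int] = (128, 128)
    tubes: tuple[TubeSpec, ...] = ()
    background: float = 80.0
    bias_amplitude: float = 0.25
    bias_scale: float = 32.0
    noise_std: float = 3.0
    seed: int = 0


@dataclass
class PhantomPair:
    image: np.ndarray
    truth: np.ndarray
    spec: PhantomSpec


def _centerline_samples(tube: TubeSpec) -> np.ndarray:
    pts = np.asarray(tube.control_points, float)
    # chord-length parameterization; quadratic spline when enough points
    d = np.r_[0.0, np.cumsum(np.hypot(*np.diff(pts, axis=0).T))]
    if d[-1] == 0:
        raise ValueError("degenerate centerline: coincident control points")
    t = d / d[-1]
    k = min(2, len(pts) - 1)
    spline = make_interp_spline(t, pts, k=k)
    n = max(int(4 * d[-1]), 8)
    return spline(np.linspace(0.0, 1.0, n))


def _rasterize_tube(shape: tuple[int, int], tube: TubeSpec) -> np.ndarray:
    h, w = shape
    samples = _centerline_samples(tube)
    if (
        samples[:, 0].min() < 0
        or samples[:, 0].max() > h - 1
        or samples[:, 1].min() < 0
        or samples[:, 1].max() > w - 1
    ):
        raise ValueError("tube centerline leaves the image bounds")
    tree = cKDTree(samples)
    rr, cc = np.mgrid[0:h, 0:w]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, _ = tree.query(pix, k=1)
    return (dist.reshape(h, w) <= tube.width / 2.0).astype(np.uint8)


def generate_vessel_phantom(spec: PhantomSpec) -> PhantomPair:
    """Rasterize the tube set, then apply bias field, then noise.

    Tube pixels (distance to centerline <= width/2) take
    ``background + contrast``; the truth mask is the tube union, captured
    before bias and noise.
    """
    h, w = int(spec.shape[0]), int(spec.shape[1])
    image = np.full((h, w), float(spec.background))
    truth = np.zeros((h, w), np.uint8)
    for tube in spec.tubes:
        mask = _rasterize_tube((h, w), tube)
        image[mask == 1] = spec.background + tube.contrast
        truth |= mask
    if spec.bias_amplitude > 0:
        image = add_bias_field(image, spec.bias_amplitude, spec.bias_scale, spec.seed)
    image = add_gaussian_noise(image, spec.noise_std, spec.seed + 1)
    return PhantomPair(image=image, truth=truth, spec=spec)


def add_bias_field(
    image: np.ndarray, amplitude: float, scale: float = 32.0, seed: int = 0
) -> np.ndarray:
    """Multiply by a smooth positive field in [1-amplitude, 1+amplitude].

    The field is heavily smoothed seeded white noise, centered to mean
    exactly 1 and scaled so its extreme deviation equals ``amplitude``.
    """
    if not 0 <= amplitude < 1:
        raise ValueError(f"bias amplitude must lie in [0, 1), got {amplitude}")
    image = np.asarray(image, float)
    if amplitude == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    g = gaussian_filter(rng.standard_normal(image.shape), scale, mode="reflect")
    g -= g.mean()
    peak = np.abs(g).max()
    if peak > 0:
        g /= peak
    return image * (1.0 + amplitude * g)


def add_gaussian_noise(image: np.ndarray, std: float, seed: int = 0) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of the given std (seeded)."""
    if std < 0:
        raise ValueError(f"noise std must be >= 0, got {std}")
    image = np.asarray(image, float)
    if std == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return image + std * rng.standard_normal(image.shape)


def two_phase_fixture(
    shape: tuple[int, int] = (128, 128),
    inside_value: float = 100.0,
    outside_value: float = 20.0,
    center: Optional[tuple[float, float]] = None,
    radius: Optional[float] = None,
    noise_std: float = 0.0,
    seed: int = 0,
) -> PhantomPair:
    """Piecewise-constant disk-on-background image with exact truth.

    A pixel belongs to the disk when its center lies strictly within
    ``radius`` of ``center``.
    """
    h, w = int(shape[0]), int(shape[1])
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if radius is None:
        radius = min(h, w) / 4.0
    if (
        center[0] - radius < -0.5
        or center[0] + radius > h - 0.5
        or center[1] - radius < -0.5
        or center[1] + radius > w - 0.5
    ):
        raise ValueError("disk leaves the image bounds")
    rr, cc = np.mgrid[0:h, 0:w]
    truth = (((rr - center[0]) ** 2 + (cc - center[1]) ** 2) < radius**2).astype(np.uint8)
    image = np.where(truth == 1, float(inside_value), float(outside_value))
    image = add_gaussian_noise(image, noise_std, seed)
    spec = PhantomSpec(
        shape=(h, w), tubes=(), background=outside_value, bias_amplitude=0.0,
        noise_std=noise_std, seed=seed,
    )
    return PhantomPair(image=image, truth=truth, spec=spec)


def default_phantom_spec(
    shape: tuple[int, int] = (128, 128),
    noise_std: float = 3.0,
    bias_amplitude: float = 0.25,
    seed: int = 0,
) -> PhantomSpec:
    """The standard test phantom: three tubes of widths 2/4/7 px with one
    crossing, background 80, contrast +60 - geometry exercising the
    thin-vessel regime.  Coordinates scale with the grid."""
    h, w = int(shape[0]), int(shape[1])
    sy, sx = (h - 1) / 127.0, (w - 1) / 127.0

    def pt(r: float, c: float) -> tuple[float, float]:
        return (r * sy, c * sx)

    tubes = (
        TubeSpec(  # medium, gently curved, crosses the image horizontally
            control_points=(pt(34.3, 4.0), pt(44.6, 63.5), pt(30.2, 123.0)),
            width=4.0,
            contrast=60.0,
        ),
        TubeSpec(  # thin, runs top-to-bottom, crosses the first tube
            control_points=(pt(4.0, 81.4), pt(63.5, 68.3), pt(123.0, 75.6)),
            width=2.0,
            contrast=60.0,
        ),
        TubeSpec(  # wide, curved, lower half
            control_points=(pt(101.7, 4.0), pt(80.4, 58.2), pt(96.3, 123.0)),
            width=7.0,
            contrast=60.0,
        ),
    )
    return PhantomSpec(
        shape=(h, w),
        tubes=tubes,
        background=80.0,
        bias_amplitude=bias_amplitude,
        bias_scale=32.0 * max(sy, sx),
        noise_std=noise_std,
        seed=seed,
    )


def default_phantom(
    shape: tuple[int, int] = (128, 128),
    noise_std: float = 3.0,
    bias_amplitude: float = 0.25,
    seed: int = 0,
) -> PhantomPair:
    return generate_vessel_phantom(
        default_phantom_spec(shape, noise_std, bias_amplitude, seed)
    )
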