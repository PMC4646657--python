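"""Run configuration for the MGDF segmentation pipeline.

All tunables of the enhancement filter bank, the local Gaussian model and
the level-set iteration loop live in a single :class:`RunConfig` so that a
run is fully described by one object.  Intensities are kept on the nominal
0-255 scale throughout; the default length weight ``nu = 0.00065 * 255**2``
is calibrated for that scale and would be meaningless on [0, 1] data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any

DEFAULT_NU = 0.00065 * 255.0 * 255.0


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline.

    Filter-bank parameters
    ----------------------
    center_frequency : radial center frequency (radians/pixel) of the finest
        scale of the quadrature filter bank; halves per scale.
    bandwidth_octaves : radial bandwidth of each log-Gabor filter.
    filter_size : side of the square spatial kernels (odd).
    n_scales, n_orientations : number of scales M and orientations J.
    beta : scale-weighting exponent used when merging per-scale responses
        (>= 1).
    alpha : normalization constant of the bounded vesselness map.  ``None``
        means "0.1 * max |P|", recomputed per image.

    Local Gaussian model
    --------------------
    sigma : std of the Gaussian window defining pixel neighborhoods (px).
    lambda1_* / lambda2_* : weights of the inside/outside data terms for
        the intensity and vesselness channels.
    dt : time step of the explicit level-set update.
    nu : contour-length weight.
    mu : distance-regularization weight (keeps phi close to a signed
        distance function).
    eta, gamma, kappa : weight, spatial scale (px) and sharpness of the
        small-|phi| neighborhood penalty that discourages isolated
        components.
    epsilon : width of the regularized Heaviside/Dirac.  The arctan
        profile has heavy (1/phi) tails, so epsilon also controls how much
        each region's local statistics leak into the other at the working
        amplitude |phi| ~ c0; the default 0.1 keeps that leakage below a
        few percent and confines the curvature flow to the interface,
        where the data forces dominate.
    c0 : magnitude of the binary-step initialization of phi.

    Loop control
    ------------
    max_iters : hard iteration cap.
    tolerance : stop when the fractional change of the interior pixel count
        over a 10-iteration window falls below this value.
    """

    # quadrature filter bank
    center_frequency: float = 5.0 * math.pi / 7.0
    bandwidth_octaves: float = 2.0
    filter_size: int = 15
    n_scales: int = 3
    n_orientations: int = 6
    beta: float = 2.0
    alpha: float | None = None
    # local Gaussian model
    sigma: float = 3.0
    lambda1_intensity: float = 1.05
    lambda2_intensity: float = 1.0
    lambda1_vesselness: float = 1.05
    lambda2_vesselness: float = 1.0
    dt: float = 0.1
    nu: float = DEFAULT_NU
    mu: float = 1.0
    eta: float = 1.0
    epsilon: float = 0.1
    c0: float = 2.0
    gamma: float = 3.0
    kappa: int = 2
    # iteration loop
    max_iters: int = 400
    min_iters: int = 50
    tolerance: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.center_frequency <= math.pi:
            raise ValueError(
                f"center_frequency must lie in (0, pi], got {self.center_frequency}"
            )
        if self.filter_size < 3 or self.filter_size % 2 == 0:
            raise ValueError(f"filter_size must be odd and >= 3, got {self.filter_size}")
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("n_scales and n_orientations must be >= 1")
        if self.beta < 1.0:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.c0 <= 0:
            raise ValueError(f"c0 must be positive, got {self.c0}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if int(self.kappa) != self.kappa or self.kappa < 1:
            raise ValueError(f"kappa must be an integer >= 1, got {self.kappa}")
        for name in (
            "lambda1_intensity",
            "lambda2_intensity",
            "lambda1_vesselness",
            "lambda2_vesselness",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.min_iters < 0:
            raise ValueError("min_iters must be >= 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    # -- plumbing -----------------------------------------------------------

    def replace(self, **changes: Any) -> "RunConfig":
        """Return a copy with some fields changed (validates the result)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
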