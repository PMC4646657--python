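"""Reference region-based active-contour baselines: CV, LBF, LGDF.

All three share the level-set engine (initialization, Heaviside/Dirac,
curvature, stopping rule) with the full model; only the data forces
differ.  CV fits two global means, LBF two Gaussian-window local fitting
functions, and LGDF is exactly the multi-feature model with the
vesselness channel weights nulled.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .level_set import SegmentationResult, evolve_model, heaviside_eps
from .mgdf import MGDFModel, window_filter

__all__ = [
    "global_means",
    "local_fit_functions",
    "segment_cv",
    "segment_lbf",
    "segment_lgdf",
    "segment",
]

_DENOM_FLOOR = 1e-10


def global_means(image: np.ndarray, phi: np.ndarray, eps: float) -> tuple[float, float]:
    """Heaviside-weighted mean intensity inside (phi < 0) and outside."""
    H1 = heaviside_eps(-np.asarray(phi, float), eps)
    H2 = 1.0 - H1
    image = np.asarray(image, float)
    c1 = float((image * H1).sum() / (H1.sum() + _DENOM_FLOOR))
    c2 = float((image * H2).sum() / (H2.sum() + _DENOM_FLOOR))
    return c1, c2


def local_fit_functions(
    image: np.ndarray, phi: np.ndarray, sigma: float, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-window local mean intensities f1 (inside), f2 (outside)."""
    image = np.asarray(image, float)
    H1 = heaviside_eps(-np.asarray(phi, float), eps)
    H2 = 1.0 - H1
    f1 = window_filter(image * H1, sigma) / (window_filter(H1, sigma) + _DENOM_FLOOR)
    f2 = window_filter(image * H2, sigma) / (window_filter(H2, sigma) + _DENOM_FLOOR)
    return f1, f2


class CVModel:
    """Piecewise-constant (two global means) data model."""

    name = "cv"
    use_mu = False
    use_gamma = False

    def __init__(self, image: np.ndarray, cfg: RunConfig):
        self.image = np.asarray(image, float)
        if self.image.ndim != 2 or min(self.image.shape) < 3:
            raise ValueError("image must be a 2-D grid of at least 3x3")
        self.cfg = cfg
        self.shape = self.image.shape
        self.c1 = np.nan
        self.c2 = np.nan

    def data_terms(self, phi: np.ndarray) -> tuple[np.ndarray, float, float]:
        cfg = self.cfg
        self.c1, self.c2 = global_means(self.image, phi, cfg.epsilon)
        d1 = (self.image - self.c1) ** 2
        d2 = (self.image - self.c2) ** 2
        force = cfg.lambda1_intensity * d1 - cfg.lambda2_intensity * d2
        H1 = heaviside_eps(-phi, cfg.epsilon)
        data_i = float(
            (cfg.lambda1_intensity * d1 * H1 + cfg.lambda2_intensity * d2 * (1.0 - H1)).sum()
        )
        return force, data_i, 0.0


class LBFModel:
    """Local binary fitting data model (window-weighted local means)."""

    name = "lbf"
    use_mu = True
    use_gamma = False

    def __init__(self, image: np.ndarray, cfg: RunConfig):
        self.image = np.asarray(image, float)
        if self.image.ndim != 2 or min(self.image.shape) < 3:
            raise ValueError("image must be a 2-D grid of at least 3x3")
        self.cfg = cfg
        self.shape = self.image.shape
        self.f1: np.ndarray | None = None
        self.f2: np.ndarray | None = None

    def data_terms(self, phi: np.ndarray) -> tuple[np.ndarray, float, float]:
        cfg = self.cfg
        I = self.image
        self.f1, self.f2 = local_fit_functions(I, phi, cfg.sigma, cfg.epsilon)
        # e_i(x) = int K(y-x) (I(x) - f_i(y))^2 dy, expanded around I(x)
        e1 = I * I - 2.0 * I * window_filter(self.f1, cfg.sigma) + window_filter(
            self.f1 * self.f1, cfg.sigma
        )
        e2 = I * I - 2.0 * I * window_filter(self.f2, cfg.sigma) + window_filter(
            self.f2 * self.f2, cfg.sigma
        )
        force = cfg.lambda1_intensity * e1 - cfg.lambda2_intensity * e2
        # energy form of the fitting term: int K(x-y)(I(y) - f_i(x))^2 dy,
        # weighted by H_i at the window center x
        wI = window_filter(I, cfg.sigma)
        wI2 = window_filter(I * I, cfg.sigma)
        g1 = wI2 - 2.0 * self.f1 * wI + self.f1 * self.f1
        g2 = wI2 - 2.0 * self.f2 * wI + self.f2 * self.f2
        H1 = heaviside_eps(-phi, cfg.epsilon)
        data_i = float(
            (cfg.lambda1_intensity * g1 * H1 + cfg.lambda2_intensity * g2 * (1.0 - H1)).sum()
        )
        return force, data_i, 0.0


def segment_cv(
    image: np.ndarray,
    cfg: Optional[RunConfig] = None,
    seeds: Optional[Sequence[tuple[float, float, float]]] = None,
    phi0: Optional[np.ndarray] = None,
) -> SegmentationResult:
    """Two-phase piecewise-constant segmentation (global means)."""
    cfg = cfg or RunConfig()
    return evolve_model(CVModel(image, cfg), cfg, seeds, phi0)


def segment_lbf(
    image: np.ndarray,
    cfg: Optional[RunConfig] = None,
    seeds: Optional[Sequence[tuple[float, float, float]]] = None,
    phi0: Optional[np.ndarray] = None,
) -> SegmentationResult:
    """Local binary fitting segmentation."""
    cfg = cfg or RunConfig()
    return evolve_model(LBFModel(image, cfg), cfg, seeds, phi0)


def segment_lgdf(
    image: np.ndarray,
    cfg: Optional[RunConfig] = None,
    seeds: Optional[Sequence[tuple[float, float, float]]] = None,
    phi0: Optional[np.ndarray] = None,
) -> SegmentationResult:
    """Single-feature local Gaussian distribution fitting segmentation.

    Delegates to the multi-feature model with both vesselness weights set
    to zero and a zero vesselness channel; by construction the result is
    identical (bit for bit) to the full pipeline under that weight
    nulling, whatever vesselness map the latter is given.
    """
    cfg = (cfg or RunConfig()).replace(lambda1_vesselness=0.0, lambda2_vesselness=0.0)
    image = np.asarray(image, float)
    model = MGDFModel(image, np.zeros_like(image), cfg)
    model.name = "lgdf"
    return evolve_model(model, cfg, seeds, phi0)


_SEGMENTERS = {"cv": segment_cv, "lbf": segment_lbf, "lgdf": segment_lgdf}


def segment(
    model: str,
    image: np.ndarray,
    vesselness: Optional[np.ndarray] = None,
    cfg: Optional[RunConfig] = None,
    seeds: Optional[Sequence[tuple[float, float, float]]] = None,
    phi0: Optional[np.ndarray] = None,
) -> SegmentationResult:
    """Dispatch by model name: 'cv', 'lbf', 'lgdf' or 'mgdf'."""
    from .level_set import evolve

    if model == "mgdf":
        if vesselness is None:
            from .local_phase import enhance

            vesselness = enhance(image, cfg or RunConfig())
        return evolve(image, vesselness, cfg, seeds, phi0)
    try:
        fn = _SEGMENTERS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; choose from cv, lbf, lgdf, mgdf")
    return fn(image, cfg, seeds, phi0)
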