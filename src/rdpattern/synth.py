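"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the three kinds of measured data the analysis modules
consume -- culture-insert intensity profiles, luminescence pattern images and
cycloheximide-chase decay courses -- with the embedded true parameters
recorded, so parameter recovery can be tested end to end. They are test
fixtures with controllable noise, not claims about the real measurement
noise. Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .gradient import DecayCourse, ProfileSet
from .metrics import ImageField
from .params import ModelKind, ModelParameters
from .simulate import SimulationConfig, StateField, integrate, make_initial_condition

__all__ = [
    "SyntheticSpec",
    "gen_gradient_profiles",
    "gen_decay_course",
    "gen_pattern_image",
    "gen_timelapse",
]

NOISE_MODELS = ("none", "multiplicative_lognormal", "additive_gaussian", "poisson_like")


@dataclass
class SyntheticSpec:
    """Noise model, seed and the ground truth embedded by a generator.

    ``multiplicative_lognormal`` multiplies by exp(sigma * Z) (intensity data
    are ratio-scale); ``additive_gaussian`` adds sigma * A * Z with A the
    clean signal's maximum; ``poisson_like`` draws shot-like counts with
    variance = sigma^2 * mean.
    """

    seed: int = 0
    noise_model: str = "multiplicative_lognormal"
    noise_sigma: float = 0.1
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply_noise(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.noise_model == "none" or self.noise_sigma == 0.0:
            return clean.copy()
        if self.noise_model == "multiplicative_lognormal":
            return clean * np.exp(self.noise_sigma * rng.standard_normal(clean.shape))
        if self.noise_model == "additive_gaussian":
            scale = self.noise_sigma * np.max(np.abs(clean))
            return clean + scale * rng.standard_normal(clean.shape)
        # poisson_like: variance = sigma^2 * mean, preserving the mean
        lam = np.clip(clean, 0.0, None) / self.noise_sigma**2
        return rng.poisson(lam) * self.noise_sigma**2


def _logistic_step(x: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth 1 -> 0 step crossing 0.5 at ``center`` over ~``width`` pixels."""
    return 1.0 / (1.0 + np.exp((x - center) / (width / 4.0)))


def gen_gradient_profiles(
    lambda_true: float,
    C_true: float,
    boundary_px: int,
    n_replicates: int = 3,
    length_px: int = 300,
    pixel_size: float = 1.6,
    spec: SyntheticSpec | None = None,
    boundary_width_px: float = 10.0,
) -> ProfileSet:
    """Culture-insert profile set with an exponential ligand gradient.

    The marker is a logistic step crossing 0.5 at ``boundary_px``; the ligand
    signal sits on a producer-side plateau and decays on the receptor side as
    (1 - C) exp(-d / lambda) + C with d the distance past the boundary in um.
    Replicates get independent noise and independent overall scale factors.
    """
    if spec is None:
        spec = SyntheticSpec()
    if boundary_px < 51:
        raise ValueError("boundary_px must be >= 51 so the reference window fits")
    if not 0 <= C_true < 1:
        raise ValueError("C_true must be in [0, 1)")
    if lambda_true <= 0:
        raise ValueError("lambda_true must be positive")
    if boundary_px >= length_px:
        raise ValueError("boundary must lie inside the profile")
    rng = spec.rng()
    x = np.arange(1, length_px + 1, dtype=float)  # 1-based pixel positions
    # center the step half a pixel before the boundary so the 0.5 crossing is
    # detected at exactly boundary_px (first pixel at or below 0.5)
    mch_clean = _logistic_step(x, boundary_px - 0.5, boundary_width_px)
    d_um = np.clip(x - boundary_px, 0.0, None) * pixel_size
    hibit_clean = (1.0 - C_true) * np.exp(-d_um / lambda_true) + C_true

    hibit = np.empty((n_replicates, length_px))
    mcherry = np.empty((n_replicates, length_px))
    for r in range(n_replicates):
        scale_h = rng.uniform(500.0, 2000.0)  # arbitrary camera units
        scale_m = rng.uniform(500.0, 2000.0)
        hibit[r] = spec.apply_noise(scale_h * hibit_clean, rng)
        mcherry[r] = spec.apply_noise(scale_m * mch_clean, rng)
    spec.truth.update(
        lambda_um=lambda_true, C=C_true, boundary_px=boundary_px, pixel_size=pixel_size
    )
    return ProfileSet(hibit, mcherry, pixel_size)


def gen_decay_course(
    gamma_true: float,
    times: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 360.0),
    spec: SyntheticSpec | None = None,
    I0: float = 1000.0,
) -> DecayCourse:
    """Cycloheximide-chase band intensities I(t) = I0 exp(-gamma t) + noise."""
    if spec is None:
        spec = SyntheticSpec()
    if gamma_true <= 0:
        raise ValueError("gamma_true must be positive")
    t = np.asarray(times, dtype=float)
    clean = I0 * np.exp(-gamma_true * t)
    noisy = np.clip(spec.apply_noise(clean, spec.rng()), 1e-12, None)
    spec.truth.update(gamma=gamma_true, I0=I0)
    return DecayCourse(t, noisy)


def _hex_lattice(period: float, extent: float) -> np.ndarray:
    """Hexagonal lattice points with nearest-neighbor distance ``period``."""
    row_h = period * np.sqrt(3.0) / 2.0
    pts = []
    n_rows = int(np.ceil(extent / row_h)) + 2
    n_cols = int(np.ceil(extent / period)) + 2
    for r in range(-1, n_rows):
        offset = 0.5 * period if r % 2 else 0.0
        for c in range(-1, n_cols):
            pts.append((c * period + offset, r * row_h))
    return np.asarray(pts)


def gen_pattern_image(
    kind: str,
    period: float = 400.0,
    domain_diameter: float = 200.0,
    size_px: int = 128,
    pixel_size: float = 8.0,
    spec: SyntheticSpec | None = None,
    background: float = 0.05,
    simulation: tuple[ModelParameters, ModelKind, SimulationConfig, StateField] | None = None,
) -> ImageField:
    """A pattern image of bright domains with known period and size.

    kinds: ``spots`` (hexagonal lattice of discs), ``stripes`` (parallel
    bands), ``rings`` (concentric cosine rings), ``from_simulation`` (final
    Nodal field of a 2D reaction-diffusion run passed via ``simulation``).
    """
    if spec is None:
        spec = SyntheticSpec(noise_model="poisson_like")
    rng = spec.rng()
    extent = size_px * pixel_size
    yy, xx = np.mgrid[0:size_px, 0:size_px] * pixel_size

    if kind == "from_simulation":
        if simulation is None:
            raise ValueError("kind='from_simulation' requires the simulation tuple")
        p, m, cfg, init = simulation
        res = integrate(init, p, m, cfg)
        clean = res.final.N_field
        img = spec.apply_noise(clean, rng)
        spec.truth.update(source="simulation")
        return ImageField(img, cfg.dx)

    if kind == "spots":
        if period <= domain_diameter:
            raise ValueError("spot period must exceed the domain diameter")
        pts = _hex_lattice(period, extent)
        d2 = np.full((size_px, size_px), np.inf)
        for px, py in pts:
            d2 = np.minimum(d2, (xx - px) ** 2 + (yy - py) ** 2)
        clean = np.where(np.sqrt(d2) <= domain_diameter / 2.0, 1.0, background)
    elif kind == "stripes":
        if period <= domain_diameter:
            raise ValueError("stripe period must exceed the band width")
        phase = np.mod(xx, period)
        clean = np.where(phase <= domain_diameter, 1.0, background)
    elif kind == "rings":
        cx = extent / 2.0
        r = np.hypot(xx - cx, yy - cx)
        clean = 0.5 * (1.0 + np.cos(2.0 * np.pi * r / period))
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    img = spec.apply_noise(clean, rng)
    spec.truth.update(kind=kind, period_um=period, domain_diameter_um=domain_diameter)
    return ImageField(img, pixel_size)


def gen_timelapse(
    stabilize_at: int,
    n_frames: int,
    spec: SyntheticSpec | None = None,
    period: float = 400.0,
    domain_diameter: float = 200.0,
    size_px: int = 96,
    pixel_size: float = 8.0,
) -> list[ImageField]:
    """Frames of a pattern that settles at ``stabilize_at``.

    Before stabilization the bright domains grow and drift between frames;
    afterwards the underlying pattern is frozen and only per-frame noise
    varies -- mimicking a time-lapse whose frame-to-frame similarity rises to
    a plateau once the pattern locks in.
    """
    if spec is None:
        spec = SyntheticSpec(noise_model="poisson_like")
    if not 0 < stabilize_at < n_frames:
        raise ValueError("need 0 < stabilize_at < n_frames")
    rng = spec.rng()
    extent = size_px * pixel_size
    yy, xx = np.mgrid[0:size_px, 0:size_px] * pixel_size
    pts = _hex_lattice(period, extent)
    drift_per_frame = 0.15 * period
    frames: list[ImageField] = []
    for k in range(n_frames):
        kk = min(k, stabilize_at)
        growth = 0.4 + 0.6 * kk / stabilize_at  # radius fraction
        offset = drift_per_frame * (stabilize_at - kk)
        d2 = np.full((size_px, size_px), np.inf)
        for px, py in pts:
            d2 = np.minimum(d2, (xx - (px + offset)) ** 2 + (yy - (py + 0.5 * offset)) ** 2)
        clean = np.where(np.sqrt(d2) <= growth * domain_diameter / 2.0, 1.0, 0.05)
        frames.append(ImageField(spec.apply_noise(clean, rng), pixel_size))
    spec.truth.update(
        stabilize_at=stabilize_at, n_frames=n_frames,
        period_um=period, domain_diameter_um=domain_diameter,
    )
    return frames
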