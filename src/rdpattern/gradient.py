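"""Quantification of ligand gradients from culture-insert profiles.

A culture insert seeds ligand-producing cells (marked with mCherry) next to
receptor cells, establishing a straight boundary. The extracellular ligand is
visualized by split-luciferase complementation and averaged into a 1D
intensity profile A_HiBiT(x); the marker gives A_Che(x). The pipeline is:

1. min-max normalize the marker profile,
2. locate the boundary x_0.5 where the normalized marker drops to 0.5,
3. normalize the ligand profile by the mean of the 50 pixels on the
   producer side of the boundary,
4. average replicates and fit the receptor-side decay to
   (1 - C) exp(-x / lambda) + C, with x in um re-origined at the boundary.

lambda is the characteristic distance (the point where the background-free
signal drops to 1/e) and satisfies lambda = sqrt(D / gamma): together with a
degradation rate gamma from a cycloheximide chase it yields the effective
diffusion coefficient D = lambda^2 * gamma.

Pixel positions follow the 1-based convention x in [1, length] at the
interface; distances are converted with the pixel size (default 1.6 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ProfileSet",
    "GradientFit",
    "DecayCourse",
    "normalize_mcherry",
    "find_boundary",
    "normalize_hibit",
    "fit_gradient",
    "fit_degradation",
    "effective_diffusion",
    "range_ratios",
    "analyze_profiles",
]

#: pixels averaged on the producer side of the boundary for ligand normalization
REFERENCE_WINDOW = 50


@dataclass
class ProfileSet:
    """Replicate ligand (HiBiT) and marker (mCherry) intensity profiles.

    ``hibit`` and ``mcherry`` are (n_replicates, length) arrays in arbitrary
    units; pixel 1 is deep inside the ligand-producing region and the last
    pixel deep inside the receptor region.
    """

    hibit: np.ndarray
    mcherry: np.ndarray
    pixel_size: float = 1.6

    def __post_init__(self) -> None:
        self.hibit = np.atleast_2d(np.asarray(self.hibit, dtype=float))
        self.mcherry = np.atleast_2d(np.asarray(self.mcherry, dtype=float))
        if self.hibit.shape != self.mcherry.shape:
            raise ValueError("hibit and mcherry must have the same shape")
        if self.hibit.shape[1] < 100:
            raise ValueError("profiles must have at least 100 pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_replicates(self) -> int:
        return self.hibit.shape[0]

    @property
    def length(self) -> int:
        return self.hibit.shape[1]


@dataclass
class GradientFit:
    """Exponential-gradient fit: decay length, background and boundary."""

    lambda_: float  # characteristic distance, um
    C: float  # background fraction in [0, 1)
    x_half: int  # boundary pixel (1-based)
    I_profile: np.ndarray  # background-subtracted normalized distribution
    fit_rmse: float

    def diffusion_coefficient(self, gamma: float) -> float:
        return effective_diffusion(self.lambda_, gamma)


@dataclass
class DecayCourse:
    """A cycloheximide-chase time course: band intensity vs time (min)."""

    times: np.ndarray = field(default_factory=lambda: np.array([0.0, 60.0, 120.0, 180.0, 360.0]))
    intensities: np.ndarray = field(default_factory=lambda: np.ones(5))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be matching 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be positive")


def normalize_mcherry(profile: ProfileSet) -> np.ndarray:
    """Min-max normalize each marker replicate to [0, 1] over the full span."""
    a = profile.mcherry
    lo = a.min(axis=1, keepdims=True)
    hi = a.max(axis=1, keepdims=True)
    if np.any(hi - lo <= 0):
        raise ValueError("constant mCherry profile: zero dynamic range")
    return (a - lo) / (hi - lo)


def find_boundary(n_che: np.ndarray) -> int:
    """First pixel (1-based, scanning from the ligand side) with N_Che <= 0.5."""
    n_che = np.asarray(n_che, dtype=float)
    if n_che.ndim != 1:
        raise ValueError("find_boundary expects a single 1D profile")
    below = np.nonzero(n_che <= 0.5)[0]
    if below.size == 0:
        raise ValueError("marker profile never drops to 0.5: no boundary found")
    return int(below[0]) + 1


def normalize_hibit(profile: ProfileSet, x_half: int) -> np.ndarray:
    """Divide each ligand replicate by its producer-side reference mean.

    The reference is the mean over the ``REFERENCE_WINDOW`` pixels
    immediately before the boundary, positions [x_half - 50, x_half - 1]
    in the 1-based convention.
    """
    if x_half < REFERENCE_WINDOW + 1:
        raise ValueError(
            f"x_half = {x_half}: the {REFERENCE_WINDOW}-pixel reference window "
            "does not fit on the ligand side"
        )
    window = slice(x_half - REFERENCE_WINDOW - 1, x_half - 1)  # 0-based
    ref = profile.hibit[:, window].mean(axis=1, keepdims=True)
    if np.any(ref <= 0):
        raise ValueError("non-positive reference mean in the ligand-side window")
    return profile.hibit / ref


def _decay_model(x: np.ndarray, lam: float, C: float) -> np.ndarray:
    return (1.0 - C) * np.exp(-x / lam) + C


def fit_gradient(
    mean_profile: np.ndarray,
    x_half: int,
    pixel_size: float = 1.6,
    lambda0: float = 50.0,
) -> GradientFit:
    """Fit the receptor-side decay of the replicate-mean normalized profile.

    The profile is restricted to x >= x_half, re-origined at the boundary and
    converted to um; nonlinear least squares estimates lambda (bounded by the
    receptor-side span) and the background fraction C in [0, 1).
    """
    mean_profile = np.asarray(mean_profile, dtype=float)
    if mean_profile.ndim != 1:
        raise ValueError("fit expects the replicate-averaged 1D profile")
    y = mean_profile[x_half - 1 :]
    if y.size < 5:
        raise ValueError("too few receptor-side pixels to fit")
    x_um = np.arange(y.size, dtype=float) * pixel_size
    span = x_um[-1]
    c0 = float(np.clip(y[-max(5, y.size // 10) :].min(), 0.0, 0.99))
    try:
        popt, _ = curve_fit(
            _decay_model, x_um, y,
            p0=[min(lambda0, span), c0],
            bounds=([1e-9, 0.0], [span, 1.0 - 1e-9]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"gradient fit did not converge (p0 lambda={lambda0}, C={c0}): {err}"
        ) from err
    lam, C = float(popt[0]), float(popt[1])
    resid = _decay_model(x_um, lam, C) - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    I_profile = (y - C) / (1.0 - C)
    return GradientFit(lam, C, x_half, I_profile, rmse)


def fit_degradation(course: DecayCourse) -> float:
    """Degradation rate gamma (min^-1) from a log-linear fit of the chase.

    First-order decay I(t) = I0 exp(-gamma t) gives a straight line in
    ln(intensity) vs time; gamma is minus the OLS slope.
    """
    if course.times.size < 2:
        raise ValueError("need at least two time points")
    slope = np.polyfit(course.times, np.log(course.intensities), 1)[0]
    return float(-slope)


def effective_diffusion(lambda_: float, gamma: float) -> float:
    """Effective diffusion coefficient D = lambda^2 * gamma (um^2 min^-1)."""
    if lambda_ <= 0 or gamma <= 0:
        raise ValueError("lambda and gamma must be positive")
    return lambda_**2 * gamma


def range_ratios(
    lambda_N: float, lambda_L: float, gamma_N: float, gamma_L: float
) -> tuple[float, float, float, float]:
    """Inhibitor-vs-activator range and diffusivity ratios.

    Returns
    -------
    range_ratio : lambda_L / lambda_N -- how much farther the inhibitor reaches.
    degradation_ratio : gamma_L / gamma_N -- how much faster it is degraded.
    equal_gamma_D_ratio : (lambda_L / lambda_N)^2 -- the diffusivity ratio if
        the degradation rates were equal.
    full_D_ratio : (lambda_L^2 gamma_L) / (lambda_N^2 gamma_N) = D_L / D_N.
    """
    if min(lambda_N, lambda_L, gamma_N, gamma_L) <= 0:
        raise ValueError("all inputs must be positive")
    range_ratio = lambda_L / lambda_N
    degradation_ratio = gamma_L / gamma_N
    equal_gamma = range_ratio**2
    full = equal_gamma * degradation_ratio
    return range_ratio, degradation_ratio, equal_gamma, full


def analyze_profiles(profile: ProfileSet, lambda0: float = 50.0) -> GradientFit:
    """Run the full pipeline on a replicate set.

    Boundary detection uses the replicate-averaged marker: replicates are
    min-max normalized, averaged, and the average is re-scaled to [0, 1] so
    the 0.5 threshold refers to the averaged profile's own dynamic range
    (with noisy replicates, a single replicate's extremes would otherwise
    depress the average and bias the crossing toward the ligand side).
    Ligand profiles are normalized per replicate, averaged, and the mean is
    fitted from the detected boundary.
    """
    n_che = normalize_mcherry(profile).mean(axis=0)
    n_che = (n_che - n_che.min()) / (n_che.max() - n_che.min())
    x_half = find_boundary(n_che)
    n_hibit = normalize_hibit(profile, x_half)
    return fit_gradient(n_hibit.mean(axis=0), x_half, profile.pixel_size, lambda0)
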