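"""Image metrics for luminescence patterns: periodicity, stability, domain size.

Periodicity is read from the normalized spatial autocorrelation

    C(x, y) = sum_{X,Y} (I(X,Y) - Ibar)(I(X+x, Y+y) - Ibar)
              / sum_{X,Y} (I(X,Y) - Ibar)^2,

summed over all pixels with out-of-image shifts contributing zero. Its radial
average C(r) has a second peak at the pattern repeat distance (peak-to-peak
spacing). Temporal stability is scored with the structural similarity index
(SSIM) between frames, and positive-domain sizes are measured by smoothing,
midpoint thresholding and connected-component analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import gaussian as _gaussian_filter
from skimage.measure import label as _label, regionprops as _regionprops
from skimage.metrics import structural_similarity as _ssim

__all__ = [
    "ImageField",
    "CorrelationProfile",
    "spatial_correlation",
    "radial_average",
    "find_second_peak",
    "ssim",
    "domain_widths",
    "correlation_profile",
]


@dataclass
class ImageField:
    """A 2D intensity image with physical pixel size (um)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 16:
            raise ValueError("image must be 2D, at least 16x16")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class CorrelationProfile:
    """Radially averaged autocorrelation C(r) and its second peak, if any."""

    radii: np.ndarray  # um, strictly increasing from 0
    values: np.ndarray
    second_peak_r: float | None = None
    second_peak_height: float | None = None


def spatial_correlation(img: ImageField) -> np.ndarray:
    """Normalized autocorrelation map over all pixel shifts.

    Returns a (2H-1, 2W-1) map with zero lag at the center: C(0,0) = 1 and
    C(x,y) = C(-x,-y). Computed with an FFT correlation of the mean-subtracted
    image, which equals the direct zero-padded sums to rounding error.
    """
    I = img.pixels
    dI = I - I.mean()
    denom = float(np.sum(dI * dI))
    if denom == 0.0:
        raise ValueError("constant image: autocorrelation undefined")
    corr = fftconvolve(dI, dI[::-1, ::-1], mode="full") / denom
    center = (corr.shape[0] // 2, corr.shape[1] // 2)
    corr[center] = 1.0  # exact by definition; guards FFT rounding
    return corr


def radial_average(
    corr_map: np.ndarray, pixel_size: float, bin_width: float | None = None
) -> CorrelationProfile:
    """Angular average of a centered correlation map into annular bins.

    Each lag (x, y) falls into the bin whose center k * bin_width is nearest
    to r = sqrt(x^2 + y^2); bin values are plain means and empty bins are
    filled by linear interpolation. The default bin width is two pixels, so
    bin 0 holds only the zero lag and the profile starts at exactly C(0) = 1.
    """
    if bin_width is None:
        bin_width = 2.0 * pixel_size
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    corr_map = np.asarray(corr_map, dtype=float)
    cy, cx = corr_map.shape[0] // 2, corr_map.shape[1] // 2
    y = (np.arange(corr_map.shape[0]) - cy)[:, None]
    x = (np.arange(corr_map.shape[1]) - cx)[None, :]
    r = np.hypot(x, y) * pixel_size
    # nearest bin, ties away from the center so bin k covers
    # [k - 1/2, k + 1/2) bin widths and bin 0 holds only r < bin_width / 2
    idx = np.floor(r / bin_width + 0.5).astype(int)
    nbins = idx.max() + 1
    sums = np.bincount(idx.ravel(), weights=corr_map.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    values = np.full(nbins, np.nan)
    nonempty = counts > 0
    values[nonempty] = sums[nonempty] / counts[nonempty]
    if np.any(~nonempty):
        bins = np.arange(nbins)
        values[~nonempty] = np.interp(bins[~nonempty], bins[nonempty], values[nonempty])
    radii = np.arange(nbins) * bin_width
    return CorrelationProfile(radii, values)


def find_second_peak(profile: CorrelationProfile, smooth_bins: int = 3) -> CorrelationProfile:
    """Locate the pattern-repeat peak of C(r); absence is a valid result.

    After a moving-average smoothing, the first local minimum at r > 0 is
    found, then the first subsequent local maximum with positive height.
    A plateau returns its leftmost bin. Returns a new profile with the
    ``second_peak_*`` fields set (or left None for monotone decay).
    """
    v = np.asarray(profile.values, dtype=float)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        pad = smooth_bins // 2
        v = np.convolve(np.pad(v, pad, mode="edge"), kernel, mode="valid")
    n = v.size
    i_min = None
    for i in range(1, n - 1):
        if v[i] <= v[i - 1] and v[i] < v[i + 1]:
            i_min = i
            break
    out = CorrelationProfile(profile.radii, profile.values)
    if i_min is None:
        return out
    j = i_min + 1
    while j < n:
        if v[j] > v[j - 1]:
            # candidate peak; absorb any plateau of equal values
            k = j
            while k + 1 < n and v[k + 1] == v[j]:
                k += 1
            if (k == n - 1 or v[k + 1] < v[j]) and v[j] > 0:
                out.second_peak_r = float(profile.radii[j])
                out.second_peak_height = float(profile.values[j])
                return out
            j = k + 1
        else:
            j += 1
    return out


def ssim(img_a: ImageField, img_b: ImageField, sigma: float = 1.5) -> float:
    """Structural similarity index between two images, in [-1, 1].

    Standard SSIM with a Gaussian window (default sigma 1.5 px) and constants
    C1 = (0.01 R)^2, C2 = (0.03 R)^2 where R is the joint dynamic range.
    Identical images score 1; a higher score between consecutive time-lapse
    frames means a more stable pattern.
    """
    a, b = img_a.pixels, img_b.pixels
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    joint_min = min(a.min(), b.min())
    joint_max = max(a.max(), b.max())
    data_range = joint_max - joint_min
    if data_range == 0.0:
        return 1.0  # two constant, equal images
    return float(
        _ssim(
            a, b,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def domain_widths(
    img: ImageField,
    smooth_sigma: float = 2.0,
    exclude_border: bool = True,
) -> tuple[list[float], float, float, int]:
    """Sizes of bright (signal-positive) domains in an image.

    Procedure: Gaussian smoothing (sigma in px), threshold at the midpoint
    (min + max) / 2 of the smoothed image, 8-connected components, border
    touchers excluded, and each domain reported as its equivalent circular
    diameter in um.

    Returns (widths, mean, sd, count); an image with no interior domains
    yields an empty list and NaN summary statistics.
    """
    I = img.pixels
    if I.max() == I.min():
        raise ValueError("constant image: no domains")
    smoothed = _gaussian_filter(I, sigma=smooth_sigma, preserve_range=True)
    thresh = 0.5 * (smoothed.min() + smoothed.max())
    binary = smoothed > thresh
    labels = _label(binary, connectivity=2)
    widths: list[float] = []
    h, w = binary.shape
    for region in _regionprops(labels):
        if exclude_border:
            minr, minc, maxr, maxc = region.bbox
            if minr == 0 or minc == 0 or maxr == h or maxc == w:
                continue
        widths.append(float(region.equivalent_diameter_area) * img.pixel_size)
    if widths:
        arr = np.asarray(widths)
        return widths, float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0, len(widths)
    return [], float("nan"), float("nan"), 0


def correlation_profile(img: ImageField, bin_width: float | None = None) -> CorrelationProfile:
    """Convenience: autocorrelation -> radial average -> second-peak search."""
    return find_second_peak(radial_average(spatial_correlation(img), img.pixel_size, bin_width))
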