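"""Scanning-window texture features for masked OCT B-scans.

A 15 x 15 pixel window (about 53 x 53 um^2) slides over the image with
stride 1.  A position is admitted only when *all* of its pixels lie
inside the tissue mask; each admitted window contributes four local
statistics — mean (mu), population standard deviation (sigma),
intensity range (max - min) and coefficient of variation (CV =
sigma/mu, defined as 0 when mu = 0).  That yields four per-image
distributions, each summarized by its mean, standard deviation and
median: 12 features per image, which are then averaged over all images
of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .octmask import MaskImage, OCTImage

__all__ = [
    "WindowStats",
    "StatDistributions",
    "ImageFeatureVector",
    "SampleOCTFeatures",
    "OCT_FEATURE_NAMES",
    "UnfeaturableImageError",
    "window_stats",
    "scan_image",
    "summarize_distributions",
    "aggregate_sample",
]

WINDOW_PARAMS = ("mu", "sigma", "range", "cv")
SUMMARY_PREFIXES = ("m", "s", "md")  # mean, std, median

#: the 12 per-image feature names, grouped by window parameter:
#: m_mu, s_mu, md_mu, m_sigma, ..., md_cv
OCT_FEATURE_NAMES = tuple(
    f"{pre}_{par}" for par in WINDOW_PARAMS for pre in SUMMARY_PREFIXES
)


class UnfeaturableImageError(ValueError):
    """Raised when an image admits no scanning window at all."""


@dataclass(frozen=True)
class WindowStats:
    mu: float
    sigma: float
    range: float
    cv: float


@dataclass
class StatDistributions:
    """Per-image distributions of the four window statistics."""

    mu_values: np.ndarray
    sigma_values: np.ndarray
    range_values: np.ndarray
    cv_values: np.ndarray

    def __post_init__(self) -> None:
        lens = {
            len(self.mu_values),
            len(self.sigma_values),
            len(self.range_values),
            len(self.cv_values),
        }
        if len(lens) != 1:
            raise ValueError("all four distributions must have equal length")

    @property
    def n_windows(self) -> int:
        return len(self.mu_values)


@dataclass
class ImageFeatureVector:
    """The 12 scanning-window summary features for one image."""

    features: dict[str, float]
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if tuple(self.features) != OCT_FEATURE_NAMES:
            raise ValueError("features must carry exactly the 12 canonical names")


@dataclass
class SampleOCTFeatures:
    sample_id: str | None
    features: dict[str, float]
    n_images: int


def window_stats(values) -> WindowStats:
    """Four statistics of one window's intensity values.

    sigma is the population standard deviation (divisor n); CV is
    sigma/mu with the convention CV = 0 when mu = 0.
    """
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("window_stats requires a non-empty value list")
    mu = float(arr.mean())
    sigma = float(arr.std())
    rng = float(arr.max() - arr.min())
    cv = sigma / mu if mu != 0.0 else 0.0
    return WindowStats(mu=mu, sigma=sigma, range=rng, cv=cv)


def scan_image(
    image: OCTImage,
    mask: MaskImage,
    window: int = 15,
    stride: int = 1,
) -> StatDistributions:
    """Collect window statistics at every admissible position.

    A window anchored at (i, j) (top-left corner, stride steps in both
    directions) is admissible when it lies fully inside the image and
    all window pixels are masked.  An oversized window yields empty
    distributions (``n_windows == 0``) rather than an error.
    """
    if not mask.fully_processed:
        raise ValueError("scan_image requires a fully processed mask "
                         "(thresholded, voids filled, saturation removed)")
    if mask.mask.shape != image.pixels.shape:
        raise ValueError("mask and image shapes differ")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    h, w = image.pixels.shape
    empty = np.empty(0, dtype=np.float64)
    if window > h or window > w:
        return StatDistributions(empty, empty, empty, empty)

    img = image.pixels.astype(np.float64)
    # admissible centers: minimum of the mask over the window is 1 and
    # the window is fully inside the image (constant-0 padding).
    adm = ndimage.minimum_filter(
        mask.mask.astype(np.uint8), size=window, mode="constant", cval=0
    ).astype(bool)

    # mean/variance via windowed moving averages; intensities are first
    # centered on the global mean to avoid cancellation in E[x^2]-E[x]^2
    c = img.mean()
    d = img - c
    mean_d = ndimage.uniform_filter(d, size=window, mode="constant", cval=0.0)
    mean_d2 = ndimage.uniform_filter(d * d, size=window, mode="constant", cval=0.0)
    var = np.clip(mean_d2 - mean_d * mean_d, 0.0, None)
    mx = ndimage.maximum_filter(img, size=window, mode="constant", cval=-np.inf)
    mn = ndimage.minimum_filter(img, size=window, mode="constant", cval=np.inf)

    r = window // 2
    sl = (slice(r, h - window + 1 + r, stride), slice(r, w - window + 1 + r, stride))
    keep = adm[sl]
    mu = (mean_d + c)[sl][keep]
    sigma = np.sqrt(var[sl][keep])
    rng = (mx - mn)[sl][keep]
    cv = np.divide(sigma, mu, out=np.zeros_like(sigma), where=mu > 1e-12)
    return StatDistributions(mu, sigma, rng, cv)


def summarize_distributions(d: StatDistributions) -> ImageFeatureVector:
    """Mean, standard deviation and median of each distribution (12 features).

    The standard deviation uses divisor n; the median of an even-length
    distribution is the mean of the middle pair (numpy convention).
    """
    if d.n_windows == 0:
        raise UnfeaturableImageError(
            "no admissible scanning window: image cannot be featurized"
        )
    feats: dict[str, float] = {}
    for par, values in zip(
        WINDOW_PARAMS, (d.mu_values, d.sigma_values, d.range_values, d.cv_values)
    ):
        feats[f"m_{par}"] = float(np.mean(values))
        feats[f"s_{par}"] = float(np.std(values))
        feats[f"md_{par}"] = float(np.median(values))
    ordered = {name: feats[name] for name in OCT_FEATURE_NAMES}
    return ImageFeatureVector(features=ordered)


def aggregate_sample(vectors: list[ImageFeatureVector]) -> SampleOCTFeatures:
    """Feature-wise arithmetic mean over one sample's images."""
    if not vectors:
        raise ValueError("aggregate_sample requires at least one image vector")
    ids = {v.sample_id for v in vectors}
    if len(ids) != 1:
        raise ValueError(f"mixed sample ids in aggregate_sample: {sorted(map(str, ids))}")
    stacked = np.array([[v.features[name] for name in OCT_FEATURE_NAMES] for v in vectors])
    means = stacked.mean(axis=0)
    return SampleOCTFeatures(
        sample_id=vectors[0].sample_id,
        features={name: float(val) for name, val in zip(OCT_FEATURE_NAMES, means)},
        n_images=len(vectors),
    )
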