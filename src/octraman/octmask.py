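"""Tissue-inclusion masks for OCT B-scans.

An OCT B-scan shows tissue below a dark background region (row 0 is the
top, i.e. the air side).  Three artifacts have to be dealt with before
texture statistics can be collected:

* background pixels must be excluded (intensity threshold),
* low-reflectance voids *inside* the tissue (e.g. adipocyte lumina in
  lipomas) must be treated as part of the tissue structure, and
* saturation lines — full-height bright columns caused by strong back
  reflection — must be excluded entirely.

The mask pipeline is: threshold -> fill interior voids -> remove
saturated columns.  Saturated columns are detected from the top
``n_top_rows`` rows of the thresholded mask (which image only
background): with B the (n_top_rows x n) top block of the mask, the row
vector S = J . B (J a row of ones) is positive exactly in columns where
a saturation line reaches the background region, and those columns are
zeroed over the full mask height.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "OCTImage",
    "MaskImage",
    "MaskConfig",
    "threshold_mask",
    "fill_voids",
    "remove_saturation_columns",
    "build_mask",
    "mask_qc",
]

#: nominal (lateral, axial) pixel pitch in microns; a 15 px window then
#: corresponds to roughly 53 x 53 um^2 of tissue.
DEFAULT_PIXEL_SIZE_UM = (3.5, 3.5)

#: intensity range of the stored 8-bit images
INTENSITY_MIN = 0
INTENSITY_MAX = 255


@dataclass
class OCTImage:
    """A single grayscale OCT B-scan.

    ``pixels`` is a 2-D array, row 0 at the top (background side).
    Stored images are 8-bit; float arrays are accepted for intermediate
    computations.
    """

    pixels: np.ndarray
    pixel_size_um: tuple[float, float] = DEFAULT_PIXEL_SIZE_UM
    sample_id: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("OCTImage.pixels must be a 2-D array")
        if self.pixels.shape[0] < 16:
            raise ValueError(
                "image height must be >= 16 rows (the top-15-row "
                f"saturation rule needs row 15 to exist); got {self.pixels.shape[0]}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MaskImage:
    """Binary tissue-inclusion mask aligned to an :class:`OCTImage`."""

    mask: np.ndarray
    thresholded: bool = False
    voids_filled: bool = False
    saturation_removed: bool = False
    removed_columns: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("MaskImage.mask must be a 2-D array")

    @property
    def fully_processed(self) -> bool:
        return self.thresholded and self.voids_filled and self.saturation_removed


@dataclass(frozen=True)
class MaskConfig:
    """Configuration of the mask pipeline.

    method: "otsu" (default, data-driven) or "fixed".
    level: required fixed threshold when method == "fixed".
    n_top_rows: number of top background rows scanned for saturation
        lines (default 15).
    """

    method: str = "otsu"
    level: float | None = None
    n_top_rows: int = 15


def threshold_mask(image: OCTImage, method: str = "otsu", level: float | None = None) -> MaskImage:
    """Binary mask: 1 where pixel intensity >= the effective level.

    ``method`` is ``"otsu"`` (threshold from the image histogram) or
    ``"fixed"`` (explicit ``level``, which must lie within the 8-bit
    intensity range).
    """
    pix = image.pixels
    if method == "otsu":
        if pix.min() == pix.max():
            # degenerate constant image: everything below/at a level above it
            eff = float(pix.min()) + 1.0
        else:
            # skimage's Otsu uses the pixel > t convention; our mask rule is
            # pixel >= level, so the effective level is the smallest stored
            # intensity strictly above t
            t = float(threshold_otsu(pix))
            if np.issubdtype(pix.dtype, np.integer):
                eff = np.floor(t) + 1.0
            else:
                eff = np.nextafter(t, np.inf)
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires a level")
        if not (INTENSITY_MIN <= level <= INTENSITY_MAX):
            raise ValueError(
                f"fixed threshold level {level} outside the 8-bit range "
                f"[{INTENSITY_MIN}, {INTENSITY_MAX}]"
            )
        eff = float(level)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return MaskImage(mask=pix.astype(np.float64) >= eff, thresholded=True)


# 4-connected structuring element: background filling must not leak
# diagonally through one-pixel tissue walls.
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def fill_voids(mask: MaskImage) -> MaskImage:
    """Fill interior voids so they count as part of the tissue structure.

    Every zero region that is *not* 4-connected to the border background
    becomes tissue; border-connected background is untouched.  Never
    removes mask pixels, and is idempotent.
    """
    if not mask.thresholded:
        raise ValueError("fill_voids requires a thresholded mask")
    filled = ndimage.binary_fill_holes(mask.mask, structure=_STRUCT_4)
    return replace(mask, mask=filled, voids_filled=True)


def remove_saturation_columns(mask: MaskImage, n_top_rows: int = 15) -> MaskImage:
    """Zero out every column whose top ``n_top_rows`` mask rows contain a hit.

    The top rows image only background, so any mask pixel there betrays
    a saturation line; the whole column is excluded from analysis.
    Never adds mask pixels.
    """
    if not mask.voids_filled:
        raise ValueError("remove_saturation_columns requires a voids-filled mask")
    h = mask.mask.shape[0]
    if n_top_rows >= h:
        raise ValueError(
            f"n_top_rows={n_top_rows} must be smaller than the image height {h}"
        )
    top = mask.mask[:n_top_rows, :]
    col_sums = top.sum(axis=0)  # S = J . B
    cols = np.flatnonzero(col_sums > 0)
    out = mask.mask.copy()
    out[:, cols] = False
    return replace(
        mask,
        mask=out,
        saturation_removed=True,
        removed_columns=tuple(int(c) for c in cols),
    )


def build_mask(image: OCTImage, config: MaskConfig = MaskConfig()) -> MaskImage:
    """Full mask pipeline: threshold -> fill voids -> remove saturation columns.

    The order is normative: voids are filled before line removal so that
    a removed column cannot re-open a void to the background.
    """
    m = threshold_mask(image, method=config.method, level=config.level)
    m = fill_voids(m)
    m = remove_saturation_columns(m, n_top_rows=config.n_top_rows)
    return m


def mask_qc(mask: MaskImage) -> dict:
    """Automated QC summary replacing manual mask inspection."""
    return {
        "masked_fraction": float(mask.mask.mean()),
        "n_removed_columns": len(mask.removed_columns),
    }
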