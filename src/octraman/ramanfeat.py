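"""Raman spectral preprocessing and band parameters p1-p8.

Spectra cover the 920-2070 cm^-1 range.  The broad autofluorescence
background is removed by iterative modified polynomial fitting
(default order 7): the polynomial is fit to the spectrum, intensities
above the fit are clamped to it, and the fit is repeated until it
stops moving.  Baseline-subtracted spectra are normalized to the
maximum intensity within the 1425-1460 cm^-1 anchor window, which
automatically picks the ~1437 cm^-1 CH2 lipid band for lipid-dominated
tissue (lipoma, skin is borderline) and the ~1446-1448 cm^-1 protein
CH2/CH3 band for protein-dominated tissue, so normalization needs no
class label.

Seven parameters p1-p7 are mean normalized intensities over fixed
wavenumber bands; p8 is the mean *unnormalized* (baseline-subtracted)
intensity over the full range, retaining overall signal strength.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "Band",
    "DEFAULT_BANDS",
    "RamanFeatureVector",
    "UnnormalizableSpectrumError",
    "canonical_grid",
    "resample_to_grid",
    "subtract_baseline",
    "normalize_spectrum",
    "band_parameters",
    "aggregate_sample_spectra",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

WAVENUMBER_LO = 920.0
WAVENUMBER_HI = 2070.0
GRID_STEP = 1.0

ANCHOR_LO = 1425.0
ANCHOR_HI = 1460.0

RAMAN_FEATURE_NAMES = ("p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8")


class UnnormalizableSpectrumError(ValueError):
    """Raised when the anchor window holds no positive intensity."""


@dataclass(frozen=True)
class Band:
    label: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.label}: lo must be < hi")


#: the seven averaging bands, in cm^-1 (endpoints inclusive)
DEFAULT_BANDS = (
    Band("p1", 925.0, 970.0),
    Band("p2", 1060.0, 1160.0),
    Band("p3", 1180.0, 1280.0),
    Band("p4", 1310.0, 1380.0),
    Band("p5", 1451.0, 1509.0),
    Band("p6", 1845.0, 1880.0),
    Band("p7", 2050.0, 2080.0),
)


@dataclass
class RamanSpectrum:
    """Wavenumber/intensity arrays with a processing-state flag.

    ``state`` is one of "raw", "baseline_subtracted", "normalized".
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    state: str = "raw"
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.wavenumbers.shape != self.intensities.shape or self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers and intensities must be equal-length 1-D arrays")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")


@dataclass
class RamanFeatureVector:
    """Band parameters p1..p7 plus the absolute-intensity parameter p8."""

    features: dict[str, float]
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if tuple(self.features) != RAMAN_FEATURE_NAMES:
            raise ValueError("features must carry exactly p1..p8")


def canonical_grid() -> np.ndarray:
    """The canonical internal wavenumber grid: 920..2070 cm^-1, 1 cm^-1 step."""
    n = int(round((WAVENUMBER_HI - WAVENUMBER_LO) / GRID_STEP)) + 1
    return WAVENUMBER_LO + GRID_STEP * np.arange(n)


def resample_to_grid(s: RamanSpectrum, grid: np.ndarray | None = None) -> RamanSpectrum:
    """Linear interpolation onto the canonical 1 cm^-1 grid."""
    grid = canonical_grid() if grid is None else np.asarray(grid, dtype=np.float64)
    intens = np.interp(grid, s.wavenumbers, s.intensities)
    return replace(s, wavenumbers=grid, intensities=intens)


def _cheb_projector(x01: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Chebyshev design matrix on [0,1]-scaled wavenumbers and its pseudo-inverse.

    The basis is fixed across the iterative refits, so the least-squares
    solve reduces to two matrix-vector products per iteration.
    """
    V = np.polynomial.chebyshev.chebvander(2.0 * x01 - 1.0, order)
    return V, np.linalg.pinv(V)


def _polyfit_eval(x01: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    V, pinv = _cheb_projector(x01, order)
    return V @ (pinv @ y)


def subtract_baseline(
    s: RamanSpectrum,
    order: int = 7,
    max_iter: int = 100,
    tol: float | None = None,
) -> RamanSpectrum:
    """Remove the autofluorescence background by iterative modified polyfit.

    Fit a polynomial of the given order (7, 8 or 9), clamp intensities
    that exceed the fit by more than the residual standard deviation
    down to that envelope (the noise-aware I-ModPoly rule: plain
    clamping to the fit ratchets the baseline into the noise floor),
    refit, and stop when the fit's maximum absolute change drops below
    ``tol`` (default 1e-6 of the spectrum maximum) or after
    ``max_iter`` passes.  The result is the input minus the final
    baseline, clipped at zero.
    """
    if s.state != "raw":
        raise ValueError(f"subtract_baseline expects a raw spectrum, got state={s.state!r}")
    if order not in (7, 8, 9):
        raise ValueError(f"polynomial order must be 7, 8 or 9; got {order}")
    n = len(s.wavenumbers)
    if n < order + 2:
        raise ValueError(f"need at least {order + 2} points to fit order {order}")

    y = s.intensities.astype(np.float64)
    scale = float(np.max(np.abs(y))) if np.any(y) else 1.0
    if tol is None:
        tol = 1e-6 * scale
    lo, hi = s.wavenumbers[0], s.wavenumbers[-1]
    x01 = (s.wavenumbers - lo) / (hi - lo)

    V, pinv = _cheb_projector(x01, order)
    work = y.copy()
    fit = V @ (pinv @ work)
    for _ in range(max_iter):
        dev = float(np.std(work - fit))
        work = np.minimum(work, fit + dev)
        new_fit = V @ (pinv @ work)
        if np.max(np.abs(new_fit - fit)) < tol:
            fit = new_fit
            break
        fit = new_fit
    out = np.clip(y - fit, 0.0, None)
    return replace(s, intensities=out, state="baseline_subtracted")


def normalize_spectrum(
    s: RamanSpectrum,
    anchor_lo: float = ANCHOR_LO,
    anchor_hi: float = ANCHOR_HI,
) -> RamanSpectrum:
    """Divide by the maximum intensity within the anchor window.

    Idempotent: a spectrum that is already normalized is returned
    unchanged (its anchor maximum is 1).
    """
    if s.state not in ("baseline_subtracted", "normalized"):
        raise ValueError("normalize_spectrum expects a baseline-subtracted spectrum")
    sel = (s.wavenumbers >= anchor_lo) & (s.wavenumbers <= anchor_hi)
    if not np.any(sel):
        raise UnnormalizableSpectrumError("anchor window holds no grid points")
    peak = float(s.intensities[sel].max())
    if peak <= 0:
        raise UnnormalizableSpectrumError(
            f"anchor-window maximum is {peak}; spectrum cannot be normalized"
        )
    return replace(s, intensities=s.intensities / peak, state="normalized")


def band_parameters(
    norm: RamanSpectrum,
    raw_bs: RamanSpectrum,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
) -> RamanFeatureVector:
    """p1..p7: band means of the normalized spectrum; p8: mean of the
    baseline-subtracted (unnormalized) spectrum over the full grid.

    Band endpoints are inclusive on both sides.
    """
    if norm.state != "normalized":
        raise ValueError("band_parameters expects a normalized spectrum")
    if raw_bs.state != "baseline_subtracted":
        raise ValueError("band_parameters expects a baseline-subtracted companion")
    if not np.array_equal(norm.wavenumbers, raw_bs.wavenumbers):
        raise ValueError("normalized and baseline-subtracted spectra must share one grid")

    feats: dict[str, float] = {}
    for band in bands:
        sel = (norm.wavenumbers >= band.lo) & (norm.wavenumbers <= band.hi)
        if not np.any(sel):
            raise ValueError(f"band {band.label} [{band.lo}, {band.hi}] contains no grid points")
        feats[band.label] = float(norm.intensities[sel].mean())
    feats["p8"] = float(raw_bs.intensities.mean())
    ordered = {name: feats[name] for name in RAMAN_FEATURE_NAMES}
    return RamanFeatureVector(features=ordered, sample_id=norm.sample_id)


def aggregate_sample_spectra(vectors: list[RamanFeatureVector]) -> RamanFeatureVector:
    """Feature-wise arithmetic mean over one sample's spectra."""
    if not vectors:
        raise ValueError("aggregate_sample_spectra requires at least one vector")
    ids = {v.sample_id for v in vectors}
    if len(ids) != 1:
        raise ValueError(f"mixed sample ids: {sorted(map(str, ids))}")
    stacked = np.array(
        [[v.features[name] for name in RAMAN_FEATURE_NAMES] for v in vectors]
    )
    means = stacked.mean(axis=0)
    return RamanFeatureVector(
        features={n: float(v) for n, v in zip(RAMAN_FEATURE_NAMES, means)},
        sample_id=vectors[0].sample_id,
    )


def read_spectrum_csv(path: str | Path, sample_id: str | None = None) -> RamanSpectrum:
    df = pd.read_csv(path)
    return RamanSpectrum(
        wavenumbers=df["wavenumber_cm1"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        state="raw",
        sample_id=sample_id,
    )


def write_spectrum_csv(s: RamanSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": s.wavenumbers, "intensity": s.intensities}
    ).to_csv(path, index=False)
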