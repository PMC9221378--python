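"""Synthetic OCT B-scans, Raman spectra and dataset manifests.

The generator emulates the statistical structure of ex vivo
skin/subcutaneous tumor measurements in the four classes skin, lipoma,
MCT (mast cell tumor) and STS (soft tissue sarcoma):

* lipoma: low-reflectance tissue riddled with dark circular voids — the
  honeycomb appearance of adipose tissue;
* MCT / STS: signal-dense, highly scattering, fairly homogeneous
  texture (hard to tell apart, as in real data);
* skin: layered appearance with a bright surface line (stratum
  corneum) over a moderately reflective dermis;
* all classes: dark background rows at the top of the B-scan, and an
  optional saturation artifact — a full-height bright column, 1-3 px
  wide with random vertical gaps, which the mask pipeline must remove.

Raman spectra are sums of class-specific Gaussian bands on a smooth
polynomial fluorescence background with additive Gaussian noise.  MCT
and STS share identical band parameters (their fingerprint spectra are
statistically indistinguishable) and differ only in overall signal
gain; lipoma is lipid-dominated (1076/1300/1437/1656 cm^-1); skin is
protein/collagen-dominated.

Biological variability is modelled as per-sample random effects on
tissue brightness, band heights and gain; per-spectrum gain jitter adds
within-sample variation.  Everything is a pure function of the
configuration, including its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .octmask import DEFAULT_PIXEL_SIZE_UM, MaskImage, OCTImage
from .ramanfeat import RamanSpectrum, canonical_grid, write_spectrum_csv

__all__ = [
    "CLASSES",
    "ClassTextureParams",
    "ClassSpectrumParams",
    "SynthConfig",
    "SampleRecord",
    "SyntheticDataset",
    "generate_oct_image",
    "generate_oct_image_with_truth",
    "generate_raman_spectrum",
    "simulate_dataset",
    "write_dataset",
    "generate_dataset",
    "scale_separation",
]

CLASSES = ("skin", "lipoma", "MCT", "STS")

MALIGNANT = ("MCT", "STS")


@dataclass(frozen=True)
class ClassTextureParams:
    """OCT texture parameters of one tissue class (8-bit intensity units)."""

    background_level: float
    tissue_mean: float
    tissue_std: float
    void_density: float  # expected voids per 10_000 tissue pixels
    void_radius_px: int
    surface_line: bool
    saturation_line_prob: float


@dataclass(frozen=True)
class ClassSpectrumParams:
    """Raman band parameters of one tissue class.

    ``baseline_poly_coeffs`` are polynomial coefficients (ascending) in
    the scaled coordinate x = (nu - 920)/(2070 - 920) in [0, 1]; the
    baseline models autofluorescence and is *not* multiplied by the
    Raman gain.
    """

    peak_centers: tuple[float, ...]
    peak_heights: tuple[float, ...]
    peak_widths: tuple[float, ...]  # Gaussian sigmas, cm^-1
    baseline_poly_coeffs: tuple[float, ...]
    noise_sd: float
    overall_gain: float


def _default_texture_params() -> dict[str, ClassTextureParams]:
    return {
        "skin": ClassTextureParams(
            background_level=5.0, tissue_mean=110.0, tissue_std=20.0,
            void_density=0.0, void_radius_px=0,
            surface_line=True, saturation_line_prob=0.15,
        ),
        "lipoma": ClassTextureParams(
            background_level=5.0, tissue_mean=75.0, tissue_std=20.0,
            void_density=70.0, void_radius_px=4,
            surface_line=False, saturation_line_prob=0.15,
        ),
        "MCT": ClassTextureParams(
            background_level=5.0, tissue_mean=160.0, tissue_std=16.0,
            void_density=0.0, void_radius_px=0,
            surface_line=False, saturation_line_prob=0.15,
        ),
        "STS": ClassTextureParams(
            background_level=5.0, tissue_mean=152.0, tissue_std=19.0,
            void_density=0.0, void_radius_px=0,
            surface_line=False, saturation_line_prob=0.15,
        ),
    }


# relative band heights of the protein/collagen fingerprint shared by
# skin and the malignant classes; heights in counts after x250 scaling
_SKIN_PEAKS = {
    935.0: 0.35, 1000.0: 0.40, 1031.0: 0.35, 1127.0: 0.30,
    1241.0: 0.20, 1343.0: 0.45, 1437.0: 0.25, 1448.0: 1.00,
    1480.0: 0.08, 1544.0: 0.30, 1586.0: 0.25, 1656.0: 0.80,
    1885.0: 0.50, 2067.0: 0.50,
}
# malignant tissue: elevated nucleic-acid band (1241), elevated
# 1480 cm^-1 band, reduced lipid 1437 shoulder
_MALIGNANT_PEAKS = {**_SKIN_PEAKS, 1241.0: 0.50, 1437.0: 0.05, 1480.0: 0.45}
_LIPOMA_PEAKS = {1076.0: 1.00, 1300.0: 0.75, 1437.0: 1.00, 1656.0: 0.60}


def _mk_spectrum_params(peaks: dict[float, float], scale: float,
                        baseline: tuple[float, ...], gain: float) -> ClassSpectrumParams:
    centers = tuple(sorted(peaks))
    return ClassSpectrumParams(
        peak_centers=centers,
        peak_heights=tuple(peaks[c] * scale for c in centers),
        peak_widths=tuple(6.0 for _ in centers),
        baseline_poly_coeffs=baseline,
        noise_sd=3.0,
        overall_gain=gain,
    )


def _default_spectrum_params() -> dict[str, ClassSpectrumParams]:
    return {
        "skin": _mk_spectrum_params(_SKIN_PEAKS, 250.0, (300.0, -230.0, 80.0), 1.2),
        "lipoma": _mk_spectrum_params(_LIPOMA_PEAKS, 300.0, (230.0, -170.0, 60.0), 1.8),
        # MCT and STS share one spectral model: their fingerprint spectra are
        # statistically indistinguishable, which is what the significance
        # analysis is expected to report
        "MCT": _mk_spectrum_params(_MALIGNANT_PEAKS, 250.0, (330.0, -270.0, 100.0), 0.85),
        "STS": _mk_spectrum_params(_MALIGNANT_PEAKS, 250.0, (330.0, -270.0, 100.0), 0.85),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic study, including its seed."""

    n_samples_per_class: int = 10
    images_per_sample: int = 4      # real studies acquire up to 14
    spectra_per_sample: int = 8     # real studies acquire 8 to 12
    image_height: int = 128
    image_width: int = 192
    seed: int = 0
    class_texture_params: dict[str, ClassTextureParams] = field(
        default_factory=_default_texture_params
    )
    class_spectrum_params: dict[str, ClassSpectrumParams] = field(
        default_factory=_default_spectrum_params
    )
    # between-sample biological variability (random effects)
    sample_mean_sd: float = 8.0        # 8-bit counts, on tissue_mean
    sample_gain_rel_sd: float = 0.12   # relative, on overall_gain
    spectrum_gain_rel_sd: float = 0.08  # relative, per spectrum
    sample_peak_rel_sd: float = 0.10   # relative, on each band height
    # biochemical heterogeneity: weak sample-specific Raman bands at random
    # positions, scaled with the class gain like any Raman signal
    nuisance_peaks_per_sample: int = 8
    nuisance_height_mean: float = 10.0   # counts; ~3% of a major band
    nuisance_width_range: tuple[float, float] = (15.0, 40.0)

    def __post_init__(self) -> None:
        for name in ("n_samples_per_class", "images_per_sample", "spectra_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(self.image_height, self.image_width) < 31:
            raise ValueError("image dimensions must be >= 31 px so a 15x15 "
                             "window fits with margin")
        grid = canonical_grid()
        for label, sp in self.class_spectrum_params.items():
            for c in sp.peak_centers:
                if not (grid[0] <= c <= grid[-1]):
                    raise ValueError(
                        f"peak center {c} cm^-1 for class {label!r} lies outside "
                        f"the generated range [{grid[0]}, {grid[-1]}]"
                    )

    def to_json(self, path: str | Path) -> None:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj).__name__)
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=enc))

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthConfig":
        raw = json.loads(Path(path).read_text())
        raw["class_texture_params"] = {
            k: ClassTextureParams(**v) for k, v in raw["class_texture_params"].items()
        }
        raw["class_spectrum_params"] = {
            k: ClassSpectrumParams(**{kk: tuple(vv) if isinstance(vv, list) else vv
                                      for kk, vv in v.items()})
            for k, v in raw["class_spectrum_params"].items()
        }
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)


def _check_class(class_label: str) -> None:
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASSES}")


def generate_oct_image_with_truth(
    class_label: str, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[OCTImage, MaskImage]:
    """Generate one B-scan plus its ground-truth tissue mask.

    The truth mask marks the tissue block (all rows from the tissue
    surface down, voids included — they are part of the tissue
    structure) minus any saturated column.
    """
    _check_class(class_label)
    p = cfg.class_texture_params[class_label]
    h, w = cfg.image_height, cfg.image_width

    img = rng.normal(p.background_level, 2.0, size=(h, w))
    # tissue surface below row 15 so the top rows image only background
    top = int(rng.integers(16, 29))
    img[top:, :] = rng.normal(p.tissue_mean, p.tissue_std, size=(h - top, w))

    if p.surface_line:
        img[top:top + 3, :] = rng.normal(230.0, 10.0, size=(3, w))

    if p.void_density > 0 and p.void_radius_px > 0:
        r = p.void_radius_px
        n_tissue = (h - top) * w
        n_voids = rng.poisson(p.void_density * n_tissue / 1e4)
        yy, xx = np.ogrid[:h, :w]
        for _ in range(n_voids):
            cy = int(rng.integers(top + r + 3, h - r - 1))
            cx = int(rng.integers(r + 1, w - r - 1))
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            img[disk] = rng.normal(p.background_level, 2.0, size=int(disk.sum()))

    truth = np.zeros((h, w), dtype=bool)
    truth[top:, :] = True

    if rng.random() < p.saturation_line_prob:
        width = int(rng.integers(1, 4))
        c0 = int(rng.integers(0, w - width + 1))
        cols = slice(c0, c0 + width)
        bright = rng.random(size=(h, width)) < 0.7  # periodic gaps
        bright[int(rng.integers(0, 15)), :] = True  # line reaches the top rows
        block = img[:, cols]
        block[bright] = 255.0
        img[:, cols] = block
        truth[:, cols] = False

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = OCTImage(pixels=pixels, pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
                     class_label=class_label)
    truth_mask = MaskImage(mask=truth, thresholded=True, voids_filled=True,
                           saturation_removed=True)
    return image, truth_mask


def generate_oct_image(class_label: str, cfg: SynthConfig,
                       rng: np.random.Generator) -> OCTImage:
    image, _ = generate_oct_image_with_truth(class_label, cfg, rng)
    return image


def gaussian_peak_sum(grid: np.ndarray, centers, heights, widths) -> np.ndarray:
    """Sum of Gaussian bands on a wavenumber grid (noise- and baseline-free)."""
    out = np.zeros_like(grid, dtype=np.float64)
    for c, a, s in zip(centers, heights, widths):
        out += a * np.exp(-((grid - c) ** 2) / (2.0 * s * s))
    return out


def generate_raman_spectrum(class_label: str, cfg: SynthConfig,
                            rng: np.random.Generator) -> RamanSpectrum:
    """One raw spectrum: gain x Gaussian bands + fluorescence baseline + noise."""
    _check_class(class_label)
    p = cfg.class_spectrum_params[class_label]
    if len(p.peak_centers) == 0:
        raise ValueError(f"class {class_label!r} defines no Raman peaks")
    grid = canonical_grid()
    x01 = (grid - grid[0]) / (grid[-1] - grid[0])
    baseline = np.polynomial.polynomial.polyval(x01, np.asarray(p.baseline_poly_coeffs)) \
        if p.baseline_poly_coeffs else np.zeros_like(grid)
    gain = p.overall_gain * max(1.0 + rng.normal(0.0, cfg.spectrum_gain_rel_sd), 0.05)
    signal = gain * gaussian_peak_sum(grid, p.peak_centers, p.peak_heights, p.peak_widths)
    noise = rng.normal(0.0, p.noise_sd, size=grid.shape) if p.noise_sd > 0 else 0.0
    intens = np.clip(signal + baseline + noise, 0.0, None)
    return RamanSpectrum(wavenumbers=grid, intensities=intens, state="raw")


@dataclass
class SampleRecord:
    sample_id: str
    class_label: str
    images: list[OCTImage]
    truth_masks: list[MaskImage]
    spectra: list[RamanSpectrum]


@dataclass
class SyntheticDataset:
    cfg: SynthConfig
    samples: list[SampleRecord]


def _perturbed_sample_cfg(class_label: str, cfg: SynthConfig,
                          rng: np.random.Generator) -> SynthConfig:
    """Per-sample random effects: jitter texture mean, band heights, gain."""
    tex = cfg.class_texture_params[class_label]
    sp = cfg.class_spectrum_params[class_label]
    tex2 = replace(tex, tissue_mean=float(
        np.clip(tex.tissue_mean + rng.normal(0.0, cfg.sample_mean_sd), 20.0, 240.0)))
    hfac = np.maximum(1.0 + rng.normal(0.0, cfg.sample_peak_rel_sd,
                                       size=len(sp.peak_heights)), 0.05)
    gfac = max(1.0 + rng.normal(0.0, cfg.sample_gain_rel_sd), 0.05)
    # sample-specific minor bands: biochemical heterogeneity between samples
    k = cfg.nuisance_peaks_per_sample
    nu_c = tuple(float(c) for c in rng.uniform(940.0, 2050.0, size=k))
    nu_h = tuple(float(h) for h in rng.exponential(cfg.nuisance_height_mean, size=k))
    nu_w = tuple(float(w) for w in rng.uniform(*cfg.nuisance_width_range, size=k))
    sp2 = replace(sp,
                  peak_centers=sp.peak_centers + nu_c,
                  peak_heights=tuple(float(h * f) for h, f in zip(sp.peak_heights, hfac)) + nu_h,
                  peak_widths=sp.peak_widths + nu_w,
                  overall_gain=float(sp.overall_gain * gfac))
    return replace(cfg,
                   class_texture_params={**cfg.class_texture_params, class_label: tex2},
                   class_spectrum_params={**cfg.class_spectrum_params, class_label: sp2})


def simulate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Generate the full in-memory dataset; pure function of cfg (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    samples: list[SampleRecord] = []
    for label in CLASSES:
        for i in range(cfg.n_samples_per_class):
            sid = f"{label}_{i:02d}"
            scfg = _perturbed_sample_cfg(label, cfg, rng)
            images, truths = [], []
            for _ in range(cfg.images_per_sample):
                img, truth = generate_oct_image_with_truth(label, scfg, rng)
                img.sample_id = sid
                images.append(img)
                truths.append(truth)
            spectra = []
            for _ in range(cfg.spectra_per_sample):
                s = generate_raman_spectrum(label, scfg, rng)
                s.sample_id = sid
                spectra.append(s)
            samples.append(SampleRecord(sid, label, images, truths, spectra))
    return SyntheticDataset(cfg=cfg, samples=samples)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write TIFF images, spectrum CSVs and manifest.csv; returns manifest path."""
    outdir = Path(outdir)
    try:
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    rows = []
    for rec in ds.samples:
        for k, img in enumerate(rec.images):
            rel = f"images/{rec.sample_id}_img{k:02d}.tiff"
            tifffile.imwrite(outdir / rel, img.pixels)
            rows.append((rec.sample_id, rec.class_label, "OCT", rel))
        for k, s in enumerate(rec.spectra):
            rel = f"spectra/{rec.sample_id}_spec{k:02d}.csv"
            write_spectrum_csv(s, outdir / rel)
            rows.append((rec.sample_id, rec.class_label, "Raman", rel))
    manifest = pd.DataFrame(rows, columns=["sample_id", "class", "modality", "path"])
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    ds.cfg.to_json(outdir / "synth_config.json")
    return manifest_path


def generate_dataset(cfg: SynthConfig, outdir: str | Path) -> Path:
    """Simulate and write a dataset; returns the manifest path."""
    return write_dataset(simulate_dataset(cfg), outdir)


def _blend(value: float, center: float, factor: float) -> float:
    return center + factor * (value - center)


def scale_separation(cfg: SynthConfig, factor: float) -> SynthConfig:
    """Shrink (factor < 1) or stretch (factor > 1) between-class contrast.

    Scalar class parameters (tissue mean/std, void density, gain) and
    per-band heights are interpolated toward their cross-class means;
    factor 1 returns an equivalent config.  Used to verify that larger
    class separation yields higher downstream classification accuracy.
    """
    tex = cfg.class_texture_params
    sp = cfg.class_spectrum_params

    mean_c = float(np.mean([t.tissue_mean for t in tex.values()]))
    std_c = float(np.mean([t.tissue_std for t in tex.values()]))
    dens_c = float(np.mean([t.void_density for t in tex.values()]))
    gain_c = float(np.mean([s.overall_gain for s in sp.values()]))

    all_centers = sorted({c for s in sp.values() for c in s.peak_centers})
    height_at = {
        lbl: {c: 0.0 for c in all_centers} for lbl in sp
    }
    width_at: dict[float, float] = {}
    for lbl, s in sp.items():
        for c, hgt, wd in zip(s.peak_centers, s.peak_heights, s.peak_widths):
            height_at[lbl][c] = hgt
            width_at[c] = wd
    center_h = {c: float(np.mean([height_at[lbl][c] for lbl in sp])) for c in all_centers}

    new_tex, new_sp = {}, {}
    for lbl in tex:
        t = tex[lbl]
        new_tex[lbl] = replace(
            t,
            tissue_mean=_blend(t.tissue_mean, mean_c, factor),
            tissue_std=max(_blend(t.tissue_std, std_c, factor), 1.0),
            void_density=max(_blend(t.void_density, dens_c, factor), 0.0),
        )
        s = sp[lbl]
        heights = {c: max(_blend(height_at[lbl][c], center_h[c], factor), 0.0)
                   for c in all_centers}
        keep = [c for c in all_centers if heights[c] > 1e-9]
        new_sp[lbl] = replace(
            s,
            peak_centers=tuple(keep),
            peak_heights=tuple(heights[c] for c in keep),
            peak_widths=tuple(width_at[c] for c in keep),
            overall_gain=max(_blend(s.overall_gain, gain_c, factor), 0.05),
        )
    return replace(cfg, class_texture_params=new_tex, class_spectrum_params=new_sp)
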