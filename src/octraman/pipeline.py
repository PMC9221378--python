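"""End-to-end orchestration: manifest -> features -> LOOCV -> report bundle.

Per sample, OCT images run through the mask pipeline and scanning-window
featurization and the 12 features are averaged over images; Raman
spectra run through baseline subtraction, normalization and band
averaging and p1-p8 are averaged over spectra.  Three per-sample
feature matrices are assembled (OCT, Raman, combined) and each is
scored by leave-one-out cross-validation, per-class and
merged-malignant sensitivity/specificity, and Mann-Whitney feature
significance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import classify, octfeat, octmask, ramanfeat
from .classify import FeatureMatrix, MERGED_LABEL
from .octmask import MaskConfig, OCTImage
from .ramanfeat import DEFAULT_BANDS, Band
from .synth import SyntheticDataset

__all__ = ["PipelineConfig", "DatasetResult", "extract_features", "run_datasets",
           "run_pipeline", "load_manifest_dataset"]

MODALITIES = ("OCT", "Raman")


@dataclass(frozen=True)
class PipelineConfig:
    modalities: tuple[str, ...] = MODALITIES
    mask: MaskConfig = MaskConfig()
    window: int = 15
    stride: int = 1
    poly_order: int = 7
    anchor_lo: float = ramanfeat.ANCHOR_LO
    anchor_hi: float = ramanfeat.ANCHOR_HI
    bands: tuple[Band, ...] = DEFAULT_BANDS
    max_dropped_fraction: float = 0.2

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


@dataclass
class LoadedSample:
    sample_id: str
    class_label: str
    images: list[OCTImage] = field(default_factory=list)
    spectra: list[ramanfeat.RamanSpectrum] = field(default_factory=list)
    load_errors: list[str] = field(default_factory=list)


def load_manifest_dataset(manifest_path: str | Path) -> list[LoadedSample]:
    """Read a manifest.csv and load the files it references.

    Unreadable files are recorded as load errors on their sample rather
    than aborting the whole run; the affected sample is dropped later.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    samples: dict[str, LoadedSample] = {}
    for row in manifest.to_dict("records"):
        sid = row["sample_id"]
        rec = samples.setdefault(sid, LoadedSample(sid, row["class"]))
        path = root / row["path"]
        try:
            if row["modality"] == "OCT":
                rec.images.append(
                    OCTImage(pixels=tifffile.imread(path), sample_id=sid,
                             class_label=rec.class_label)
                )
            elif row["modality"] == "Raman":
                rec.spectra.append(ramanfeat.read_spectrum_csv(path, sample_id=sid))
            else:
                raise ValueError(f"unknown modality {row['modality']!r} in manifest")
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            rec.load_errors.append(f"{row['path']}: {exc}")
    return list(samples.values())


def oct_sample_features(images: list[OCTImage], cfg: PipelineConfig) -> dict[str, float]:
    vectors = []
    for img in images:
        mask = octmask.build_mask(img, cfg.mask)
        dists = octfeat.scan_image(img, mask, window=cfg.window, stride=cfg.stride)
        vec = octfeat.summarize_distributions(dists)
        vec.sample_id = img.sample_id
        vectors.append(vec)
    return octfeat.aggregate_sample(vectors).features


def raman_sample_features(spectra: list[ramanfeat.RamanSpectrum],
                          cfg: PipelineConfig) -> dict[str, float]:
    vectors = []
    for s in spectra:
        s = ramanfeat.resample_to_grid(s)
        bs = ramanfeat.subtract_baseline(s, order=cfg.poly_order)
        norm = ramanfeat.normalize_spectrum(bs, cfg.anchor_lo, cfg.anchor_hi)
        vectors.append(ramanfeat.band_parameters(norm, bs, cfg.bands))
    return ramanfeat.aggregate_sample_spectra(vectors).features


def _dataset_to_loaded(ds: SyntheticDataset) -> list[LoadedSample]:
    return [
        LoadedSample(rec.sample_id, rec.class_label, rec.images, rec.spectra)
        for rec in ds.samples
    ]


def extract_features(
    samples: list[LoadedSample] | SyntheticDataset,
    cfg: PipelineConfig = PipelineConfig(),
) -> dict[str, FeatureMatrix]:
    """Per-sample feature matrices for the requested modalities.

    Returns a dict keyed by dataset tag ("OCT", "Raman", "combined");
    "combined" is present when both modalities are.  Samples whose
    files fail to process are dropped with a warning; the run aborts if
    more than ``max_dropped_fraction`` of samples drop.
    """
    if isinstance(samples, SyntheticDataset):
        samples = _dataset_to_loaded(samples)

    oct_rows, raman_rows, labels = {}, {}, {}
    dropped = []
    for rec in samples:
        try:
            if getattr(rec, "load_errors", None):
                raise RuntimeError("; ".join(rec.load_errors))
            if "OCT" in cfg.modalities:
                oct_rows[rec.sample_id] = oct_sample_features(rec.images, cfg)
            if "Raman" in cfg.modalities:
                raman_rows[rec.sample_id] = raman_sample_features(rec.spectra, cfg)
            labels[rec.sample_id] = rec.class_label
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            oct_rows.pop(rec.sample_id, None)
            raman_rows.pop(rec.sample_id, None)
            labels.pop(rec.sample_id, None)
            dropped.append(rec.sample_id)
            warnings.warn(f"sample {rec.sample_id} dropped: {exc}", stacklevel=2)
    if len(dropped) > cfg.max_dropped_fraction * len(samples):
        raise RuntimeError(
            f"{len(dropped)}/{len(samples)} samples failed to process: {dropped}"
        )

    label_series = pd.Series(labels, name="class")
    out: dict[str, FeatureMatrix] = {}
    if "OCT" in cfg.modalities:
        oct_df = pd.DataFrame.from_dict(oct_rows, orient="index")[list(octfeat.OCT_FEATURE_NAMES)]
        out["OCT"] = FeatureMatrix(X=oct_df, labels=label_series, dataset_tag="OCT")
    if "Raman" in cfg.modalities:
        raman_df = pd.DataFrame.from_dict(raman_rows, orient="index")[
            list(ramanfeat.RAMAN_FEATURE_NAMES)
        ]
        out["Raman"] = FeatureMatrix(X=raman_df, labels=label_series, dataset_tag="Raman")
    if "OCT" in cfg.modalities and "Raman" in cfg.modalities:
        combined = out["OCT"].X.join(out["Raman"].X)
        out["combined"] = FeatureMatrix(X=combined, labels=label_series,
                                        dataset_tag="combined")
    return out


@dataclass
class DatasetResult:
    tag: str
    features: FeatureMatrix
    predictions: pd.DataFrame          # 4-class LOOCV table with LD coords
    merged_predictions: pd.DataFrame   # MCT+STS pooled
    metrics: dict
    significance: pd.DataFrame


def _score(fm: FeatureMatrix) -> DatasetResult:
    pred = classify.loocv(fm)
    merged = classify.merge_malignant(pred)
    per_class = {
        c: dataclasses.asdict(classify.confusion_metrics(pred, c)) for c in fm.classes
    }
    metrics = {
        "n_samples": int(len(pred)),
        "accuracy": classify.accuracy(pred),
        "merged_accuracy": classify.accuracy(merged),
        "per_class": per_class,
        MERGED_LABEL: dataclasses.asdict(
            classify.confusion_metrics(merged, MERGED_LABEL)
        ),
    }
    return DatasetResult(
        tag=fm.dataset_tag,
        features=fm,
        predictions=pred,
        merged_predictions=merged,
        metrics=metrics,
        significance=classify.mann_whitney_matrix(fm),
    )


def run_datasets(matrices: dict[str, FeatureMatrix]) -> dict[str, DatasetResult]:
    """LOOCV + metrics + significance for every assembled feature matrix."""
    return {tag: _score(fm) for tag, fm in matrices.items()}


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig = PipelineConfig(),
) -> dict[str, DatasetResult]:
    """Full run from a manifest on disk, writing the report bundle.

    Outputs under ``out_dir``: features.csv, predictions.csv,
    metrics.json, significance.csv, ld_scatter.csv and run_log.json.
    Deterministic: rerunning with the same inputs and config reproduces
    metrics.json byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = load_manifest_dataset(manifest_path)
    matrices = extract_features(samples, cfg)
    results = run_datasets(matrices)

    features = None
    for tag in ("combined", "OCT", "Raman"):
        if tag in matrices:
            features = matrices[tag].X.copy()
            features.insert(0, "class", matrices[tag].labels)
            break
    features.rename_axis("sample_id").to_csv(out_dir / "features.csv")

    pred_frames, sig_frames, ld_frames = [], [], []
    metrics = {}
    for tag, res in results.items():
        p = res.predictions.copy()
        p.insert(0, "dataset", tag)
        pred_frames.append(p)
        sig_frames.append(res.significance)
        ld_cols = [c for c in res.predictions.columns if c.startswith("LD")][:2]
        ld = res.predictions[["sample_id", "true_label", "predicted_label", *ld_cols]].copy()
        ld.insert(0, "dataset", tag)
        ld_frames.append(ld)
        metrics[tag] = res.metrics
    pd.concat(pred_frames, ignore_index=True).to_csv(out_dir / "predictions.csv", index=False)
    pd.concat(sig_frames, ignore_index=True).to_csv(out_dir / "significance.csv", index=False)
    pd.concat(ld_frames, ignore_index=True).to_csv(out_dir / "ld_scatter.csv", index=False)
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    (out_dir / "run_log.json").write_text(
        json.dumps(
            {
                "config_hash": cfg.config_hash(),
                "n_samples": len(samples),
                "datasets": sorted(results),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return results
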