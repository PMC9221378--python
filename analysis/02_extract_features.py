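#!/usr/bin/env python
"""Extract per-sample features from a dataset manifest.

For each sample: OCT B-scans are masked (threshold, void fill,
saturation-line removal) and scanned with the 15x15 stride-1 window,
yielding 12 texture features averaged over the sample's images; Raman
spectra are baseline-corrected, normalized and reduced to the band
parameters p1-p8 averaged over the sample's spectra.

    python analysis/02_extract_features.py --manifest scratch/dataset/manifest.csv
"""

import argparse
from pathlib import Path

from octraman.pipeline import PipelineConfig, extract_features, load_manifest_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--manifest", type=Path, default=Path("scratch/dataset/manifest.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/features.csv"))
    args = ap.parse_args()

    samples = load_manifest_dataset(args.manifest)
    mats = extract_features(samples, PipelineConfig())
    features = mats["combined"].X.copy()
    features.insert(0, "class", mats["combined"].labels)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    features.rename_axis("sample_id").to_csv(args.out)
    print(f"wrote {args.out}: {features.shape[0]} samples x "
          f"{features.shape[1] - 1} features (12 OCT + 8 Raman)")
    print(features.groupby("class")[["m_mu", "m_cv", "p5", "p8"]].mean().round(3))


if __name__ == "__main__":
    main()
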