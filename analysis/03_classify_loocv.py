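#!/usr/bin/env python
"""Classify samples by LDA with leave-one-out cross-validation.

Builds the OCT-only, Raman-only and combined feature matrices from the
extracted feature table, cross-validates each, and reports per-class
and merged-malignant (MCT + STS pooled) sensitivity/specificity.

    python analysis/03_classify_loocv.py --features results/features.csv
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from octraman.classify import FeatureMatrix
from octraman.octfeat import OCT_FEATURE_NAMES
from octraman.pipeline import run_datasets
from octraman.ramanfeat import RAMAN_FEATURE_NAMES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = pd.read_csv(args.features, index_col="sample_id")
    labels = table["class"]
    mats = {
        "OCT": FeatureMatrix(table[list(OCT_FEATURE_NAMES)], labels, "OCT"),
        "Raman": FeatureMatrix(table[list(RAMAN_FEATURE_NAMES)], labels, "Raman"),
        "combined": FeatureMatrix(
            table[list(OCT_FEATURE_NAMES) + list(RAMAN_FEATURE_NAMES)], labels, "combined"
        ),
    }
    results = run_datasets(mats)

    args.outdir.mkdir(parents=True, exist_ok=True)
    metrics, preds, lds = {}, [], []
    for tag, res in results.items():
        metrics[tag] = res.metrics
        p = res.predictions.copy()
        p.insert(0, "dataset", tag)
        preds.append(p)
        ld_cols = [c for c in p.columns if c.startswith("LD")][:2]
        lds.append(p[["dataset", "sample_id", "true_label", "predicted_label", *ld_cols]])
    (args.outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    pd.concat(preds, ignore_index=True).to_csv(args.outdir / "predictions.csv", index=False)
    pd.concat(lds, ignore_index=True).to_csv(args.outdir / "ld_scatter.csv", index=False)

    rows = []
    for tag, res in results.items():
        m = res.metrics
        for cls, pc in m["per_class"].items():
            rows.append((tag, cls, pc["sensitivity"], pc["specificity"]))
        rows.append((tag, "malignant (MCT+STS)", m["malignant"]["sensitivity"],
                     m["malignant"]["specificity"]))
    summary = pd.DataFrame(rows, columns=["dataset", "class", "sensitivity", "specificity"])
    print(summary.to_string(index=False))
    print(f"\nwrote {args.outdir}/metrics.json, predictions.csv, ld_scatter.csv")


if __name__ == "__main__":
    main()
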