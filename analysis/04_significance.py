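#!/usr/bin/env python
"""Nonparametric feature significance between tissue classes.

Runs the two-sided Mann-Whitney U test for every feature and class
pair (stars: *** p<0.001, ** p<0.01, * p<0.05, NS otherwise) and
prints the star matrix for the Raman band parameters — the expected
pattern is NS between the two malignant classes on p1-p7 and strong
significance of both against lipoma.

    python analysis/04_significance.py --features results/features.csv
"""

import argparse
from pathlib import Path

import pandas as pd

from octraman.classify import FeatureMatrix, mann_whitney_matrix
from octraman.octfeat import OCT_FEATURE_NAMES
from octraman.ramanfeat import RAMAN_FEATURE_NAMES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/significance.csv"))
    args = ap.parse_args()

    table = pd.read_csv(args.features, index_col="sample_id")
    labels = table["class"]
    frames = []
    for tag, cols in (("OCT", OCT_FEATURE_NAMES), ("Raman", RAMAN_FEATURE_NAMES)):
        fm = FeatureMatrix(table[list(cols)], labels, tag)
        frames.append(mann_whitney_matrix(fm))
    sig = pd.concat(frames, ignore_index=True)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    sig.to_csv(args.out, index=False)

    raman = sig[sig.dataset == "Raman"]
    stars = raman.pivot_table(
        index=["class_a", "class_b"], columns="feature", values="stars", aggfunc="first"
    )[list(RAMAN_FEATURE_NAMES)]
    print("Raman band significance (rows: class pairs):")
    print(stars.to_string())
    print(f"\nwrote {args.out} ({len(sig)} feature x pair tests)")


if __name__ == "__main__":
    main()
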