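#!/usr/bin/env python
"""Run the four segmentation pipelines over a downloaded dataset directory.

UNTESTED helper: the public cell datasets (U2OS/NIH3T3 from
http://murphylab.web.cmu.edu/data/, HT29 from
https://data.broadinstitute.org/bbbc/BBBC008/) are not bundled; download
them, arrange matching ``images/`` and ``truth/`` file names, then:

    python reproduce/run_datasets.py --images DIR/images --truth DIR/truth \
        --out results/dataset_metrics.json

Interactive rows need per-image scribble PNGs (labels 0/1/2) in a third
directory; without one, only the automatic rows are produced.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from cellcut import (
    BinaryMask,
    confusion,
    read_gray_image,
    scribble_seeds,
    segment,
    segment_auto,
)
from cellcut.metrics import per_image_f1, pooled_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--images", type=Path, required=True)
    parser.add_argument("--truth", type=Path, required=True)
    parser.add_argument("--scribbles", type=Path, default=None)
    parser.add_argument("--lambda1", type=float, default=20.0)
    parser.add_argument("--cp", type=float, default=20.0)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    rows: dict[str, list] = {}
    for img_path in sorted(args.images.iterdir()):
        image = read_gray_image(img_path)
        truth = BinaryMask(
            (read_gray_image(args.truth / img_path.name).pixels > 127).astype(np.uint8)
        )
        variants = {
            "automatic-static": lambda: segment_auto(
                image, mode="static", lambda1=args.lambda1, c_p=args.cp),
            "automatic-adaptive": lambda: segment_auto(
                image, mode="adaptive", lambda1=args.lambda1, c_p=args.cp),
        }
        if args.scribbles is not None:
            seeds = scribble_seeds(
                read_gray_image(args.scribbles / img_path.name).pixels, image
            )
            variants["interactive-static"] = lambda s=seeds: segment(
                image, s, mode="static", lambda1=args.lambda1, c_p=args.cp)
            variants["interactive-adaptive"] = lambda s=seeds: segment(
                image, s, mode="adaptive", lambda1=args.lambda1, c_p=args.cp)
        for name, run in variants.items():
            rows.setdefault(name, []).append(confusion(run().mask, truth))

    summary = {}
    for name, counts in rows.items():
        pooled = pooled_report(counts)
        mean_f1, std_f1 = per_image_f1(counts)
        summary[name] = {
            "pooled_ai": pooled.ai,
            "pooled_f1": pooled.f1,
            "per_image_f1_mean": mean_f1,
            "per_image_f1_std": std_f1,
            "n_images": len(counts),
        }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
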