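# cellcut

Graph-cut binary cell segmentation with interactive (scribble) or automatic
(Otsu) seeding, and a **static or boundary-adaptive regularization parameter
λ**. The energy combines a seed-histogram data term `−log P(I|S)` (weighted
by λ, default 20) with a Gaussian intensity-similarity smoothness term over
the 4-neighborhood; it is minimized exactly by an Edmonds–Karp max-flow /
min-cut solver. In adaptive mode, cell-boundary pixels (morphological band
of the Otsu mask by default) have their object-terminal link boosted by a
factor `c_p` (default 20) and their background-terminal link zeroed, which
counteracts the shrink bias that otherwise shaves boundary pixels off
segmented cells.

The package also ships the full evaluation battery — pixel confusion counts,
accuracy index, precision/recall/F1, ROC/AUC over a λ sweep, a Welch t-test
on per-image F1 — plus a synthetic microscopy-like image generator (bright
round cells, optional intermediate-intensity boundary rings, per-cell
brightness heterogeneity, background speckle, salt-and-pepper noise) so
every pipeline is testable end-to-end without downloading datasets.

## CLI

```bash
# generate a synthetic image + ground truth + scribbles
cellcut synth --preset ring --seed 1 --out demo/

# interactive segmentation from a scribble mask (labels 0/1/2)
cellcut segment --image demo/image.png --scribbles demo/scribbles.png \
    --mode adaptive --lambda1 20 --cp 20 --out mask.png

# fully automatic (Otsu-seeded) segmentation
cellcut segment --image demo/image.png --auto --mode static --out mask.png

# evaluate a mask against ground truth
cellcut eval --pred mask.png --truth demo/truth.png --out metrics.json

# λ sweep and salt-and-pepper robustness tables (CSV)
cellcut sweep --image demo/image.png --auto --truth demo/truth.png \
    --grid 1:400:20 --out sweep.csv
cellcut noise --image demo/image.png --auto --truth demo/truth.png \
    --densities 0,0.05,0.1,0.2 --out noise.csv
```

Every flag can also come from a plain-text config file (`key = value` lines)
via `--config`; explicit flags win.

## Library sketch

```python
import cellcut as cc

image, truth = cc.generate(cc.preset("ring", seed=1))
scribble = cc.generate_scribbles(truth, coverage=0.3, seed=1, erosion_radius=3)
seeds = cc.scribble_seeds(scribble, image)

static = cc.segment(image, seeds, mode="static")     # one global λ = 20
adaptive = cc.segment(image, seeds, mode="adaptive") # λ adapted at boundaries

print(cc.report(cc.confusion(adaptive.mask, truth)))
```

T-link convention (documented choice): the object-terminal (source) link of
a pixel carries the *background* data cost and the background-terminal
(sink) link the *foreground* cost, so a pixel labeled foreground pays
`−log P(I|fg)` through its severed sink link. Boundary adaptation boosts the
source link and zeroes the sink link, biasing boundary pixels toward
foreground.

## Reproducing published dataset tables

The dataset-level numbers require the public U2OS and NIH3T3 collections
(http://murphylab.web.cmu.edu/data/) and HT29 (BBBC008,
https://data.broadinstitute.org/bbbc/BBBC008/). A documented, untested
helper is provided in `reproduce/run_datasets.py`: point it at the
downloaded images and ground truths and it iterates the four pipelines and
emits pooled and per-image metrics per dataset.
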