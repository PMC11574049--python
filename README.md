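# punctafiber

Quantification of immunoreactive puncta on segmented nerve fibers in
two-channel fluorescence microscopy images.

The package implements an end-to-end, reproducible analysis pipeline:

1. **imaging_io** — TIFF stack/mask I/O, channel splitting, maximum-intensity
   projection (analysis always runs on 2-D projections).
2. **synthetic** — seeded generation of two-channel synthetic images
   (curvilinear fibers + Gaussian puncta + noise) with exact ground truth,
   plus simulated multi-expert annotations with known sensitivity/specificity.
3. **segmentation** — trainable pixel classification of the fiber channel:
   a multi-scale feature bank (Gaussian, gradient magnitude, LoG, Hessian
   eigenvalues, DoG at scales 1–16 px, plus raw intensity) feeding a
   100-tree random forest; an *external mask* backend wraps masks produced
   by any other tool (e.g. a deep-learning model) behind the same interface.
4. **staple** — STAPLE expectation-maximization fusion of multiple raters'
   binary masks into a consensus, estimating each rater's sensitivity and
   specificity; majority vote as a baseline.
5. **detection** — puncta as local intensity maxima strictly above a
   threshold (default 200 AU) restricted to the fiber mask, with exact
   plateau handling and an exhaustive brute-force reference implementation.
6. **quantify** — per-image punctum count, mean fluorescence intensity over
   the fiber mask (AU), and fiber area (µm², default 0.16 µm/pixel).
7. **stats** — method-agreement statistics: IoU/Dice, Spearman (midranks,
   t-approximation p), two-way absolute-agreement ICC(A,1) with
   poor/moderate/good/excellent bands at 0.5/0.75/0.9, Kruskal-Wallis with
   tie correction, and Dunn post-hoc with Bonferroni adjustment.
8. **pipeline / cli** — a single JSON config drives
   simulate → train → segment → quantify → compare with per-artifact
   provenance sidecars and byte-identical reruns for a fixed seed.

## CLI

```sh
punctafiber default-config > cfg.json          # starting config
punctafiber run --config cfg.json --seed 42 --out rundir
punctafiber simulate --config cfg.json --seed 1 --out dataset/
punctafiber train img1.tif img2.tif \
    --fiber-strokes f1.tif --fiber-strokes f2.tif \
    --background-strokes b1.tif --background-strokes b2.tif \
    --out classifier.joblib
punctafiber segment pgp95.tif --backend rf --model classifier.joblib --out mask.tif
punctafiber fuse rater1.tif rater2.tif rater3.tif --out consensus.tif
punctafiber detect trpv1.tif --mask mask.tif --threshold 200 --out spots.csv
punctafiber quantify --manifest dataset/manifest.json --backend truth --out quant.csv
punctafiber compare quant.csv --manual manual.csv --out report.json
```

All commands log to stderr and print only the final artifact path on stdout.
Manual counts join the comparison as a CSV with columns
`image_id,rater,n_puncta`.

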