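# gfpquant

Automatic quantification of GFP-labeled tumor-cell proliferation in
xenografted zebrafish embryos, plus the supporting pieces a screening
workflow needs:

- **Threshold sweep & selection** (`gfpquant.quantify`) — counts GFP pixels at
  every integer intensity threshold 0–50 and picks, per image, the smallest
  threshold from which the area curve is stable (every remaining unit step
  loses < 10% of the threshold-0 area). This strips the embryo's dim yolk
  autofluorescence without user intervention. Flat curves (no
  autofluorescence) fix the threshold at 1 and are flagged; curves that never
  stabilize are pinned at the sweep maximum with a `saturated` flag and a
  warning.
- **Proliferation index** — for a 0 hpi / 72 hpi image pair, thresholds are
  selected per timepoint, the *higher* one is applied to both, and
  `PI = (nGFP_72 · GMV_72) / (nGFP_0 · GMV_0)` where nGFP is the pixel count
  above threshold and GMV their mean intensity. PI > 1 reads as
  proliferation, < 1 as cell death, = 1 as stable.
- **Cell counting** (`gfpquant.counting`) — circular-Hough detection of cells
  in a pre-injection droplet micrograph, with a relative gradient-magnitude
  edge cutoff (exposure-invariant), an integer radius sweep and Euclidean
  non-maximum suppression. Exact for well-separated cells, a ~±15% estimate
  in the crowded 400–500-cell regime.
- **Phantoms** (`gfpquant.phantoms`) — seeded synthetic micrographs (yolk
  ellipse with intensity plateau + falloff, bright disk masses, Gaussian
  noise) with exact ground truth; these are the test bed standing in for the
  original micrographs, which are not deposited anywhere.
- **Cohort statistics** (`gfpquant.stats`) — pooled survival summaries
  (percent + sample SD of replicate proportions), Tukey/IQR outlier
  filtering with spreadsheet-style inclusive quartiles, and a two-group
  comparison gated on Levene's variance-equality test (Student's t when
  homoscedastic, Kruskal–Wallis otherwise).
- **Batch driver** (`gfpquant.batch` / CLI) — manifest CSV in, per-embryo PI
  table and discard report out; group-level summaries and pairwise tests.

## CLI

```bash
# one embryo: 0 hpi and 72 hpi images
gfpquant measure e1_0hpi.png e1_72hpi.png --sweep-csv sweeps.csv

# a whole experiment: manifest with embryo_id,timepoint,image_path[,labels...]
gfpquant batch manifest.csv --output-dir out/

# droplet cell count before injection
gfpquant count drop.png --r-min 4 --r-max 8 --detections-csv det.csv

# render phantoms from a YAML spec list
gfpquant simulate specs.yaml --output-dir phantoms/

# group comparison on a batch results CSV
gfpquant stats out/results.csv --group-by temp --alpha 0.01
```

Defaults (tolerance, t_max, Hough radii, alpha, …) can be set once in a YAML
file passed as `gfpquant --config cfg.yaml <subcommand> …`; per-invocation
options override it. Logs go to stderr, tables are CSV.

Images are read as 8- or 16-bit TIFF/PNG; RGB inputs contribute only their
green (GFP) channel and 16-bit data are mapped linearly onto the 0–255 scale
all thresholds are defined on.

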