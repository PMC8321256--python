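# veglatent

Self-supervised compression of satellite vegetation-index time series for
clustering, visualization and classification of vegetation types.

The pipeline takes dated six-band surface-reflectance scenes (Blue, Green,
Red, RedEdge1, RedEdge3, NIR), computes 16 spectral vegetation indices per
scene, composites them into per-pixel monthly medians — a 192-feature
(16 indices × 12 months) annual vector — and compresses that vector to
k ∈ {3, 5, 10} latent features with either a dense autoencoder (AE) or a 1-D
convolutional autoencoder (CAE, convolving over the month axis with 16 index
channels). Compressed features are evaluated against a Random-Forests
feature-importance baseline using bootstrap-resampled Random-Forests
classification with percentile confidence intervals, and visualized as 3-D
class scatter plots and false-color RGB composites.

A synthetic-scene generator with class-specific phenology (16 built-in
vegetation / non-vegetation classes) makes the whole pipeline runnable and
testable without any satellite downloads.

## CLI

Each stage is a subcommand of `veglatent`:

```sh
# 1. synthetic scenes + ground-truth points
veglatent simulate --config sim.yaml --out scenes/
# sim.yaml keys: grid_size, scenes_per_month, cloud_fraction, seed, points_scale

# 2. 16-index stack per scene
veglatent indices --in scenes/scene_2018-05-16_008.tif --out stacks/s008.tif \
    [--band-map B=1,G=2,R=3,RE1=4,RE3=5,N=6]

# 3. 192-band monthly-median composite (gap-filled)
veglatent composite --in stacks/ --out composite.tif

# 4. train an autoencoder, write the k-band latent raster + history sidecar
veglatent encode --composite composite.tif --kind cae --latent-dim 3 \
    --out latent.tif --model model.npz --seed 0

# 5. bootstrap-resampled Random-Forests evaluation at ground-truth points
veglatent evaluate --features latent.tif --points scenes/ground_truth.csv \
    --n-boot 1000 --train-fraction 0.75 --confidence 0.95 --seed 0 \
    --out report.json

# 6. figures
veglatent visualize scatter --latents latent.tif --points scenes/ground_truth.csv --out scatter.png
veglatent visualize rgb --latents latent.tif --out rgb.png
```

Rasters are multi-band float32 TIFFs; acquisition date, band names and the
nodata value travel in a metadata tag, and masked cells carry the nodata
value.

## Library layout

| module | contents |
| --- | --- |
| `veglatent.simulate` | class profiles, synthetic scene generator |
| `veglatent.indices` | 16-index registry (ARVI … VARI), per-scene stacks |
| `veglatent.compositing` | monthly medians, gap filling, 192-vector assembly |
| `veglatent.encoders` | AE / CAE models, training, persistence |
| `veglatent.evaluation` | point extraction, RF top-k baseline, bootstrap CIs |
| `veglatent.visualization` | 3-D scatter plots, percentile-stretch RGB |
| `veglatent.raster` | TIFF-backed raster container with validity masks |

Two registry conventions worth knowing: ARVI uses the Kaufman–Tanre form
with gamma = 1 (`rb = 2R − B`), and GCI is `N/R − 1` (implemented exactly as
tabulated in the source material). Composite band order is month-major
(`m01_ARVI … m12_VARI`), which is what lets the CAE reshape the 192-vector
into a 12-step, 16-channel sequence.

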