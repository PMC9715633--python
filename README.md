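# alpinepheno

A tested, reusable pipeline for seasonal growth phenology of alpine
grassland: image-derived canopy greenness and mini-rhizotron root-area time
series, penalized-spline extraction of phenological timepoints, soil-
temperature season metrics, and group comparison statistics — together with
a synthetic-study generator that provides analytic ground truth so every
stage is testable without any external data.

## Modules

| Module | What it does |
| --- | --- |
| `alpinepheno.synth` | Synthetic temperature logs, leaf/greenness/root trajectories (closed-form truth dates), canopy photographs and rhizotron scan stacks with truth masks |
| `alpinepheno.imaging` | Canopy greenness G/(R+G+B); rhizotron chain: destripe (FFT notch), brightness/contrast normalization, phase-correlation alignment, tiling, classical ridge-based root segmentation, root area (mm2 cm-2) and medial-axis diameters |
| `alpinepheno.phenometrics` | Percent-of-maximum scaling, GCV-penalized spline smoother (<= 8 basis functions), peak / 50%-decline / growth-quantile / max-rate dates, area under the curve, moving-window root-growth onset |
| `alpinepheno.season` | Season-start detection from soil temperature (warm + diurnal-cycle persistence), configured season ends, first-N-day mean temperature, growing degree hours, visit pooling, elongation/browning rates |
| `alpinepheno.vigour_stats` | Photosynthetic vigour index, per-species scaling, pooled-variance pairwise group contrasts, paired max-vs-last change, simple OLS regression |
| `alpinepheno.pipeline` / `alpinepheno.cli` | End-to-end orchestration with a YAML config and a `click` CLI |

## CLI

One entry point with subcommands (exit codes: 0 ok, 1 usage error, 2 data
error):

```bash
# generate a synthetic study (measurements, temperatures, truth, windows)
alpinepheno synth --seed 1 --out study/

# fit smoothers and extract per-unit metrics
alpinepheno pheno --windows study/windows.csv --out metrics.csv study/measurements.csv

# season-start detection from a temperature CSV
alpinepheno season detect study/temperature.csv

# pairwise group contrasts for one metric
alpinepheno stats --metric days_to_peak --variable leaf_length_cm metrics.csv

# canopy greenness for images (optional ROI mask)
alpinepheno imaging greenness --roi mask.png photo1.jpg photo2.jpg

# full rhizotron chain on a directory of scans
alpinepheno imaging roots --dpi 1200 --out roots.csv scandir/

# synthetic end-to-end run (generate -> fit -> metrics -> contrasts)
alpinepheno run --seed 1 --out outputs/
```

## Data formats

All I/O is plain text: measurement CSV (`unit_id, group, doy, variable,
value`), temperature CSV (`unit_id, timestamp, temp_C`, ISO-8601 at 1 h or
2 h steps), metrics/contrast CSVs, truth JSON, and PNG/TIFF rasters for
images and masks.
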