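# hcsquant

Quantification of ATF6α nuclear translocation and ER exit-site (ERES)
engagement in high-content fluorescence microscopy screens.

ATF6α is an ER-membrane transcription factor of the unfolded protein
response: upon ER stress it traffics in COPII vesicles to the Golgi, is
cleaved, and its N-terminal fragment enters the nucleus. Imaging screens
for modulators of this pathway therefore need two quantitative readouts,
both of which this package implements as a tested, reusable pipeline:

1. **Nuclear translocation scoring.** Per cell, masks for the nucleus
   (DAPI) and the ER (GRP94) are segmented and the ratio

   r = mean ATF6 intensity over nucleus / mean ATF6 intensity over ER

   is computed. A plate-adaptive activation threshold t is the minimum
   ratio greater than 1 at which the stressed-control well's ratio
   histogram rises above the unstressed control's (common bins, per-bin
   relative frequencies). Percent activation of a well is the percentage of
   its cells with r > t, and a test well is a **hit** when its percent
   activation falls below mean − 3·SD of the stressed-control wells.

2. **ERES colocalization.** Sec31A and Sec16 images are multiplied after
   per-channel median background subtraction, so only pixels carrying both
   COPII markers are non-zero. Puncta are detected on this product image by
   automatic (Otsu) thresholding with intensity-based declumping, gated to
   equivalent diameters of 0.167–1.67 μm, and used as masks to measure the
   original channels. Colocalization of GFP-ATF6α with Sec31A is the
   pixelwise Pearson r over a cell's pooled ERES pixels, per z-slice,
   aggregated per cell and per treatment.

Because raw screening microscopy is rarely redistributable, the package
ships a **synthetic scene generator** (`hcsquant.synthetic`) that emulates
both assays with full ground truth — cell masks, per-cell activation labels
and true ratios, punctum positions/diameters/co-occurrence, and a target
within-punctum correlation ρ imposed by Gaussian copula mixing — plus
Poisson shot noise and Gaussian read noise. Every pipeline stage is
validated against these known answers.

Classical statistics used in reporting (pooled-variance unpaired two-tailed
t-test, one-way ANOVA, two-tailed variance-ratio F test, t-based 95%
confidence limits) live in `hcsquant.stats`.

## Worked example

Score a simulated stressed/unstressed control pair through the full image
pipeline (segmentation → per-cell ratios → plate threshold → percent
activation):

```python
import hcsquant as hq
from hcsquant.segmentation import segment_nuclei, segment_cells
from hcsquant.translocation import score_cells, derive_threshold, percent_activation

scenes = {
    "stressed": hq.translocation_scene(n_cells=25, field_shape_px=(760, 760),
                                       activated_fraction=0.6, seed=1),
    "unstressed": hq.translocation_scene(n_cells=25, field_shape_px=(760, 760),
                                         activated_fraction=0.02, seed=2),
}
ratios = {}
for name, spec in scenes.items():
    images, truth = hq.generate_translocation_field(spec, well_id=name)
    ch = {im.channel: im for im in images}
    nuclei = segment_nuclei(ch["dapi"])
    _, cells = segment_cells(ch["er"], nuclei)
    ratios[name] = score_cells(ch["atf6"], cells)

thr = derive_threshold(ratios["stressed"], ratios["unstressed"])
print(f"plate threshold: {thr.value:.2f} (bin width {thr.bin_width})")
for name, r in ratios.items():
    wa = percent_activation(r, thr, well_id=name, min_cells=20)
    print(f"{name}: {wa.n_cells} cells, {wa.percent_activation:.1f}% activation")
```

prints

```
plate threshold: 1.40 (bin width 0.05)
stressed: 25 cells, 44.0% activation
unstressed: 25 cells, 4.0% activation
```

All 25 planted cells are recovered in each field. The threshold of 1.40
sits where the activated (nuclear, ratio-median 2.5) mixture component
overtakes the inactive (ER-retained, median 0.8) one; 44% of the stressed
well's cells score above it (11 of 25 were planted as activated in this
small field — percent activation estimates the planted activated fraction,
here with ~25-cell sampling noise), versus 4% of the unstressed well's.

## Command line

Each stage is also exposed as a subcommand of `hcsquant`:

```sh
hcsquant simulate --plate plate.yaml --seed 4 --out-dir fields/
hcsquant segment  --field fields/A01_f00.ome.tif --config config.yaml --out-dir masks/
hcsquant score    --fields fields/ --config config.yaml --out scores.csv
hcsquant hits     --scores scores.csv --layout layout.yaml --out-dir results/
hcsquant eres     --fields eres_fields/ --out-dir eres_results/
hcsquant report   --wells results/wells.csv --scores scores.csv \
                  --layout layout.yaml --out-dir report/
```

`plate.yaml` describes the well layout (roles: `unstressed_control`,
`stressed_control`, `test`) and per-role scene parameters; `config.yaml`
overrides analysis defaults (see `hcsquant.config.default_config()` for
the complete set with units).

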