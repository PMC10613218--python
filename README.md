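# vesicoloc

Quantification of multivesicular endosome (MVE) imaging: scale-tuned
Laplacian-of-Gaussian spot detection, line-profile peak-overlap
colocalization scoring, mitochondrion–MVE contact-site (MMCS) counting with
perinuclear/peripheral region assignment, an electron-microscopy
direct-contact rule, and post-processing of 3D single-molecule localization
tables — together with a synthetic-scene generator that provides ground
truth for every stage.

## Who this is for

Cell biologists quantifying punctate organelles (CD63- or EEA1-labelled
endosomes, phosphoinositide reporters, exocyst subunits, mitochondria) in
multichannel confocal images, and anyone who wants those measurements as a
scripted, reproducible pipeline instead of interactive point-and-click
analysis.

## The measurements

**Spot detection.** Vesicles are found as local maxima of the
scale-normalized negated LoG response
`R = -σ² (G_σ * ∇²) I`, with `σ = d/(2√2)` matched to the estimated object
diameter `d` (10 px ≈ 1 µm for CD63-like vesicles, 6 px ≈ 0.6 µm for
EEA1-like structures). The response value at a maximum is the detection
"quality"; maxima below a quality threshold are discarded and duplicates
within `d/2` are suppressed. Suspected unresolved doublets are flagged, not
split.

**Line-profile colocalization.** On 8-bit images (fixed linear display
range, identical across a condition set), a 40-px line is drawn across each
vesicle and both channels are sampled along it. A *signal* is a maximal run
of samples strictly above a cutoff of 100 (8-bit units). A vesicle is
marker-positive when the overlap area between the vesicle peak and the
marker peak — the sum of the pointwise channel minimum over the
intersection of their supports — exceeds 50% of the marker peak area.
The fraction of positive vesicles is the percentage of marker-positive
MVEs; the same machinery quantifies reporter (e.g. phosphoinositide probe)
intensity per vesicle.

**Contact sites.** A 50-px profile is drawn across each vesicle toward the
closest mitochondrion; overlapping supra-background signal runs of the two
channels call an MMCS. Contacts are assigned to the perinuclear disk (twice
the equivalent-area nuclear diameter, centred on the nucleus centroid) or
the peripheral remainder of the cell. In EM annotation tables, a vesicle
and a mitochondrion are in direct contact when their boundary-to-boundary
gap is below the image's mean vesicle radius.

**Localization rendering.** 3D localization tables (nm) are scaled and
exported as uranium pseudo-atom XYZ files, converted to Gaussian density
volumes (unit-integral kernels, σ = sigma_factor × resolution), and
dust-filtered: a localization with no neighbour within 60 nm is removed.

**Statistics.** Group summaries are mean ± s.d.; differences are tested
with the two-sided unpaired pooled-variance Student's t-test; channel
correlation is Pearson's r on raw whole images.

## Worked example

Score two synthetic conditions (10 cells × 50 vesicles each) that differ in
the true fraction of marker-carrying vesicles:

```python
import numpy as np
from vesicoloc import SceneParams, RunConfig, run_pipeline, unpaired_t_test

control = RunConfig(
    scenes=[SceneParams(n_vesicles=50, marker_positive_fraction=0.45)] * 10,
    seed=1,
)
depleted = RunConfig(
    scenes=[SceneParams(n_vesicles=50, marker_positive_fraction=0.10)] * 10,
    seed=2,
)
res_c = run_pipeline(control)
res_d = run_pipeline(depleted)
print(f"control:  {np.mean(res_c.percent_positive_per_cell):.1f} +- "
      f"{np.std(res_c.percent_positive_per_cell, ddof=1):.1f} % marker-positive "
      f"(n = {len(res_c.percent_positive_per_cell)} cells)")
print(f"depleted: {np.mean(res_d.percent_positive_per_cell):.1f} +- "
      f"{np.std(res_d.percent_positive_per_cell, ddof=1):.1f} % marker-positive "
      f"(n = {len(res_d.percent_positive_per_cell)} cells)")
t = unpaired_t_test(res_c.percent_positive_per_cell,
                    res_d.percent_positive_per_cell)
print(f"unpaired two-sided t-test: t = {t.t:.2f}, df = {t.df}, p = {t.p:.2e}")
```

Output:

```
control:  45.8 +- 8.0 % marker-positive (n = 10 cells)
depleted: 9.4 +- 4.2 % marker-positive (n = 10 cells)
unpaired two-sided t-test: t = 12.76, df = 18, p = 1.86e-10
```

The pipeline detects each cell's vesicles, scores every detection against
the marker channel by the peak-overlap rule, and recovers the simulated
45% vs 10% marker-positive fractions; the t-test separates the conditions
decisively. `run_pipeline` also emits per-detection, per-call and
per-contact CSVs plus a config echo when given an `output_dir`.

A command-line interface wraps the same library:

```sh
vesicoloc simulate --n-cells 3 --marker-fraction 0.45 --seed 1 --out scenes/
vesicoloc detect scenes/cell_000/scene.tif --channel 0 --quality 30
vesicoloc em-contacts annotations.csv
vesicoloc render-locs locs.csv --xyz-out cloud.xyz --volume-out density.tif
vesicoloc report --config run.yaml --out results/
```

## Documentation

`docs/methods.md` describes the model behind the synthetic scenes, every
procedure constant and its default, the numerical choices (rounding,
interpolation, tie-breaks, strict comparisons) and the known limitations.
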