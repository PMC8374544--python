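# vfoct

Quantitative analysis of coronal-plane optical coherence tomography (OCT)
image sequences of the vibrating human vocal folds.

Endoscopy sees only the superior epithelial surface of the vocal folds.
Long-range swept-source OCT images the folds in coronal cross-section at
micrometer resolution and hundreds of frames per second, exposing the
layered structure — epithelium (EP) over lamina propria (LP) — and the
*vertical* component of the mucosal wave that surface imaging cannot
measure. `vfoct` turns such frame sequences into numbers: per-A-line layer
thicknesses, vertical vibration amplitude, depth-resolved videokymograms,
and space-time surface velocity fields. It is written for laryngology /
voice-science groups working with coronal OCT of the larynx, and for anyone
who needs a tested, reproducible reference pipeline for two-layer OCT
segmentation of oscillating tissue.

## Method

Per frame, the analysis chain is:

1. **Preprocess** — template-matching stabilization against bulk motion
   (integer-pixel, normalized cross-correlation), ROI cropping, and split-
   Bregman total-variation denoising (λ = 0.1).
2. **Threshold** — the intensity histogram of a fold image is tri-modal
   (noise floor < EP < LP, because the collagen-dense LP backscatters more).
   The histogram is smoothed with a quadratic univariate spline; the two
   troughs separating the three dominant modes give per-frame thresholds
   `t_noise/EP` and `t_EP/LP`. Frames without three modes carry forward the
   previous frame's thresholds, or fall back to fixed fractions of the
   occupied intensity range.
3. **Contour** — marching-squares iso-contours at the two thresholds give
   sub-pixel boundaries: the EP outer surface and deep LP/noise transition
   at `t_noise/EP`, the EP/LP interface at `t_EP/LP`. Speckle islands are
   rejected by enclosed area, contours are split at the glottal midline,
   and per-A-line boundary rows are refined by first-order edge
   relocalization and ordered (EP outer < interface < LP deep).
4. **Measure** — thickness per A-line is the boundary row gap × the tissue
   axial pitch `p_t = p_air / n` (5.94 μm/px ÷ 1.4 = 4.24 μm/px for the
   default instrument); vertical displacement tracks the superior-medial
   surface point against its rest baseline; 30 points per fold, equidistant
   in x along the superior contour, yield per-point velocities
   `v_y = Δrow · p_t · f_frame`, `v_x = Δcol · p_lat · f_frame` and net 2D
   vectors; kymographs stack per-A-line thickness over time with an AIR
   sentinel marking the glottal gap.

Because no public coronal-OCT data of phonating folds exists, the package
ships a first-class synthetic phantom (`vfoct.phantom`): a two-layer,
bilateral fold scene with tri-modal intensities, multiplicative log-normal
speckle, exponential depth attenuation (~1 mm penetration), a glottal gap,
and sinusoidal vertical/lateral vibration with exact analytic ground truth.
Every stage of the chain is validated against it.

## Worked example

Run the full pipeline on a speckled phantom (30 frames at 250 Hz, 10 Hz
vibration, 0.1 mm vertical amplitude, 100 μm EP / 420 μm LP):

```python
from pathlib import Path
from vfoct.phantom import PhantomConfig
from vfoct.pipeline import RunConfig, run

ph = PhantomConfig(frame_shape=(200, 240), n_frames=30, n_rest_frames=5,
                   fundamental_freq=10.0, vertical_amplitude=0.1,
                   lateral_amplitude=0.05, glottal_half_gap=150.0,
                   speckle_sigma=0.12, lateral_taper=0.05, rng_seed=1)
manifest = run(RunConfig(output_dir="demo_out", phantom=ph))
print(manifest.n_accepted, manifest.amplitudes_mm)
```

which prints

```
30 {'left': 0.10151630752586663, 'right': 0.10134418267972081}
```

— all 30 frames segmented, and the 0.1 mm configured amplitude recovered to
about 1% on both folds. The thickness summary written to
`demo_out/thickness_summary.csv` reads (μm, "select" = within ±3 SD of the
full-distribution mean):

```
   layer     phase  n_points  mean_full  sd_full  mean_select  sd_select  n_excluded
      ep phonation      5199       99.1      1.3         99.1        1.1           8
      lp phonation      5199      421.2      1.4        421.3        1.1          11
combined phonation      5199      520.4      0.8        520.4        0.7          12
```

recovering the configured 100 μm EP and 420 μm LP to ~1 μm. `demo_out/`
also contains per-frame boundary polylines (JSON), per-A-line thickness and
velocity tables (CSV), EP/LP/combined kymograph matrices and renderings,
and a JSON manifest echoing every parameter.

The same is available from the shell:

```bash
vfoct phantom --out ph_out --seed 1
vfoct run --config run.yaml
vfoct calibrate --out cal_out      # mirror-stage sweep + px/mm regression
```

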