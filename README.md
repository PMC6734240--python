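# nucquant

Per-nucleus volumetric fluorescence quantification for 3D confocal stacks —
with a built-in simulator that makes every stage testable against ground
truth.

Many questions about nuclear proteins reduce to *how much of it is in each
nucleus, and at what concentration*: is the concentration constant within a
cell type, how different are cell types (e.g. neurons vs glia), does a DNA
stain integrate to the expected G2/G1 = 2 ratio, and do two per-nucleus
signals (say, nascent-mRNA labelling and a transcription factor) co-vary?
`nucquant` implements the measurement chain those questions need:

1. **synthetic scenes** — ellipsoidal nuclei with known per-channel
   concentrations, rendered at confocal sampling (0.112/0.112/0.200 µm) with
   depth-dependent blur, Poisson shot noise, Gaussian read noise and a
   background floor;
2. **theoretical-PSF MLE deconvolution** — Richardson–Lucy restoration with
   depth "bricks" (a PSF per z-slab), SNR-tied damping and a 0.1%
   quality-change stopping rule;
3. **iso-surface segmentation** — thresholding at the background level,
   filtering truncated (face-touching), merged and too-small objects;
4. **per-nucleus measurement** — the volume integral `T` (a.u.), the volume
   `V` (µm³, partial-volume corrected), the concentration `T/V`, and a fast
   ellipsoid approximation `V ≈ 2/3 × (largest transversal area) × thickness`;
5. **statistics** — through-origin constant-concentration fits
   (`slope = Σ(T·V)/Σ(V²)`), between-population concentration ratios with
   bootstrap CIs, DNA-content KDE peak calling, Spearman correlation with an
   exact small-n permutation test, and rectangle-volume gel densitometry with
   local background subtraction.

## Worked example

Simulate a two-population "cortex" field — neuron-like nuclei at
5.0 a.u./µm³ and glia-like nuclei at 1.0 a.u./µm³ (a 5:1 contrast) — and
recover the contrast end-to-end:

```python
from nucquant import RunConfig, run_pipeline
from nucquant.pipeline import SceneSection

cfg = RunConfig(
    scene=SceneSection(preset="cortex",
                       n_per_type={"neuron": 12, "glia": 12}, n_fields=1),
    seed=1,
)
res = run_pipeline(cfg)
r = res.stats["glia_vs_neuron"]
print(f"kept {res.n_kept} nuclei")
print(f"glia = {r['percent_of_neuron']:.1f}% of neuron concentration "
      f"(95% CI {r['percent_ci95'][0]:.1f}-{r['percent_ci95'][1]:.1f}%)")
```

Output from this exact configuration:

```
kept 24 nuclei
glia = 20.2% of neuron concentration (95% CI 20.2-20.3%)
```

All 24 simulated nuclei survive QC, and the recovered glia-to-neuron
concentration percentage lands on the injected 20% (= 1/5): the render →
deconvolve → segment → integrate chain is quantitatively unbiased, not just
qualitatively sensible. The same driver exposes the other readouts:
`constant_concentration` scenes yield a through-origin slope within a few
percent of the injected concentration with a concentration-vs-volume Spearman
CI covering zero, and `cycling_dapi` scenes put the second DNA-content peak
at 2.0 ± 0.05 after normalizing the first to 1.

A command-line interface wraps the same stages
(`nucquant simulate | deconvolve | quantify | stats | run`), reading and
writing multi-page TIFF with voxel-size metadata, measurement CSVs and JSON
reports; see `nucquant --help`.

## Layout

```
src/nucquant/
  scene.py     ground-truth scenes, presets, rendering
  optics.py    theoretical PSFs, depth bricks, RL deconvolution
  quant.py     background, segmentation QC, per-nucleus measurement
  stats.py     fits, ratios, ploidy peaks, Spearman, densitometry
  pipeline.py  RunConfig + end-to-end driver with provenance
  tiffio.py    TIFF + voxel-size metadata I/O
  cli.py       command-line interface
docs/methods.md   models, conventions, numerical choices, limitations
```
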