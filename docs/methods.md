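# Methods

`nucquant` quantifies per-nucleus fluorescence in 3D confocal stacks and
validates that quantification on simulated ground truth. This note documents
the models, the numerical choices, and what the synthetic data do and do not
establish.

## The measurement model

A field of view contains nuclei `i = 1..N`, each an ellipsoid of volume
`V_i` (µm³) with a uniform intranuclear fluorophore concentration `c_i`
(a.u./µm³) per channel. The microscope reports

    I(x) = (PSF_depth ⊛ [signal + background])(x) · shot noise + read noise + offset

and the pipeline inverts this chain to recover the per-nucleus *volume
integral* `T_i = c_i · V_i` (total signal, a.u.) and `V_i`, from which the
concentration `c_i = T_i / V_i` follows. The biological questions attached to
these quantities are: is `c` constant within a cell type (totals proportional
to volume through the origin), how do cell types differ (concentration
ratios), does a DNA stain integrate to the expected 2:1 G2/G1 ratio, and do
two channels' totals co-vary (rank correlation).

## Synthetic scenes (`nucquant.scene`)

Nuclei are ellipsoids with semi-axes `(a, b, c)` (x, y, z), rotated only about
the optical axis; `c` is the short axis so populations look like adherent or
tissue nuclei in thin stacks. Within a cell type, volumes are lognormal
(CV 15% by default); the `constant_concentration` preset instead lays volumes
on a jittered geometric ladder so a ≥2-fold spread is guaranteed at any `n`.
Placement is rejection sampling, largest nuclei first, with non-overlap
decided by the support-function criterion (centre distance must exceed the sum
of both support radii along the centre line, plus a 0.5 µm clearance); 1000
failed attempts for one nucleus raise a placement error naming the bound.

Presets and their study conditions:

* `cortex` — neuron-like nuclei (mean 520 µm³) at 5.0 a.u./µm³ and glia-like
  nuclei (mean 150 µm³) at 1.0 a.u./µm³. The 5:1 concentration contrast is the
  quantity of interest; the absolute volumes are plausible placeholders (the
  imaging literature does not pin them) and only the ratio carries meaning.
* `constant_concentration` — one type, one shared concentration
  (default 3.0 a.u./µm³), volumes spanning ~3-fold.
* `cycling_dapi` — a cycling population: integrated DNA signal per nucleus is
  `g1_total · d_i · s_i` with `d_i = 1` (G1 fraction 0.55), `2` (G2, 0.30), or
  uniform in (1, 2) (S, 0.15), and `s_i` multiplicative staining noise
  (CV 5%). Phase counts are apportioned deterministically (largest
  remainder), so the designed fractions are exact at any `n`. Nuclear volume
  is drawn independently of phase; the DNA *concentration* is `total/V`.
* `correlated_channels` — two channels; channel-2 concentration is
  `α·c1 + ε` (α = 1, ε Gaussian σ = 0.25) in `correlated` mode or an
  independent draw in `independent` mode, mirroring a factor that tracks
  transcription vs one that does not.

Rendering voxelizes each ellipsoid at voxel centres, refining boundary voxels
(identified by a Lipschitz bound on the normalized radius) with 3×3×3
sub-voxel sampling — volume bias of the rasterization is below ~0.5%. The
diffuse background floor is added, the depth-appropriate PSF brick blurs each
slab, and the detector model applies Poisson noise at `photon_scale`
(default 8000 photons per a.u., putting bright interiors near 100
photons/voxel, i.e. image SNR ≈ 10), Gaussian read noise (2×10⁻⁴ a.u.), and a
baseline offset (10⁻³ a.u.). All randomness flows from a single integer seed
through named `SeedSequence` children, so identical inputs give bit-identical
stacks.

Default sampling is 0.112 × 0.112 µm laterally and 0.200 µm axially. Fields
are desk-scale (64–80 µm across, 7.5–14 µm deep — thin stacks for
cultured-cell-like presets, as monolayers are imaged, deeper for the
tissue-like cortex preset); populations larger than one field can hold are
tiled across several independently rendered fields and the measurements
pooled, exactly as cells from several microscope fields are pooled in
practice.

What the simulator deliberately omits: intranuclear texture (chromatin
granularity), autofluorescent structures, spectral bleed-through,
photobleaching, and stage drift. Passing tests therefore demonstrate that the
*quantification chain* is unbiased for blob-like uniform nuclei under
realistic optics and noise — not that segmentation would survive textured
tissue backgrounds.

## Optics (`nucquant.optics`)

The theoretical confocal PSF is the standard Gaussian approximation:
`σ_xy = 0.21·λ/NA`, `σ_z = 0.66·λ·n/NA²` (λ emission wavelength, default
527 nm; NA 1.30; n 1.515). Kernels are voxel-integrated 1D Gaussians (exact
within each voxel — important because `σ_xy` is below one voxel at default
sampling), outer-multiplied, unit-sum, trimmed where a tail holds < 10⁻⁶
mass. Depth-dependent spherical aberration inflates `σ_z` by `(1 + β·depth)`
with `β = 0.01/µm`. Depth bricks partition the stack: mode `more` → 6 bricks,
`few` → 2, `one` → 1, each brick using the PSF at its mid-depth; slabs are
padded by the kernel half-width and blended by linear feathering. Thin
(<10 µm) stacks use a single brick — the depth range is too small for the
aberration model to matter.

Deconvolution is the classical maximum-likelihood estimator for Poisson data
(Richardson–Lucy multiplicative updates), with two conventions where
commercial implementations are proprietary:

* **Regularization**: the update is damped Tikhonov-style,
  `e ← e·(H'r + λ)/(1 + λ)` with `λ = 1/SNR²` (SNR default 10), which leaves
  the RL fixed point intact but tempers noise amplification.
* **Stopping**: the restoration quality is the normalized L2 data residual
  `q = ‖data − H·e‖ / ‖data‖`; iteration stops when the relative change of
  `q` drops below the quality-change threshold (default 0.1%). On noisy data
  this halts at the noise floor after ~15–25 iterations; a plain
  estimate-to-estimate change metric never reaches 0.1% because RL keeps
  re-arranging amplified noise indefinitely.

The background estimate is subtracted (clipped at zero) before restoration,
so the output is background-free; above-background flux is conserved within
1% for interior content, non-negativity is preserved by construction, and
non-convergence at the iteration cap is recorded in provenance and warned
about, never silently altered.

## Segmentation and measurement (`nucquant.quant`)

The background level of a stack is the mode of its intensity histogram (512
bins capped at the 99.5th percentile); the noise scale is the MAD. The
iso-surface threshold "at the background/non-specific level" is
`mode + k·MAD` with `k = 3`; because the deconvolved stack is
background-free, the pipeline applies the equivalent level `k·MAD(raw)` to
it. Binarization is followed by per-z-slice hole filling (3D filling could
seal the gap between stacked nuclei), 26-connected labelling, and three QC
filters in order: components below `min_volume` (default 30 µm³ — noise
speckles), components touching any stack face (*truncated*: their integral
would be incomplete), and components larger than 2.5× the robust median
volume (*merged* objects that failed to separate). Kept labels are contiguous
and provably absent from every face.

Totals are `Σ(voxel − background)` over each label, per channel. Two volume
estimators are reported:

* `volume` (default): **partial-volume weighted** — `flux / plateau`, where
  the plateau is the mean intensity of the eroded component core. A low
  iso-surface necessarily sweeps in the boundary skirt (partially covered
  voxels plus residual blur), which inflates plain voxel counts by ~5–15%
  *more for small nuclei than large ones* — a size-dependent bias that would
  masquerade as a concentration–volume trend. Because blur and RL conserve
  flux, dividing the component flux by the interior plateau recovers the true
  volume to ~0.5% for uniform nuclei, independent of size. The estimator
  assumes uniform intranuclear concentration; on strongly textured real
  nuclei it degrades gracefully toward a flux-weighted effective volume.
* `volume_voxels`: the plain voxel count × voxel volume, always reported, and
  selectable as the primary volume (`partial_volume=False`).

The accelerated pathway (`measure_ellipsoid_fast`) approximates each nucleus
by `volume = 2/3 × (largest single-z-slice area) × (z extent)`. The formula
is exact for ellipsoids in *any* orientation (the largest section of an
ellipsoid with z-support half-width `h` has area `πabc/h`, and
`2/3 · πabc/h · 2h = 4/3·πabc`); on non-ellipsoidal shapes it biases low
(about −33% on a cube), which is the documented price of the speed-up.

## Statistics (`nucquant.stats`)

* **Constant-concentration fit**: through-origin least squares
  `slope = Σ(T·V)/Σ(V²)` — the population concentration, the "radial
  iso-concentration line". A free-intercept fit is reported as a diagnostic,
  and the Spearman rho between per-cell concentration and volume (with a
  bootstrap CI) is the constancy test: ≈0 under constancy, →1 when totals
  grow faster than volume. Bootstrap CIs are percentile, 2000 resamples,
  seeded.
* **Concentration ratio** between two populations: ratio of mean
  concentrations with a within-group bootstrap CI; both orientations and the
  totals ratio are reported.
* **Ploidy peaks**: Gaussian KDE (Silverman bandwidth unless given in a.u.),
  local maxima above 5% prominence, positions normalized to the lowest peak;
  the second peak of a cycling population should sit at 2.0. Silverman's rule
  slightly over-smooths a bimodal mixture and the S-phase shelf pulls the G2
  peak inward by ~0.01–0.03 — well inside the ±0.05 acceptance band, and
  the bandwidth is configurable for sharper data.
* **Spearman correlation**: average-rank rho; the p-value is an exact
  full-enumeration permutation test for n ≤ 10 and the t-approximation above
  (exact enumeration beyond ~10 is combinatorially impossible). No
  multiple-testing correction is applied — the correlations are reported
  descriptively.
* **Densitometry**: band volume = rectangle sum − (mean of a 2-pixel frame) ×
  area, normalized per lane by a loading-control rectangle and expressed as
  fold change over a named reference condition. The frame-based local
  subtraction makes volumes invariant to global intensity offsets.

## Pipeline and provenance (`nucquant.pipeline`, `nucquant.cli`)

`run_pipeline` ties the stages together from a JSON-serializable `RunConfig`
(lossless round-trip, content hash), writes measurements CSV / stats JSON /
scene truth / provenance, and in simulate-and-analyze mode adds a
truth-vs-estimate table matched by nearest centroid (1.5 µm gate).
Re-running a config is byte-identical; analyze-only runs on previously
written stacks reproduce the same statistics. Warnings (non-convergence,
empty segmentations, small samples) are collected into provenance and drive
the CLI exit code unless `--allow-warnings`.

## Problem sizes used for validation

The end-to-end validation runs use 300 nuclei tiled over nine 80×80×7.6 µm
fields (DNA-doubling check) and 24+24 nuclei over two 72×72×14 µm fields
(5:1 contrast check) at the default 0.112/0.112/0.200 µm sampling — chosen as
the smallest populations/fields at which the two printed validation numbers
are meaningfully testable, while a full run stays in the minutes range on one
CPU. Unit tests use single-nucleus or few-nucleus fields a few microns
across.

## Known limitations

* The Gaussian PSF ignores the Airy side-lobes and axial asymmetry of a real
  (Gibson–Lanni) confocal PSF; whole-nucleus integrals are insensitive to
  tail shape, but sub-resolution morphology would not be.
* The partial-volume volume estimator assumes uniform intranuclear signal.
* Merged-nucleus rejection (2.5× robust median) presumes a unimodal-ish
  volume distribution per field; a field dominated by one giant cell type
  plus a few small ones could mis-flag the giants.
* Touching nuclei are rejected, not split — no watershed pathway.
* The exact brick count behind the commercial "More" mode, its quality
  metric, and its SNR→regularization mapping are unpublished; the
  conventions above (6 bricks, data-residual quality, λ = 1/SNR²) are this
  package's documented choices.
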