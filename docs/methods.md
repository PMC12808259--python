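# Methods

This note records the model behind `gsrquant`, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Imaging model and calibration

All images are unit-interval float grids regardless of file bit depth
(8/16-bit integers are divided by their type maximum), so thresholds and
presets are independent of the capture format.  Greyscale conversion of
colour input uses fixed Rec. 601 luma weights (0.299, 0.587, 0.114): the
in-camera monochrome rendering of the original photographs is not
specified anywhere, and a fixed published standard keeps results
reproducible.  The HSV value channel is the hexcone model `V = max(R,G,B)`.

Physical calibration is a single number, `l_pixel` (mm per pixel),
supplied by the user; the package makes no attempt to detect scale bars.
Every pixel count `n` converts to area as `A = l_pixel² · n`.  Both the
raw pixel total and the physical area are reported, since pixel-denominated
areas are what the quantification typically gets compared on.

## Frequency-domain fabric suppression

Filters are radial masks in the centred 2-D DFT plane.  The radial
coordinate is measured in **cycles per image width** on both axes (the
per-axis normalized frequency times the width), which makes a preset
transfer across resolutions for square pixels.  Two shapes exist:

- high-pass: 0 below `low_cut`, 1 above — removes illumination gradients
  and any large-scale unevenness;
- band-pass: 1 on (`low_cut`, `high_cut`) — additionally removes a
  periodic weave band above `high_cut`.

Transitions are Gaussian-edged (an erf profile of width
`transition_width`); width 0 gives an ideal hard edge, used by the
analytic tests.  The DC bin is always forced to zero, so high-pass output
is exactly zero-mean and a constant image is annihilated.  After
filtering, the real part is affinely rescaled to [0, 1] (a constant
pre-normalization result maps to all zeros) so that downstream thresholds
operate on a common scale.

Per-fabric presets — white cotton: high-pass, `low_cut` 8, transition 4;
denim: band-pass, 6–64, transition 4 — are tunable defaults validated on
the synthetic suite, not measured properties of any particular fabric.
The original analyses are described as individually tuned per image; the
presets plus a TOML config file and CLI override flags mirror that
practice while keeping every parameter an explicit, logged artifact.

## Thresholding

Foreground is `intensity < threshold`.  `AUTO` implements Otsu's
between-class-variance criterion on a 256-bin histogram, with two
numerical choices that matter in the particle-counting regime:

1. **Plateau midpoint.**  With a tiny foreground fraction the criterion
   is constant across the empty histogram gap between the dark spots and
   the background.  Taking the first maximizing bin (the common library
   convention) parks the threshold at the top of the dark mode and loses
   particles whose intensity ties the threshold; `gsrquant` takes the
   middle of the maximizing plateau, i.e. the centre of the gap.
2. **Unimodality guard.**  On an image with no particles at all, Otsu
   splits the noise mode near its middle and "foreground" becomes about
   half the frame.  AUTO therefore returns an empty mask when the split
   claims more than 25 % of the pixels *and* the two classes are
   separated by less than 4 pooled standard deviations (Ashman's D).
   Splitting a single Gaussian yields D ≈ 2.7 independent of the noise
   level, while genuine dark populations in this problem are either
   sparse (far below 25 %) or separated by D > 20, so the rule has a wide
   margin on both sides.  A consequence: a handful of particle pixels in
   a megapixel frame (foreground fraction below ~3·10⁻⁴) is below AUTO's
   detection floor, because splitting the noise then carries more
   between-class variance than isolating the particles; a manual
   threshold still works there.

## Particles

Connected components under 8-connectivity (4 is available for
sensitivity analysis) with per-region pixel count, centroid and half-open
bounding box.  Particles smaller than `min_pixels = 2` are discarded by
default — isolated dark pixels at these scales are sensor noise.  Border
particles are kept; residue patterns legitimately reach the frame edge.
The pipeline order is fixed: filter → threshold → size filter → label →
summarize, and every parameter is recorded in the summary's provenance.

## Rater statistics

Visibility scores are ordinal 0–5 (`none_visible` … `substantial`).
Agreement is ICC(3,1) — two-way mixed model, single measures, consistency
— computed from the ANOVA decomposition of the subjects × raters table
with the interaction as error:

    ICC(3,1) = (MS_rows − MS_err) / (MS_rows + (k−1)·MS_err)

Consistency means a rater with a constant offset still agrees perfectly;
the absolute-agreement coefficient ICC(2,1) is available behind a flag.
A constant matrix has no defined ICC (zero variance to apportion) and
raises.  Round-off occasionally pushes a perfect-agreement coefficient a
few ulp above 1; it is clamped to 1.  The agreement bands as commonly
printed overlap at the fair/good boundary (0.4–0.69 fair vs 0.6–0.74
good); the implementation uses half-open bands with the boundary at 0.60:
poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent ≤ 1.

The independent-samples t-test defaults to the pooled-variance Student
form — the usual reading of "independent samples t-test" — with Welch
available via a flag; both are two-sided at α = 0.05.  Two identical
constant samples are reported as t = 0, p = 1 rather than an error.

## Synthetic scenes

The generator is a forward model of the study conditions, not of physics.
Defaults (all in one constants block):

| parameter | default | rationale |
| --- | --- | --- |
| frame | 512 × 512 px | enough bins for the filters, fast to test |
| particle radii | 1–2 px | residues are near the resolution limit |
| particle intensity | 0.05–0.15 | soot is nearly black in VL and IR |
| scatter | isotropic Gaussian, σ = 0.3·min(H,W) | simplest decaying radial density for a close-range cloud |
| white cotton base | 0.85 | bright fabric, both modalities |
| denim base | 0.55 IR / 0.25 VL | encodes "denim brighter in IR" |
| denim twill | 90 cycles/width per axis, amplitude 0.12 | a strong periodic band inside the band-pass stopband (radial ≈ 127) |
| white weave | 128 cycles/width, amplitude 0.02 | fine weave, period 4 px |
| illumination gradient | ~1 cycle, amplitude 0.05 | flash fall-off |
| noise | Gaussian, σ = 0.01 | sensor noise |
| blood | VL wet 0.10 / VL dry 0.15 / IR wet 0.35 / IR dry 0.55 | ordinal facts: blood very dark in VL; dry lighter than wet in IR |

Particle centres are rejection-sampled to the frame, away from the
optional central defect, and (by default) to mutual non-overlap with a
2.2 px clearance between disc boundaries — enough that no two discs share
or 8-touch a pixel, so the ground-truth component count equals the number
planted exactly.  The same seed-derived random streams drive geometry
regardless of modality, so a scene renders under VL and IR with identical
geometry.  Scenes that cannot be packed raise a generation error rather
than silently degrading.

What the generator does **not** emulate: real weave irregularity and
fraying, specular fibres, JPEG artefacts, depth-of-field blur, particle
shape irregularity, intensity overlap between faint residues and dark
fabric regions.  Passing the synthetic suite therefore demonstrates the
correctness of the numerics and the internal consistency of the pipeline
under its own assumptions — not field performance on casework images,
which the original tuning-per-image workflow suggests is materially
harder.

## Validation problem sizes

The test and acceptance runs use: 50 random 8×8 images against a direct
O(N⁴) DFT oracle; 200 random 32×32 masks against a BFS flood fill (both
connectivities); 20 white-cotton scenes at 100–2500 planted particles
(count within ±5 % of truth on every scene); 10 denim scenes at 200
particles (band-pass F1 ≥ 0.9, strictly above the no-filter baseline);
100 random 10×3 rating matrices against an ANOVA sums-of-squares oracle
(agreement to 1e-12).  These sizes keep a full run in seconds while
exercising every code path; they are the package's chosen validation
conditions, not estimates of any study's scale.

## Known limitations

- Touching or overlapping particles merge into one component; no
  watershed splitting is attempted (by design — counts on dense patterns
  under-estimate).
- AUTO thresholding has the sparse-scene detection floor described above.
- The band-pass preset attenuates the smallest particles on denim;
  recovery there is ~93–97 %, not exact.
- Cutoffs assume square pixels; anisotropic sampling would need per-axis
  scaling.
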