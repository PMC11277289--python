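# Methods

This note records the scientific and numerical choices behind
`gammapatch`: the models, the conventions that fix otherwise ambiguous
details, what the synthetic data does and does not emulate, and the known
limitations.

## Spectral estimation and the gamma response

Per-trial power spectra are computed with discrete prolate spheroidal
(Slepian) tapers, averaged over tapers and then over trials. The default
is a single taper with time–bandwidth product 1, appropriate for the short
250 ms analysis windows; the taper count and bandwidth are arguments.
Windows are half-open in samples (`[start, end)`), so 250 ms at the 2 kHz
default sampling rate is exactly 500 samples and the frequency spacing is
4 Hz. Tapers are normalized to unit energy and one-sided spectra scaled so
that summed power equals the taper-weighted signal variance (a sinusoid of
amplitude *a* contributes *a*²/2 of summed band power); band *ratios* are
invariant to this convention, absolute PSD values are not.

The gamma response is the linear ratio of summed stimulus-window
(250–500 ms) to baseline-window (−250–0 ms) power over 30–80 Hz, with band
bins selected by a closed interval on bin centers (30 and 80 Hz bins both
included). High gamma uses 80–150 Hz. Decibel values are provided for
display only; all model fitting operates on linear ratios, because a
product of factors composes naturally on a ratio scale.

## Separability analysis

The separability index si = λ₁²/Σλᵢ² comes from the full SVD of the raw
linear band-ratio matrix. Scaling a matrix does not change si or any
intercept-bearing r², so no area normalization is applied before analysis
(such scaling is a plotting convention only). Singular-vector signs are
fixed by requiring the first left singular vector to have a nonnegative
sum. Three regressions share the same degrees of freedom: vec(M) on
[1, vec(u₁λ₁v₁ᵀ)], vec(M) on [1, vec(FGᵀ)] with F, G the row/column sums,
and vec(M) on the two broadcast marginals with *no* intercept. Note that
the intercept-free sum model cannot absorb the constant `n_cols·mean(G) +
n_rows·mean(F)`, so it is exact for additive matrices only when the
marginals are zero-sum — on positive tuning data it is genuinely the
weaker model, which is the point of the comparison.

Significance of si uses 20 surrogate matrices with i.i.d. normal entries
matched to the data's mean and variance, and a two-sided one-sample
*t* test of the surrogate indices against the observed one (α = 0.05).
This statistic compares a single observation with the surrogate *mean*, so
its null false-positive rate is far above α (empirically ≈ 0.48; the *t*
value is inflated by about √(n_iter+1)). We keep the procedure because it
is the field's convention for this analysis and because in practice the
observed si of separable data sits many surrogate standard deviations from
the null; the anti-conservatism only matters for marginal cases and is
asserted, not hidden, in the test suite.

## Multiplicative tuning models

All single-feature factors are bounded in [0, 1] before gain/offset
scaling: Gaussian and von Mises densities are normalized to peak at 1, and
the size/contrast/saturation terms are unit-gain sigmoids
1/(1+10^(−slope·Δ)) (reading the size, contrast and saturation terms of
the product model as divisions; only this reading makes responses scale
*down* from the full-screen/full-contrast ceiling). Orientation angles are
doubled before the von Mises so the period is 180°; hue keeps a 360°
period. Value is carried in percent and divided by 100 inside the linear
term; values below 25 % are outside the modelled domain and are clamped
with a warning. A zero size or contrast uses the analytic limit of the
log-domain sigmoid (0), which lets zero-contrast protocol rows participate
in the contrast fit with their full design count instead of being
discarded. Full-screen stimuli are encoded as 25 dva, beyond any fitted
size midpoint (configurable).

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`)
with multi-start and tight tolerances; shallow sigmoid slopes and Gaussian
centers beyond the probed grid lie on nearly flat cost ridges where a
single local solve can stall, while the multi-start reliably reaches the
zero-cost solution on noiseless data. Each single-feature curve carries
its own gain A and offset B and is fit on the protocol's full grid pooled
(averaged) across the orthogonal orientation axis — for balanced designs
this has the same least-squares optimum as fitting every grid point, but a
zero cost floor. The reported design sizes are the assembled grids: 40
points (5 SF × 8 orientations) each for the spatial-frequency and
orientation fits, 48 (6 × 8) for size, 28 or 48 for contrast, 48
(36 hues + 6 max-saturation + 6 max-value) for the hue lobes, 7 for the
hue size curve, 30 (6 × 5) for saturation, 24 (4 values × 6 hues) for the
value line. Hue lobe centers start at red (0°) and cyan (180°) and may
move by at most ±80° and ±100°; a true center beyond the bound is pinned
at the bound.

The value line g·V/100 + o has no separate gain, so on product-model data
a naive fit recovers (g, o) only up to the scale contributed by the other
factors. The implementation therefore enters the already-fitted hue,
saturation and size factors as known multipliers in a linear
least-squares solve for (g, o), which pins the absolute scale (and
recovers the parameters exactly on noiseless product data).

Cross-validation splits trials per condition into random halves, fits
shapes on fold-1 averages, and fits gain/offset and records the Pearson
correlation on fold-2 averages, averaged over three iterations. Median
pooling across electrodes uses plain medians, with circular medians
(period 180° for orientation, 360° for hue centers) for angular centers.
The packaged median parameter table stores hue centers in radians (as
published) and converts to degrees on load.

## Image-patch approximation

Ring statistics grow from a 0.3 dva disk in 0.3 dva increments to 2.1 dva.
Hue statistics are circular on the 0–2π radian scale, and the uniformity
thresholds for hue (SD > 0.1, |mean difference from the first disk| >
0.05) are applied on that radian scale for unit consistency; saturation
and value use linear statistics with thresholds 0.2/0.1 and 0.2/0.1. A
crossing must persist for the two subsequent rings; transient crossings
are skipped. Consequently a crossing at one of the last two probe radii
cannot be verified and does not qualify — and a fully uniform region
reports the maximum probed radius, 2.1 dva, since larger uniformity is
simply not measured. The reported radius is the last ring *before* the
persistent crossing (the patch the radius circumscribes is uniform); a
persistent crossing at the first disk reports radius 0, "no uniform
patch". Patch color uses saturation-weighted hue vectors: H = arg Σ s·e^iθ
and S = |Σ s·e^iθ|/N — the pixel-count normalization keeps S in [0, 1] as
the saturation sigmoid requires. When the vectors cancel (S ≈ 0) the hue
is undefined and flagged; the saturation factor then dominates any
downstream prediction regardless of H.

Gabor approximation crops a 14 dva square (edge-replicated if the image is
smaller) around the RF center of the value layer, masks with Gaussians of
σ = 0.3–2.1 dva (zeroed beyond 3σ), and reads the 2-D FFT magnitude in
polar (SF, orientation) form with 24 orientation bins of 7.5° over 180°
and nearest-bin SF annuli. The local mask-weighted mean is subtracted
*before* masking: subtracting a scalar afterwards leaves a copy of the
Gaussian envelope in the spectrum whose low-SF blob (spectral σ ≈ 0.5 cpd
for the smallest mask) can dominate the true carrier peak. Peaks below
0.1 cpd are skipped; peak magnitudes are made comparable across mask sizes
by dividing by the L2 norm of the matched unit-amplitude Gabor; the best
size maximizes that normalized magnitude with higher orientation variance
(OV) breaking ties. Phase is the argument of the complex coefficient at
the peak and contrast is Michelson over the 3σ disk. Accepted Gabors need
SF in 0.4–8 cpd and OV above threshold. OV is the variance across
orientation bins of the annulus magnitudes in the normalized-magnitude
units of this implementation; the default threshold (5.0) was calibrated
once on synthetic full- to 30 %-contrast gratings (OV ≳ 12) versus
isotropic noise and disk edges (OV ≲ 0.1) — published thresholds in other
conventions do not transfer numerically. A qualifying Gabor on a chromatic
region (mean saturation ≥ 0.1 over the mask) is recorded but flagged
non-predictable, since the achromatic grating model does not apply;
otherwise the hue-patch path decides.

## Prediction

Uniform hue patches are evaluated by the hue product model with the pooled
median shape; unmatched patches (R = 0) and non-predictable Gabors predict
exactly 0. Gains and offsets are omitted: Pearson correlation is invariant
to affine rescaling. `r_full` correlates over all images of a set with the
zeros included; `r_sel` uses matched patches only, and a set qualifies for
population summaries at ≥ 8 of 16 matched images. The
gamma-minus-high-gamma variant subtracts the linear high-gamma ratio from
the linear gamma ratio to discount broadband (spiking-related) power
increases. Feature ablations pin unused features to hue 0°, saturation 1,
value 100 % and size 10 dva; the fixed-radius basic model averages H, S, V
over a fixed disk (0.5/1/2 dva defaults) instead of the detected radius.

## Synthetic data: what it emulates and what it does not

Trial generation adds, to 1/f-shaped background noise spanning the whole
−500…+800 ms epoch, a gamma-band sinusoid (52 Hz default) present only
after stimulus onset, with per-trial random phase so the rhythm is induced
rather than evoked and only trial-averaged *power* carries it. Noise is
synthesized on the epoch's frequency grid with deterministic per-bin
amplitudes and random phases, so its expected band power is known in
closed form; the oscillation amplitude is a = √(2·B₀·(ρ−1)) with B₀ the
analytic 30–80 Hz noise power, making the expected stimulus/baseline ratio
equal the product model's scaled response ρ = G·F + O (O defaults to 1,
the no-response ratio; targets below 1 are rejected since no real
oscillation amplitude achieves them). Synthetic images plant hard-edged
uniform disks or sinusoidal gratings (stripe orientation measured
anticlockwise from horizontal with y upward; the wave vector at θ+90°) at
known positions, with 20 px/dva defaults.

Real recordings differ in ways the generator deliberately ignores:
broadband stimulus-locked transients, gamma peak-frequency shifts with
contrast and other features, non-sinusoidal and bursty gamma, electrode
noise correlations, and natural images' soft edges and mixed textures.
Passing tests therefore validate the *analysis chain* — that each stage
recovers what was planted under its own model assumptions — not that the
model captures all of cortical physiology.

Parameter-recovery validation uses representative ground-truth shapes
(`RECOVERY_GRATING_SHAPE`, `RECOVERY_HUE_SHAPE`) whose centers and
midpoints sit near the published medians but whose SF center, spreads and
slopes lie in the range the protocol grids can identify. This screening is
deliberate: a Gaussian peaking beyond the probed 0.5–8 cpd grid, or a
value slope near 0, is unidentifiable from those grids at any noise level,
so "recovery" against such a truth would be meaningless. Noisy recovery
simulates per-trial noise with SD equal to 10 % of the grid's dynamic
range and 100 trials per condition (grids are trial averages); at the
lower per-protocol trial counts typical of awake recordings the
Cramér–Rao bound for sigmoid slopes already exceeds the 15 % recovery
tolerance, which is a statement about those designs, not about the
estimator — the fitted estimator empirically attains the bound.

## Conventions and degenerate inputs

Pixel coordinates are 0-based (row, col); azimuth increases rightward,
elevation upward, so an RF at (az, el) dva maps to pixel
fixation + (−el, +az)·ppd, rounded to nearest. Pixels-per-degree is a
required configuration value (20 px/dva for synthetic fixtures). Grayscale
images use the same HSV container with hue = saturation = 0. All-zero
matrices, zero baseline band power, zero-variance regressions and
zero-variance bootstrap inputs raise `DegenerateInputError`; precondition
violations raise `ValidationError`; non-convergent curve fits are flagged
on the returned record rather than raised. All generators and fits are
deterministic given their seeds.

## Known limitations

* The multiplicative model is a baseline: it ignores peak-frequency
  structure, luminance changes between background and stimulus, and
  chromatic gratings (hue × contrast interactions), and HSV "value" maps
  to different luminances for different hues.
* Uniform-patch detection reports at most 2.1 dva and cannot certify
  crossings at the last two probe radii; radius estimates are quantized to
  0.3 dva.
* The bootstrap significance test is anti-conservative under the null (see
  above).
* Absolute PSD values depend on the taper convention; only band ratios are
  comparable across implementations.
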