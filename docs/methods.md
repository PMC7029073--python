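# Methods

This note records the models implemented by `camoquant`, the parameters
that matter, the deliberate choices made where the underlying methods are
conventionally under-specified, and what the synthetic-scene validation
does and does not establish about real photographs.

## Reflectance calibration

Inputs are assumed to be *linear* RGB images (demosaiced raw exports or
synthetic renders); gamma-encoded consumer JPEGs are out of scope, as is
raw (CR2) decoding itself. Each photograph carries gray-standard patches
of known diffuse reflectance. Calibration fits, per channel, the
least-squares line from measured patch means to `reflectance × 65535`;
with exactly two standards this reduces to two-point normalization. The
affine (gain + offset) model absorbs both illumination differences and a
constant black-level; values are clipped — not wrapped — to [0, 65535],
matching field practice where exposure is chosen to avoid clipping in the
first place. Resampling to the working resolution (default 17 px/mm) is
bilinear, with a Gaussian anti-aliasing prefilter when downsampling.

## Granularity analysis

The pattern channel is the pixelwise mean of R and G. The default filter
bank has 15 sizes, 2 → 256 px in multiples of √2. Band-pass filtering is
an ideal (hard-edged) isotropic annulus in the Fourier domain; pixels
outside the analysis region are filled with the region mean before the
FFT (mean-fill, not zero-fill, to suppress boundary ringing), and the
energy of a band is the *population SD of the band-filtered values over
region pixels only*.

Band edges sit at the geometric midpoints between neighbouring sizes
(half a √2 step), so band `s` passes spatial periods `[s/g, s·g)` with
`g = 2^(1/4)`. Two boundary choices make the bank an exact partition of
all non-DC frequencies: the smallest-size band keeps everything above its
lower period edge out to the grid's corner frequencies (a literal period
cutoff at `2/g` px would orphan the corner region of the square spectrum,
about 5% of white-noise power), and the largest band extends to period
`256·g`. Exactness is what makes the Parseval property assertable: on a
fully masked grid the band variances sum to the total variance to
rounding error, and to within ~5% on masked sub-regions.

Descriptors: `e_max = max(energies)`; `Filter_max` is the size at the
maximum, ties broken toward the *smallest* size; `e_prop = e_max / Σ
energies ∈ (0, 1]`. A constant region has an all-zero spectrum and no
defined descriptors (an error, mirroring the exclusion of unusable
images from real analyses). Group statistics use log10 transforms of all
three descriptors; raw values are always retained in the output.

## GabRat

The outline is every 8-connected boundary pixel of the (single,
connected) target mask. The tangent at a boundary pixel is perpendicular
to the gradient of the Gaussian-smoothed (σ = 2 px) mask indicator —
orientation comes from the *mask*, not the image, so internal false edges
cannot corrupt the outline estimate. At each outline pixel a quadrature
pair (even + odd) of Gabor filters with envelope σ (default 5 px,
appropriate for ~17 px/mm imagery), wavelength λ = 2σ, and aspect ratio 1
is evaluated at two orientations: carrier across the boundary (coherent)
and carrier along it (false). Energy is √(even² + odd²); the even filter
is DC-corrected, making the metric exactly invariant to global affine
intensity changes. GabRat per channel is the outline mean of
`E_false / (E_false + E_coh)`; the reported value averages R, G, B.

Numerical choices: outline pixels whose total quadrature energy falls
below `1e-9 × (1 + max |channel|)` are *skipped* rather than scored 0 or
0.5 (a flat scene has no edge evidence either way); the number skipped is
reported. Only the single perpendicular orientation is used for false
energy, not a maximum over many orientations. Filters near the image
border use reflect padding.

Note that GabRat conflates two sources of "false" energy: genuine
boundary-crossing elements and any internal/background texture at the
filter scale. A perfectly background-matching target with *no* luminance
step at its outline has weak coherent energy everywhere and GabRat ≈ 0.5
regardless of markings; the metric discriminates disruption best when the
target is discriminable at all. The monotonicity validation therefore
runs on scenes with a nonzero mean offset.

## Background matching

Per-individual channel means are taken over the dorsal mask and an
adjacent equal-area background annulus. Across a species × sex group the
animal mean is regressed on the background mean per channel with a
major-axis (Type II) fit: β is the direction of the leading eigenvector
of the 2×2 sample covariance matrix — appropriate because both variables
carry error on the same scale. `r²` is the squared Pearson correlation.

The slope test at b0 computes the correlation r_s between residual
scores `y − b0·x` and axis scores `x + b0·y` (zero exactly at the fitted
slope, by eigenvector orthogonality) and refers
`t = r_s·√(df/(1 − r_s²))`, df = n − 2, to a t distribution. Confidence
limits for β invert this test in *angle* space (slope = tan θ), which
handles steep slopes gracefully and makes "the 95% CI covers b0" exactly
equivalent to "the slope test at b0 is not significant at α = 0.05". If
even the least-favourable direction cannot be rejected, the interval is
the whole line (±∞). Perfectly collinear data use the degenerate
convention r_s = 0, p = 1 (matching cannot be rejected). Slope tests are
computed for every group but flagged as "reported" only where the
regression correlation itself is significant, the conventional reporting
rule; the verdicts are `matching` / `mismatch` / `no_association`.

## Group statistics

ANOVAs are two-factor with interaction, Type III sums of squares under
sum-to-zero contrasts (the choice that keeps main effects interpretable
in unbalanced field cohorts), computed via statsmodels. The MANOVA
reports Wilks' λ = det(E)/det(E+H) per Type III term; with one
hypothesis df per term, `F = (1 − λ)/λ · (v − p + 1)/p` is exact, not an
approximation. Tukey–Kramer HSD uses the studentized-range distribution
with the pooled within-cell error — identical to the two-way-with-
interaction error term for a 2×2 layout — and a compact-letter display
built from maximal cliques of the non-significance graph. Paired t tests
compare dorsal vs background descriptors per individual; zero-variance
differences are a degenerate-design error at the API level and reported
as NaN rows by the pipeline.

## Synthetic scenes

A scene is: band-limited Gaussian background texture (controllable
dominant period and contrast), an elliptical target filled with
transverse sinusoidal bands (dominant period = marking size, SD =
marking contrast, plus `k − 1` weaker √2-spaced components driving
pattern diversity down as k grows), boundary-crossing "disruptive"
spokes (radial gratings, phase-continuous across the outline and
windowed to a ±5 px band around it, amplitude ∝ the disruption
parameter d ∈ [0, 1]), gray standards rendered through a known
per-channel calibration line, and additive Gaussian sensor noise applied
on the raw (pre-calibration) scale. The background texture is centred on
the measurement annulus and the target texture on the target mask, so
rendered region means equal their nominal values exactly before noise.
The default scene is 192² px at 17 px/mm with a 110 × 60 px target —
deliberately smaller than a field photograph so that whole-cohort
simulations remain cheap; the granularity-recovery checks at 32-px
periods use 256² scenes with a larger target so several marking cycles
fit the region.

Cohorts are two crossed factors (species × sex) with per-cell parameter
distributions; per-individual seeds are split from one master seed via
`SeedSequence(master, spawn_key=(cell, index))`, so generation is
deterministic and order-independent. Background-matching structure uses
a latent-variable model: microhabitat brightness L per individual, with
`background = base + a_c(L + e_x)` and `animal = base + a_c(slope_c·L +
e_y)`. With slope 1 and equal jitter variances this is the exact
symmetric errors-in-both-variables null of the MA slope test. Female
matching jitter is drawn once per individual and shared across channels
(achromatic brightness matching — the biologically natural reading of
overall color matching, and the reason female channel CIs behave as one
event rather than three independent ones); the male deficit is
channel-specific (R slope 0.2 with independent jitter).

The `paper_mimic_cohort` preset encodes the qualitative field pattern:
164 individuals (35/44/42/43 per cell); males with higher marking
contrast, more band components, disruption ≈ 0.65–0.70 vs ≈ 0.10 for
females, and the R-channel matching deficit; one "species" on a more
homogeneous, lower-contrast background than the other.

**What passing tests do not show.** Synthetic backgrounds are Gaussian
textures, not vegetation; targets are ellipses with sinusoidal bands,
not grasshoppers; illumination is uniform; sensor noise is additive
white Gaussian. Recovery of ground truth here validates the *measurement
chain* — calibration, spectra, GabRat, regression, statistics — not the
ecological conclusions one would draw from real photographs, and
absolute descriptor values (e.g. GabRat magnitudes) are not comparable
between synthetic and field imagery.

## Validation problem sizes

The test-suite simulations use: 100 randomized scenes for the GabRat
bound; 40 scenes (4 periods × 10 seeds) for `Filter_max` recovery and 50
for the `e_max`-vs-contrast monotonicity (Spearman ρ > 0.95); 500
replicates (n = 40) for the MA slope-test null; 1,000 replicates for the
ANOVA/paired-t type-I error (±0.02 of nominal); 200 replicates for MANOVA
null-p uniformity; and 20 master seeds of the full 164-individual mimic
cohort (GabRat + matching measurements) for the qualitative sex/species
contrasts. A note on that last check: each female per-species CI-covers-1
event has exactly nominal 95% probability under the generator's null, so
the two-species joint event holds in ~90% of seeds in expectation — the
check is intrinsically near its own threshold, which is a property of
nominal confidence coverage, not of the implementation.

## Known limitations

- Visible spectrum only; no UV channel, no camera spectral-sensitivity or
  predator vision modelling, no vignetting correction.
- Granularity is isotropic; orientation-resolved pattern analysis is out
  of scope.
- GabRat uses one false-edge orientation (perpendicular), σ fixed per run.
- The MA confidence construction inverts the r_s test; other published
  CI constructions differ slightly in small samples.
- Mixed models, non-parametric alternatives, and just-noticeable-
  difference (receiver-dependent) matching metrics are not provided.
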