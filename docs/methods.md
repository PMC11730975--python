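# Methods

This note records the modelling conventions, default parameters, and
design choices behind the package, and what the synthetic data do and do
not establish.

## Calibration and luminance conventions

Images are dimensionless luminance in [0, 1] with 0.5 mid-gray; physical
cd/m² are metadata only. Spatial frequency is always in cycles per degree
and converted through a pixels-per-degree (ppd) calibration carried on
every `ImageStimulus`; no estimator hard-codes a display. The default ppd
(≈ 40.6) is derived in `config.py` from the study display geometry
(1024×768 on a 22″ 4:3 monitor at 1 m). The Gaussian-edged presentation
window (flat radius 150 px, σ = 10 px) yields a visible field of roughly
7.3° at that calibration.

## Stimulus generators

**Bump noise.** The band-pass filter is a raised-cosine window in
ν = log₂(f/f₀): gain 1 for |ν| ≤ (1−β)/(2T), half-cosine roll-off to zero
at |ν| = (1+β)/(2T), with T = 0.9 and β = 0.5 (flat over ±0.28 octaves,
support out to ±0.83 octaves). The exact analytic form used in the
original construction is not recoverable from the available text, so this
standard raised-cosine reading is a documented assumption. White Gaussian
noise is shaped in the frequency domain and rescaled into [0, 1] by
max-|deviation| normalisation, which is linear and therefore leaves the
spectral shape intact (only DC moves): out-of-support energy is numerical
leakage only (< 1%). Because the passband is flat over ±0.28 octaves, the
radially averaged spectrum of a single realisation peaks somewhere inside
the passband — not necessarily within one frequency bin of f₀ — and the
tests assert exactly that.

**1/fᵏ noise.** Amplitudes are set deterministically to fᵏ and only the
phases are random, so the construction is an exact oracle for the slope
estimator. Exponents are accepted in [−3, 1]; natural images live near
k = −1.

**Stripe textures.** High-contrast square-wave stripes with an optional
sinusoidal bend stand in for op-art works; they are labelled surrogates,
not reproductions of any artwork. Note that a *sampled* square wave at an
off-grid frequency is not exactly periodic (edge-position jitter adds
broadband energy), so unlike pure gratings these may retain a defined —
if noisy — spectral slope.

**Temporal envelope.** A raised sinusoid 0.5(1 − cos 2πrt) in [0, 1] at
r = 5 Hz: the stimulus fades in and out of mid-gray, so space-average
luminance is constant over time. Whether the original presentation ramped
contrast monotonically within each cycle or counter-phased is not
determinable from the text; the raised sinusoid is the documented choice
(20 s at 60 Hz = 1200 frames = exactly 100 cycles).

**Synthetic ratings.** rating = intercept + Xβ + observer intercept +
noise, clipped to [1, 7]. Rounding to integer Likert points is available
(`discretize=True`) but off by default: the continuous clipped scale
keeps the zero-noise case an exact linear system, which the recovery
tests exploit; rounding adds quantisation noise the fitted model does not
represent. Defaults (11 observers, observer SD 0.5, residual SD
0.8–1.0 on a 7-point scale) are chosen to mimic the between/within
spread typical of discomfort rating studies.

**Synthetic EEG.** One 20 s trial per condition at 256 Hz on a 16-channel
montage (the nine posterior channels of interest, linked mastoids, five
midline/frontal sites). Posterior channels carry a·sin(2π·5t) plus a
harmonic at 10 Hz (amplitude ratio 0.25); all channels carry independent
1/f-power background noise (amplitude ∝ f^−½, flattened below 0.5 Hz).
Artifact injection adds a 1 s ±600 μV 10 Hz burst centred in a chosen 2 s
sub-epoch, on every channel except the mastoids — a common-mode pulse
would be removed by re-referencing, and an out-of-band pulse by the
band-pass — so exactly the targeted sub-epochs exceed the ±500 μV
rejection threshold.

## V1 population model

Cells are log-Gabor filters: Gaussian in ln f (bandwidth 1.2 octaves
FWHM), Gaussian in orientation with the **half-width-at-half-height**
convention for the 16–17° orientation bandwidth, zero DC gain, quadrature
phase via a single-sided (analytic) angular profile. Tuning distributions
are parametric approximations — the physiological sources give shapes,
not parameters: peak frequency log-normal (median 2.2 c/deg, ln-SD 0.8)
truncated to 0.5–16 c/deg; orientation a cardinal-biased mixture (35%
wrapped normal at vertical, 25% at horizontal, SD 20°, 40% uniform);
phase a wrapped-normal mixture at 0°/180° (SD 30°). All are overridable
through `distribution_params`, and the orientation mixture exposes its
analytic CDF for distributional tests.

Filters are normalised to **unit peak gain** by default. Unit-L2
normalisation is available (`normalize='l2'`) but is not the default
because the L2-normalised peak gain scales like 1/√(f₀·bandwidth): a cell
tuned slightly below a grating's frequency then out-responds the matched
cell, breaking the basic tuning contract ("the cell tuned to the stimulus
responds most"). With unit peak gain that contract is exact.

An image is converted to Weber contrast (pixels − mean)/mean; each cell's
response is the mean over pixels of the half-wave-rectified filter output
at the cell's phase (an energy/squared aggregation is available via
`aggregation='energy'`). Rectified-mean aggregation is positively
homogeneous, so scaling contrast by c scales the total by exactly c and
leaves kurtosis unchanged. Adding a constant luminance rescales all
responses by mean/(mean + δ) — Weber contrast is a ratio — so the
response *pattern* and kurtosis are luminance-invariant while the total
carries the Weber scaling; this is the intended behaviour of a
contrast-coding front end. Kurtosis is the non-excess sample kurtosis
(≥ 1 for any non-degenerate vector); the all-zero response to a uniform
image has undefined kurtosis and is returned as NaN, not an error.
Whether the original "total model output" summed rectified responses,
absolute values, or energies is not stated; rectified-mean with
total = Σ cells is the documented default.

## Image statistics

**Spectral slope.** First-order polynomial fit of log mean amplitude
against log frequency over integer-radius annuli of the 2-D amplitude
spectrum, DC and super-Nyquist bins excluded. Radial averaging before the
fit is the standard, anisotropy-robust choice. Validity: periodic
stimuli have no meaningful slope. The concentration test is run on a
Hann-windowed copy of the image (an off-grid sinusoid leaks amplitude
across many radial bins of the raw spectrum, which would defeat a raw
single-bin criterion); if the top three radial bins hold more than half
the non-DC amplitude the image is flagged periodic and the slope is NaN.
This flags all grating variants (windowed or not) while passing every
noise class down to k = −2. No low-frequency cutoff is applied beyond DC
removal.

**Fractal dimension.** Rescale to 8-bit, posterize at 128 (ties — values
exactly 128 — are foreground), zero-pad to the smallest power of two not
below the longest side (300 px → 2⁹ = 512), count occupied boxes at every
power-of-2 size, local slopes Δlog n/Δlog r between consecutive sizes.
D is minus the mean local slope over the longest plateau of ≥ 3
consecutive slopes agreeing within 0.1; if no plateau exists a global
log-log fit is used and flagged (`fractal_global_fit`). Exact rasters
give exact answers: a filled plane yields slopes of −2 everywhere
(D = 2), a one-pixel line −1 (D = 1), the bitwise-AND Sierpinski raster
−log₂3 (D = 1.585).

**Contrast.** RMS contrast is σ/μ of luminance. CSF-filtered contrast
weights the Weber-contrast spectrum by the Mannos–Sakrison sensitivity
(peak ≈ 8 c/deg), zeroes everything above 60 c/deg and DC, and takes the
RMS of the filtered image; it is bounded by max A(f) times the RMS
contrast and is zero iff the image is constant.

**Edges and entropy.** The image is resized to ≤ 340 px on its longest
side and convolved with 24 odd-symmetric Gabor kernels (σ = 1.669 px,
orientations 0–π). The sine-carrier wavelength is not recoverable from
the available description; the default 2πσ ≈ 10.5 px makes each kernel an
odd, derivative-of-Gaussian-like edge detector and is exposed in
`EdgeExtractionConfig`. Per pixel the orientation is the filter with the
largest |response| and the intensity that magnitude; the response sign
recovers contrast polarity, extending orientation to 0–360° (a 180°
rotation reverses polarity). A 15 px border is discarded and the 10,000
strongest strictly-positive responses retained (ties broken by raster
order for determinism).

First-order entropy is the Shannon entropy (bits) of the
intensity-weighted 24-bin orientation histogram. Second-order entropy
enumerates unordered distinct edge pairs; each pair deposits its
intensity product twice — once from each member's viewpoint, under
(distance bin, signed orientation difference of the other edge, own
orientation section) — making the histogram independent of edge ordering.
Distances use 500 bins up to the bounding-box diagonal; orientation
differences use 48 bins over 0–360°. Within each occupied (d, α) cell the
24-section histogram is normalised (an even spread gives exactly 1/24 per
section) and the cell entropies are averaged. Both entropies are bounded
by log₂24 ≈ 4.585 bits. The full 10,000-edge case (~5×10⁷ pairs) is
accumulated in blocks of 256 rows via flat `bincount`s; a naive O(n²)
oracle in the test suite pins the definition exactly.

## SSVEP chain

Re-referencing subtracts the mean of M1/M2 from every channel. The
band-pass is a zero-phase forward-backward 8th-order Butterworth
(0.1–40 Hz); the order is a package choice (the filter design is not
specified in the source description) set so that 50 Hz line noise is
attenuated by > 20 dB. Resampling uses polyphase filtering to 256 Hz with
event indices rescaled. Epoching: 20 s from stimulus onset, minus the
mean of the 1 s pre-stimulus baseline; ten 2 s sub-epochs, the first
discarded as an onset transient; any sub-epoch exceeding ±500 μV on an
analysed channel is rejected, with exact bookkeeping (kept + rejected =
9 per clean trial).

Welch PSD: each 2 s sub-epoch is one segment (512 samples at 256 Hz,
0 overlap → 0.5 Hz bins, so 5 and 10 Hz fall exactly on bins), boxcar
taper, density scaling, averaged over sub-epochs. The boxcar is chosen
because the stimulation frequencies are bin-aligned by design: a tone of
amplitude a then contributes a²/2 of integrated power to a single bin,
making `amplitude_estimate(power) = √(2·P·Δf)` exact for clean input.
The SSVEP is read at the exact 5/10 Hz bins (not a local-maximum search —
the grid guarantees alignment) and averaged over the nine posterior
channels. Bad-channel detection/interpolation and ocular correction are
not implemented: the synthetic recordings contain no bad channels or
ocular artifacts unless injected, and injected artifacts are handled by
the amplitude rejection.

## Statistical modelling

PCA operates on the correlation matrix (variables are z-scored; they
carry incommensurate units), eigen-decomposition via `numpy.linalg.eigh`,
components signed so their largest-|loading| variable is positive,
Kaiser retention (eigenvalue > 1) reported with explicit overrides
allowed (mirroring analyses that retain a third component on model-build
grounds). Rows with an undefined slope (gratings) drop out of the PCA
input but remain in every contrast-only model.

Mixed models use statsmodels MixedLM (REML; L-BFGS with Powell/BFGS
fallback) with an observer random intercept and optional random slope;
the package contract is the model structure and reporting (coefficients,
SEs, 95% Wald CIs, variance components, marginal R² = fixed-effect
variance over total), not a bespoke optimizer. An exactly-linear response
(zero residual variance) makes a mixed model singular; it is detected and
reported as an OLS fit with a `degenerate_zero_residual` diagnostic
rather than a silently degenerate variance estimate. Spatial-frequency
tuning is fitted with linear + quadratic terms in log₂ frequency — the
stimulus grids are geometric (0.75–9 c/deg in octave steps), under which
a quadratic is symmetric around its vertex −b/(2a), reported back in
c/deg. Likert ratings are treated as numeric; an ordinal re-analysis is
out of scope. No multiple-testing correction is applied, and the report
footer says so.

## The synthetic study and problem sizes

`run_full_synthetic_study` chains every stage and writes report CSVs with
a fixed float format; all randomness derives from the master seed through
`numpy.random.SeedSequence`, so repeated runs are byte-identical. The
default study configuration uses 128 px images at 16 px/deg, 200 model
cells, and 1,500 retained edges — deliberately modest sizes that keep a
full run under ten seconds while exercising every code path; the
`analysis/` scripts run the same pipeline at 256 px/500 cells/3,000
edges, and every size is configuration, not estimator defaults.

## What passing tests show — and what they do not

The generators emulate the *statistical structure* the estimators target:
power-law spectra, band-pass spectra, known mixed-model coefficients,
bin-aligned SSVEP tones over 1/f noise. Passing tests therefore establish
estimator correctness and end-to-end recovery of known ground truth. They
do not establish anything about real artworks, photographs, human
ratings, or recorded EEG: real images have phase structure (edges,
objects) that 1/fᵏ noise lacks; real EEG has non-stationary, spatially
correlated noise, ocular artifacts, and inter-individual variability that
the synthetic montage does not model; and the true rating process is
ordinal and context-dependent. Headline quantities from the original
human study (regression coefficients, variance shares, category means)
depend on those non-redistributable data and are not reproduced here.

## Known limitations

* The bump filter, Gabor carrier wavelength, "total model output"
  aggregation, and first-order entropy weighting follow documented
  readings of under-specified descriptions; each is switchable where an
  alternative is plausible.
* The spectral-slope estimator assumes approximate isotropy; strongly
  oriented broadband images yield a slope of the orientation-average.
* Box-counting D on grayscale images characterises the posterized set,
  and is near 2 for most windowed noise (the foreground is space-filling);
  its discriminative power lives on sparse structures.
* MixedLM Wald CIs slightly under-cover at 11 groups (measured ≈ 92–94%
  at the study scale); the acceptance threshold (≥ 90%) accounts for
  this.
* EDF import and scalp interpolation are not implemented; recordings
  enter as in-memory `EEGRecording` containers.
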