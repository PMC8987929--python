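# Methods

`fuskit` analyzes 2D+t functional ultrasound (fUS) acquisitions: Power
Doppler movies of one coronal brain slice whose per-pixel intensity is taken
as proportional to cerebral blood volume (CBV).  Because no public dataset of
this kind exists, the package ships a synthetic-data generator whose outputs
carry known ground truth, and every analysis stage is validated against that
ground truth.  This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic validation does and
does not establish about real data.

## Synthetic acquisition model

**Phantom.** One coronal slice on a pixel grid (default 64×64 at 0.1 mm/px):
an elliptical brain mask, a lognormal smooth tissue field (`baseline_intensity`
× exp(0.25·G) with G a heavily smoothed standard-normal field), and bright
vessel speckle — a `vessel_density` fraction of brain pixels boosted by a
uniform 2–6× factor.  Eight named elliptical ROIs (visual cortex subdivisions,
superior colliculus, pretectum, hippocampus CA1, thalamus, retrosplenial
cortex) form the synthetic atlas; by construction it is in template space, so
no atlas coregistration step exists.  With `vessel_density = 0` the baseline
equals its smooth component exactly, a useful degenerate case for tests.

**Resting runs.** The signal model is multiplicative:

    pd(t, p) = baseline(p) · (1 + a·s_r(p)(t) + σ·ε(t, p))

where `s_r` is the latent fluctuation shared by all pixels of region r
(fraction `a = fluct_amp`, default 0.02 of baseline), and ε is white
per-pixel measurement noise (`noise_sd`, default 0.01 of baseline).  Latents
are Gaussian noise band-passed to 0.01–0.08 Hz — the band in which regional
homogeneity and fALFF are later evaluated, which makes their local-
connectivity ground truth analytic — then QR-orthonormalized so their sample
correlation is exactly the identity.  Programmed pairwise correlations are
realized by mixing with L where L·Lᵀ = R′ and R′ is the target matrix
compensated for the attenuation a_i = a/√(a² + σ²/n_i) that ROI-averaged
white noise induces on an n_i-pixel ROI mean; the expected ROI-mean Pearson r
then equals the programmed value.  Non-positive-semidefinite targets are
rejected naming the most suspect pair.  Because the latents live strictly
inside the connectivity band-pass (0.00067–0.13 Hz), the later filtering
leaves the programmed structure intact; the default amplitude/noise/ROI sizes
keep the compensation below 0.01 in r.

**Stimulation runs.** The same multiplicative model with region responses
`(amplitude %, shape)` locked to the block design.  Shapes:

* `sustained` — a boxcar of height 1 over the stimulation window.  (A
  convolved onset ramp was considered, but a boxcar keeps the programmed
  stimulation-window mean exactly equal to the programmed amplitude, which is
  the property the recovery tests need.)
* `initial-peak` — gamma-variate (t/t_p)^α e^{α(1−t/t_p)} with α = 3 and mode
  `peak_time` (default 6 s) after onset: an early transient that decays
  during the block.
* `late-peak` — same family with α = 8 and mode `late_peak_delay` (default
  5 s) after stimulation offset; the larger α makes it decay before the next
  block.

The generator records per-region ground truth (stimulation-window mean %CBV
and time-to-maximum on the frame grid) alongside the movie.  Note one honest
consequence of rest-normalization: a late-peak response extends well into the
rest window, so the rest baseline is biased upward and the measured
stimulation-window %CBV of such regions can even turn slightly negative.
This is a property of the analysis definition, not a bug, and the default
baseline therefore excludes the 5 s immediately after each offset.

**Compound stacks.** Tissue clutter is an exactly rank-1 space×time product
(smooth spatial pattern × slowly modulated amplitude, default 100× the blood
amplitude ≈ 40 dB); blood is confined to vessel pixels, white in time, with
per-vessel strengths uniform in [0.5, 1.5].  The realized blood-power image
(temporal mean square of the blood component) is returned for filter
validation.  No acoustics are simulated: the stack models the statistical
structure the SVD clutter filter assumes (low-rank coherent tissue vs
fast-decorrelating blood), nothing else.

**Misalignment.** Inter-acquisition motion is injected as rigid transforms
(≤ 3 px translation, ≤ 2° rotation, uniform), applied identically to all
frames of an acquisition.

## Power Doppler formation

The movie stack is reshaped to its (pixels × time) Casorati matrix and the
`rank_cut` leading singular components are removed; the Power Doppler image
is the per-pixel temporal mean squared magnitude.  Orthogonality of singular
components gives exact energy bookkeeping (‖X‖² = ‖filtered‖² + ‖clutter‖²),
asserted in tests.  No published cutoff exists for this instrument class;
the generic default ceil(0.1·n_frames) is deliberately conservative for real
data, while the pipeline's synthetic runs use `rank_cut = 5`, a small margin
above the rank-1 tissue model they are known to contain.  The rank sweep in
`analysis/02_doppler_formation.py` shows the trade-off directly: rank 0
leaves tissue dominating (r ≈ 0 with the true blood map), rank 1–5 recovers
it almost perfectly, and large cuts begin discarding blood signal (white in
time, hence spread across all components).

## Registration

Groupwise alignment follows iterative template construction: mean image →
linear registration of every acquisition onto it → new mean, iterating until
the mean absolute difference between successive templates falls below `tol`
(default 1e-3 of the dynamic range; below that, vessel-speckled Doppler
images only jitter at the sub-pixel interpolation noise floor, so a tighter
tolerance never triggers).  The linear stage is a full 2D affine maximizing
normalized cross-correlation, initialized by sub-pixel phase correlation and
refined multi-resolution; non-linear refinement uses diffeomorphic Demons
with Gaussian field smoothing (σ = 1 px) and aborts with diagnostics if the
post-warp similarity drops more than 10%.  Registration is estimated on
SVD-denoised temporal means and applied to the original frames (linear
interpolation during optimization, cubic B-spline for final resampling,
nearest-neighbor for labels).

Two caveats worth stating plainly.  First, the common space of a template is
defined only up to a global transform, so recovered per-acquisition motion is
evaluated after removing the cohort-mean offset.  Second, truncating the
temporal SVD of a movie and then taking the temporal mean leaves the mean
essentially unchanged whenever the dominant temporal component is
near-constant (the trailing temporal singular vectors are then near-orthogonal
to the constant vector); the denoising is kept because it is cheap and
robustifies the optimization inputs, but it should not be expected to lower
the RMSE of the mean image itself, and the tests assert what actually holds.

Resampled pixels whose interpolation footprint touches out-of-frame or
previously invalidated pixels are marked invalid (NaN + mask removal).
Invalid inputs are filled from their nearest valid neighbor before warping
because the B-spline prefilter is an IIR recursion whose tail would otherwise
carry an artificial intensity cliff far into the frame.

## Temporal filtering and smoothing

Three band settings, all zero-phase:

| preset | band | use |
|---|---|---|
| `stim` | 0.0025 Hz high-pass + Gaussian low-pass, half power at 0.0375 Hz | stimulation runs |
| `fc` | 0.00067–0.13 Hz | long-range connectivity |
| `reho` | 0.01–0.08 Hz | ReHo/fALFF band (spectral-domain only) |

Butterworth edges are 4th order run forward–backward (`sosfiltfilt`); the
Gaussian low-pass is a real frequency-domain gain exp(−ln2/2·(f/f_c)²) on a
reflect-padded record, which places exactly half power at the cutoff.  The
filter order and type for the Butterworth edges are this package's defaults —
only the cutoffs are externally specified.  One consequence users should
expect: the 0.0375 Hz low-pass attenuates the harmonics of a 30 s boxcar
response, so pipeline-recovered block means sit some 10–15% below the
programmed amplitude; the recovery benchmarks that check amplitude ground
truth therefore quantify %CBV on the unsmoothed data.

Spatial smoothing (0.3 mm FWHM default) is a mask-aware normalized
convolution followed by restoration of the in-mask mean — smoothing trades
variance for local bias but is not allowed to move the map's DC level, which
also makes the mean-conservation contract exact.  FWHM below 0.1 px passes
through with a warning.

## Visual-response quantification

%CBV = 100·(s − baseline)/baseline with the baseline the mean over rest
frames excluding 5 s post-offset.  Per-ROI means over the stimulation frames,
onset-locked five-block averages (default post-window 15 s, where late peaks
live), pixel-wise Tmax as the argmax of the block-averaged response (ties →
earliest frame; computed on the five-block average, matching a single map of
mean time-to-maximum — a per-block-then-average variant would be a config
change), and activation maps as one-sample t across animals of (stimulation
mean − rest mean), converted to Z by probability matching and thresholded
two-sided at p < 0.001.  Zero-variance pixels are excluded rather than
producing infinite statistics.

## Long-range connectivity

ROI mean time-courses from `fc`-filtered movies; interleaved slices are
synchronized by shifting slice 2 by its 1.4 s lag and linearly
re-interpolating onto slice-1 timestamps (linear is adequate: the band of
interest ends at 0.13 Hz, far below the 0.179 Hz Nyquist of 2.8 s sampling).
Pearson matrices use frames after discarding the first minute, with exact
symmetry enforced and constant series invalidated rather than propagated;
Fisher Z = atanh(r) with |r| clipped at 1−1e-7.  Group statistics run on
Fisher-Z values, displayed group matrices are back-transformed mean r.  The
default joint matrix spans both slices (cross-slice pairs on synchronized
series, within-slice pairs on native grids); per-slice analysis is available
by filtering the ROI list.

## Local connectivity (ReHo, fALFF)

Coherence between two series is computed from Welch estimates (Hann window,
default 64 samples, 50% overlap, per-segment linear detrend) as

    Coh = |⟨S_xy⟩_band|² / (⟨S_xx⟩_band · ⟨S_yy⟩_band),

with ⟨·⟩ the average over frequency bins inside 0.01–0.08 Hz (inclusive
edges).  The alternative reading that averages |S_xy(f)|²/(S_xx S_yy)
per bin is available via `pointwise=True`.  ReHo assigns to each pixel the
mean coherence over all 36 unordered pairs of its 3×3 cluster; at mask edges
the cluster truncates to valid members, and centers with fewer than 3 valid
cluster pixels are masked out.  The vectorized implementation reproduces
per-pair `scipy.signal.csd`/`welch` coherences to 1e-10 (this is an
acceptance-tested oracle equivalence, not an approximation).  Maps are
Z-scored over the brain mask (population SD); group maps smooth each
animal's Z map (0.3 mm FWHM) and apply the same one-sample t → Z → p < 0.001
machinery as activation maps.

fALFF is the ratio of the amplitude spectrum (|rFFT| of the demeaned series)
summed over 0.01–0.08 Hz to the sum over all positive frequencies, DC
excluded.  No Welch averaging is used for fALFF — it is a spectral fraction,
not a density estimate — so a pure tone off the FFT grid leaks amplitude and
sits below 1; tests use grid-aligned tones where exactness matters.

## Group statistics

Two-way ANOVA with factors group × region uses Type-II sums of squares
(robust to the unbalanced cohorts, 7 vs 9 animals, this design anticipates),
flagging zero-error-variance layouts as degenerate instead of emitting
infinite F.  Follow-up per-region two-sample contrasts are corrected with
Benjamini–Hochberg FDR at q = 0.1, applied separately per analysis family
(%CBV, Fisher-Z connectivity, ReHo Z).  Time-course comparisons use a
group × time mixed-design repeated-measures ANOVA with per-timepoint
contrasts at the Sidak-adjusted level 1−(1−α)^(1/m).  t → Z conversion is
probability matching, Z = Φ⁻¹(F_t(t; df)), evaluated through whichever tail
keeps floating-point precision; it is strictly monotone and sign-preserving.
All tests are two-sided.

## Problem sizes used by the validation suite

The acceptance experiments run at sizes chosen to make their statistics
decisive while staying desk-scale: correlation recovery uses one 20-minute
resting run (429 frames at 2.8 s, first minute discarded; the sampling SE of
r = 0.7 there is ≈ 0.026, small against the ±0.1 acceptance band);
amplitude recovery uses 7 + 7 animals at the full 405 s protocol on a 32×32
grid; translation recovery uses 8 acquisitions at 64×64; the ROI-family
calibration uses 200 null cohorts (under the global null BH's familywise
error is exactly q = 0.1, so the measured mean FDP concentrates near 0.10);
the pixel calibration uses 20 null cohorts of 5 animals.  Oracle equivalences
run on 8×8×256 (ReHo) and 32×32×64 (SVD filter) arrays.

## What passing tests do and do not show

The generator emulates the statistical structure the analyses assume:
multiplicative signals on a vascular baseline, band-limited shared
fluctuations, block-locked responses with the three qualitative temporal
shapes, white measurement noise, rigid inter-acquisition misalignment, and
low-rank tissue clutter.  It does not emulate ultrasound physics (speckle
statistics, angle compounding, attenuation), spatially correlated or
non-Gaussian noise, physiological confounds (breathing, anesthesia depth
drift), non-rigid within-acquisition motion, or real vascular anatomy.
Ground-truth recovery here therefore demonstrates the correctness of the
implementations and the internal consistency of the pipeline — not that the
pipeline would reproduce any particular in-vivo effect size.  The two-strain
group differences produced by the default cohort configuration are
illustrative of the workflow, not a reproduction of animal results.

## Known limitations

* 2D single-slice only; no volumetric registration or cross-modality atlas
  alignment.
* The SVD clutter cutoff is a free parameter; no adaptive threshold is
  implemented.
* Coherence ReHo assumes a common time grid per slice; no Kendall's-W
  variant.
* Pixel inference is uncorrected p < 0.001 (matched to the workflow it
  implements); no cluster-extent or permutation correction.
* The repeated-measures ANOVA uses listwise deletion of timepoints with
  missing animals.
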