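# Methods

## The decomposition model

Every ROI time-series (after motion censoring) is modelled as

    y(t) = b0 + b_slfo * x_slfo(t) + b_alpha * x_alpha(t)
              + b_beta * x_beta(t) + e(t)

where `x_slfo` is the systemic regressor (heart rate and respiratory flow
convolved with their scan-specific physiological response functions and
summed) and `x_alpha`, `x_beta` are HRF-convolved EEG band-power series,
all sampled at the volume times and z-scored.  The global signal is the
unweighted ROI mean; its decomposition uses partial correlations (each
regressor controlling for all others), with significance assessed against
inter-subject surrogates: every ordered subject pair (i, j), i != j,
contributes the partial correlation of subject i's global signal with
subject j's regressor, controls taken from subject j and both sides
truncated to the shorter censored length.  Observed and surrogate samples
are compared with a two-sided Wilcoxon rank-sum test; the four band
p-values are Benjamini–Hochberg corrected as a family, the SLFO p-value is
reported uncorrected.  Two-sided testing is used throughout because the
EEG couplings are negative while the SLFO coupling is positive.

## Process-specific synthetic datasets

For a process p in {slfo, alpha, beta}, the fitted signal is
`y_pi = b_p x_p` and the "clean" series `y_pi_res` removes the intercept
and the two other fitted terms from y.  With `r_pi = corr(y_pi, y_pi_res)`
and `r_res = corr(y_pi_res - y_pi, y_pi_res)`, the synthetic series is

    y_synth = r_pi * Z[y_pi] + r_res * Z[psi],

psi an AR(1) draw.  Because `y_pi_res - y_pi` is the OLS residual, it is
orthogonal to `x_p`, so `r_pi^2 + r_res^2 = 1` holds exactly per ROI; the
package asserts it at 1e-8.  Choices where the construction is open:

* the AR(1) coefficient of psi is the lag-1 autocorrelation of the ROI's
  own residual (the filler should mimic the temporal structure of what it
  replaces); a zero-variance residual yields phi = 0 with a degenerate
  flag;
* psi is drawn as one contiguous series of kept-frame length, ignoring
  censoring gaps;
* an exactly-zero fitted coefficient makes the ROI degenerate: it is
  emitted as pure AR(1) with `r_pi = 0, r_res = 1`;
* each process uses an independent, seed-derived noise substream, so
  datasets built from the same seed are mutually independent;
* the per-ROI regression is fitted on the minimally preprocessed data.
  Fitting on denoised data would remove the very component whose removal
  the pipeline comparison measures, collapsing the contrast of interest.

## Physiology

* **Beat detection**: local maxima with >= 0.3 s separation, gated at the
  amplitude threshold `median(x) + 0.25 * (P98(x) - median(x))`.  A gate
  based on the spread of candidate peak heights fails in both tails —
  tightly clustered beat heights (clean traces) and noise-dominated
  candidate sets — whereas the baseline-to-systole quantile gate handles
  both.
* **Heart rate**: 60/IBI at interval midpoints, Hampel filter (11-sample
  window, 3 MAD, replace with window median) against missed/extra beats,
  then shape-preserving PCHIP interpolation to a uniform 10 Hz grid (no
  spline overshoot, which matters next to replaced outliers).
* **Respiratory flow**: linear detrend, Hampel, 5 Hz low-pass, z-score,
  1.5 s moving average, squared time-derivative, 10 Hz resampling — in
  that order.  The square makes the measure invariant to the belt's sign
  convention and doubles the dominant frequency of a sinusoidal breath.
* **PRFs**: each curve is `a1 g(t; ttp1, tau1) - a2 g(t; ttp2, tau2)` with
  gamma-shaped `g` of unit peak; time-to-peak bounded to 1–20 s and width
  tau to 0.3–3.5 s, which forces decay below 1 % of peak within the 60 s
  support.  The four shape parameters per scan pair are optimised by
  L-BFGS-B (numeric gradients, 80 iterations) from a fixed 8-point start
  grid; the four amplitudes are profiled out by OLS at every objective
  evaluation (maximising the Pearson correlation between the modelled and
  observed global signal).  No randomness: results are bit-reproducible.
* Regressors are padded by holding their first value for one kernel
  length before convolution, so onset transients do not dominate the fit;
  the same convention is used for HRF convolution of band power.

**Identifiability note.** PRF *shape* recovery requires the driving series
to carry broadband slow (0.01–0.15 Hz) variance.  A purely quasi-periodic
respiratory flow concentrates variance at twice the breathing rate; any
smooth 60 s kernel suppresses that component almost equally, so different
shapes fit the global signal equally well and the respiratory curve is
under-determined even when the overall fit is excellent.  The recovery
simulations therefore drive the respiratory channel with a positive
broadband-slow series; with the quasi-periodic default flow the combined
SLFO regressor is still recovered accurately (r ≈ 0.95 against truth on
default cohorts) even where the individual respiratory curve is not.

## EEG

Analytic Morlet CWT (`omega0 = 6`, exposed as a parameter) on a
log-spaced grid of 10 voices per octave spanning 1–40 Hz; power is the
squared magnitude; the scale-to-frequency map uses the discretised
wavelet's measured centre frequency so grid frequencies are exact.  The
global spectrogram is the entrywise RMS of channel *power* values (not of
magnitudes).  Band power averages bins inside delta (1.5–4), theta (4–8),
alpha (8–15), beta (15–26 Hz).  The canonical HRF is a double gamma with
shapes 7 and 15.5 (scale 1 s, ratio 1/6, 32 s support), giving a 6 s peak
and a 16 s undershoot trough of the summed curve.  Band regressors are
zero-phase low-pass filtered at 0.2 Hz before TR sampling (anti-aliasing
below the volume-sampling Nyquist rate of ~0.236 Hz at TR = 2.12 s);
censored frames are removed after convolution.

## Censoring and pipelines

A volume is flagged if FD > 0.25 mm (rotations as arc length on a 50 mm
sphere) or DVARS > median + 3 MAD (MAD unscaled); both neighbours of a
flagged volume are removed, as is any sub-threshold volume whose immediate
predecessor and successor are flagged.  The three pipelines operate on the
kept frames: MinPrep (nothing further), WM10 (top-10 white-matter PCA
score series regressed out, the count selectable and sweepable against the
FCC), WM10_GSR (global signal and WM scores in one joint OLS; the ROI-mean
global signal of the regressed data is then exactly zero).  The FCC is the
standardised rank-sum statistic comparing within- against between-network
upper-triangle edges.  FC-matrix similarity is the Pearson correlation of
strictly-upper-triangle entries, raw r by default (a Fisher-z flag
exists); pipeline contrasts use the unpaired rank-sum test (a signed-rank
variant sits behind a flag, with a warning, since subjects are actually
paired).

## The synthetic cohort generator

Defaults describe the desk-scale study conditions: 11 subjects, 30 ROIs in
5 equal networks, T = 425 volumes at TR = 2.12 s (~15 min), heart rate
70 ± 3 bpm with 0.01–0.15 Hz variability, breathing at 0.3 Hz with slow
depth/rate modulation, and four positive log-normal band-power processes.
Per subject:

    bold = 100 + x_slfo b_slfo' + x_alpha b_alpha' + x_beta b_beta'
               + network latents + uniform slow nuisance + AR(1) noise

* `b_slfo ~ N(1.0, 0.7^2)` per ROI — the systemic component dominates.
* `b_alpha`, `b_beta`: per-ROI deviations `N(0, 0.7^2)` centred to zero
  within subject plus a uniform loading chosen analytically so the
  group-level partial correlation with the global signal equals the
  configured target (default −0.1).  The centring mirrors the empirical
  observation that regional EEG–BOLD couplings have both signs and largely
  cancel in the global mean, and it makes the weak target coupling exact
  rather than buried under sampling noise of the regional draws.
* Network latents (loading 0.4) and a spatially uniform nuisance
  (SD 0.3) are band-limited to 0.01–0.2 Hz — the hemodynamic passband;
  ROI noise is AR(1) with phi = 0.3, SD 0.85.  This composition leaves the
  generative couplings recoverable by OLS (pooled RMSE ≈ 0.08 of the
  coupling spread at T = 425) while keeping realistic shares: the SLFO
  explains most of the global signal (r ≈ 0.93) and the EEG bands a few
  per cent.
* White-matter channels mix lagged (0–4 s) copies of the SLFO, five
  shared non-neural latents, and channel noise, so 10-component WM-PCA
  removal strips the systemic component only partially — as in practice —
  leaving GSR measurable additional work.
* Motion is a smooth drift plus Poisson-placed (rate 3/scan) one-frame
  0.6 mm displacements whose frames are stored as ground truth; with the
  default DVARS rule the realised censored fraction is ~20 %.
* Raw 1 kHz traces (von-Mises-shaped pulse waveform following the HR
  series; modulated-sinusoid belt signal) are generated on demand and do
  not influence the BOLD draw, so analyses that only need regressors can
  skip them.

Determinism: subject k of a cohort draws from
`SeedSequence(seed, spawn_key=(k,))`, split further into fixed, named
substreams (HR, breathing, EEG, motion, couplings, latents, noise, WM,
nuisance).

### What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: slow
physiological drivers with PRF coupling, weak negative alpha/beta
coupling with regional sign cancellation, network-block covariance,
partial WM capture of the systemic signal, and motion-censoring
morphology.  It does not emulate voxel-level spatial structure, EEG
channel topography (band power is generated directly; channel-level
waveforms exist only as a test fixture), scanner drifts/spikes, cardiac
pulsatility aliasing, or non-stationary arousal dynamics.  Passing tests
therefore establish the correctness and calibration of the *pipeline*
under known ground truth, not claims about any particular empirical
recording.

## Numerical conventions and degenerate inputs

* Z-normalisation rejects (near-)constant series with a dedicated error.
* Volume k is sampled at `t = k * TR` (0-based); 10 Hz series are read
  out at `round(k * TR * 10)`.
* FC entries of zero-variance ROIs are NaN and excluded pairwise from
  similarity; averaging of FC matrices uses raw r.
* TSVs are written at 17 significant digits and parsed with the
  round-trip float parser, so write/read cycles are bitwise.
* All optimisation and surrogate constructions are deterministic; the
  only random draws (cohort generation, AR(1) fillers) flow from explicit
  seeds.

## Problem sizes used by the shipped checks

Recovery and calibration runs use the defaults above (11 × 425 × 30)
except the surrogate-calibration sweep, which uses 100–200 cohorts of 6
subjects at T = 200 — the smallest design in which the ordered-pair
surrogate set (30 pairs) still dwarfs the observed sample.  These sizes
were chosen so each property is measured with comfortable Monte-Carlo
margin at interactive runtimes.

## Known limitations

* The respiratory PRF shape is weakly identified from quasi-periodic flow
  (see the identifiability note); per-scan respiratory curves should be
  interpreted with care even when the combined SLFO fit is good.
* The rank-sum surrogate test is slightly anti-conservative/conservative
  depending on cohort size because surrogate values sharing a subject are
  dependent; measured type-I error at the shipped sizes stays within
  0.02–0.08 at nominal 0.05.
* The FCC is one of several possible network-identifiability statistics;
  it is exposed as a pluggable function.
* Group-level conclusions from synthetic cohorts scale with the
  configured couplings; magnitudes (e.g. the full-model R ≈ 0.93) are
  properties of the default generative composition, not empirical
  estimates.
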