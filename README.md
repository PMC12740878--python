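# gsdecomp

Decomposition of the resting-state fMRI **global signal** (GS) into its
systemic-physiological and electrophysiological components, and a
synthetic-cohort framework for quantifying what **global signal
regression (GSR)** does to functional connectivity attributable to each
source.

## The scientific problem

The BOLD global signal mixes at least two very different things:

* **SLFOs** (systemic low-frequency oscillations): slow (< 0.15 Hz) blood
  flow modulations driven by beat-to-beat heart-rate variability and
  breathing-pattern changes, transmitted to BOLD through physiological
  response functions (PRFs);
* **electrophysiological activity**, visible as EEG band-power
  fluctuations (delta/theta/alpha/beta) convolved with the hemodynamic
  response function (HRF).

Regressing the GS out of every region removes physiological artifact, but
may also delete neural signal.  `gsdecomp` implements the analysis chain
that separates the two contributions and measures the collateral damage of
GSR on each:

1. **Physiology** — heart rate from pulse-oximeter beats, respiratory flow
   as the squared derivative of the smoothed belt signal, scan-specific
   PRF estimation (difference-of-gammas, fit to the GS), and the combined
   SLFO regressor.
2. **EEG** — Morlet CWT spectrograms (10 voices/octave), RMS pooling
   across channels, band-power extraction, canonical double-gamma HRF
   convolution, TR sampling.
3. **Preprocessing** — FD/DVARS motion censoring (0.25 mm / median + 3 MAD
   with neighbour and sandwich rules), white-matter PCA denoising, GSR,
   and the functional connectivity contrast (FCC) quality metric.
4. **GS decomposition** — partial correlations of the GS with the SLFO and
   band-power regressors, inter-subject surrogate null distributions,
   Wilcoxon rank-sum tests with BH-FDR across bands.
5. **Process-specific synthetic datasets** — per ROI, the multiple
   regression `y = b0 + b_slfo x_slfo + b_alpha x_alpha + b_beta x_beta + e`
   is refit and each process's fitted signal is recombined with a
   variance-matched AR(1) filler:
   `y_synth = r_pi * Z[y_pi] + r_res * Z[psi]`, where
   `r_pi^2 + r_res^2 = 1` exactly (OLS orthogonality).
6. **Connectivity comparison** — upper-triangle similarity between
   process-synthetic and experimental FC matrices under three pipelines
   (MinPrep, WM10, WM10 + GSR), with rank-sum pipeline contrasts.

Since the raw simultaneous EEG–fMRI recordings behind this design are not
public, a fully specified **synthetic cohort generator** (`gsdecomp.synth`)
produces physio traces, band power, motion, white-matter channels, and ROI
BOLD with known ground truth (couplings, PRFs, network structure), so every
stage can be validated by parameter recovery.

## Worked example

```bash
gsdecomp analyze --config small.yaml --seed 4 --out analysis_demo
# small.yaml:  n_subjects: 6
#              n_volumes: 200
```

`analysis_demo/contributions.tsv` (GS contributions, 6 synthetic subjects):

```
regressor  mean_r   sd_r    p_value   p_fdr    significant
slfo        0.921   0.020   1.3e-04   1.3e-04  True
delta      -0.062   0.097   0.289     0.373    False
theta       0.029   0.104   0.373     0.373    False
alpha      -0.096   0.113   0.082     0.164    False
beta       -0.134   0.155   0.030     0.122    False
```

The SLFO regressor explains most of the GS (partial r ≈ 0.92), while the
alpha/beta couplings sit at their configured weak negative target
(≈ −0.1); at n = 6 they are not yet significant against the inter-subject
surrogate null (they are at the default n = 11).

`analysis_demo/pipeline_comparison.tsv` (FC similarity of the SLFO
synthetic dataset to each pipeline):

```
process  pipeline_a  pipeline_b  mean_a  mean_b  p_value
slfo     MinPrep     WM10        0.696   0.268   0.0039
slfo     WM10        WM10_GSR    0.268   0.041   0.0039
alpha    MinPrep     WM10        0.354   0.520   0.016
alpha    WM10        WM10_GSR    0.520   0.513   0.87
```

WM denoising and then GSR strip the physiological (SLFO) connectivity
pattern step by step (0.70 → 0.27 → 0.04, both drops significant), while
the alpha-band pattern is untouched by GSR (0.52 → 0.51, ns) — the
signature result this package exists to quantify.

The same workflow is available as library calls
(`gsdecomp.workflow.contribution_analysis`, `similarity_table`) and the
physiology chain as `gsdecomp physio --cardiac ... --resp ... --gs ...`.

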