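# Methods

## Signal model and normalization

The package models spoiled gradient-echo imaging of inhaled fluorinated
gases in steady state:

    S = S₀ (1 − E₁) e^(−TE/T2*) sin α / (1 − cos α E₁),  E₁ = e^(−TR/T₁)

S₀ is taken proportional to the number of chemically equivalent ¹⁹F nuclei
in the imaged peak — 8 for OFCB's single line, 6 for PFP's CF₃ main line
(the 2-F CF₂ line produces a chemical-shift ghost and is simulated but not
imaged). Transient approach to steady state is not modeled; the closed form
is taken as given.

Noise is assumed white and complex Gaussian in k-space, so SNR grows as
√NSA while scan time grows linearly in NSA. Comparisons at fixed scan time
therefore use SNR/NSA. Theoretical SNR is `signal × √NSA`; the normalized
value divides by a `norm_nsa` that defaults to the protocol's own NSA. The
override exists because the continuous-breathing predictions in the source
analysis were normalized by the breath-hold NSAs (16/24) rather than their
own (144/221); both conventions are reachable and the shipped
`continuous-70` scenario uses the 16/24 convention. Under it, with TRs
derived from the 185-s scan window (20.07/13.08 ms), the prediction
evaluates to 96.0%; with each protocol's own NSAs it is ~100.5%. The
published figure of 98% sits between the two conventions and is not exactly
reproducible on either path; the package reports what the model computes.

The breath-hold TRs are not printed anywhere; they are derived from the
fixed scan window via TR = scan_time/(n_lines·NSA), giving 21.48 ms (OFCB,
NSA 16) and 14.32 ms (PFP, NSA 24) — the only choice consistent with the
11-s breath-hold and the one that reproduces the 86% prediction.

`advantage_surface` evaluates the normalized ratio on a TR×TE grid (rows =
TR, cols = TE, ascending). By default both gases share the grid TR; with
`tr_b_ms` the comparison gas is pinned at its own operating point while the
TR axis sweeps the first gas. Only the pinned reading produces the
documented short-TR crossover where PFP overtakes OFCB (computed boundary
≈6.9 ms at TE 0.63 ms under fixed NSA 16/24); on the shared-TR surface OFCB
wins everywhere practical.

Angles are degrees at every interface (converted internally), times are
milliseconds, frequencies Hz.

## Relaxometry

T2* comes from a Lorentzian least-squares fit (lmfit; one to three lines
plus a constant baseline for scanner DC offset) via T2* = 1/(π·FWHM).
Initialization: centers from greedy maxima picking (or a user hint), FWHM
from the raw width at half maximum, amplitudes non-negative. Fits default
to the real part of phased data; magnitude fitting is available. Peaks are
returned in descending-area order. Convergence: relative parameter
tolerance 1e−8, up to 1000 iterations per parameter triple.

T₁ comes from a three-parameter inversion-recovery fit
M(TI) = M₀(1 − 2β e^(−TI/T₁)); the inversion-efficiency β (default free,
bounded [0, 1.2]) makes the fit robust to imperfect 180° pulses and reduces
to the textbook model at β = 1. T₁ is initialized from the zero crossing
(TI_null/ln 2). Magnitude-acquired data has polarity restored by flipping
points up to the |M| minimum; because the point nearest the null can lie on
either side of the crossing, both assignments are fitted and the lower-RMS
fit kept. Fits with T₁ outside (0, 10·TI_max) raise rather than return
nonsense. Default TI grids are the study's: 4:3:91 ms for pure gases,
4:1:28 ms for O₂ mixtures.

## Synthetic data

The generators emulate the acquisition chain, not scanner hardware:

* **Spectra** — sums of complex Lorentzians (absorption + dispersion,
  analytic area = concentration × per-peak fluorine count, FWHM =
  1/(π·T2*)) on a 32-kHz, 2048-point window, plus complex Gaussian noise
  per frequency sample. The PFP CF₃–CF₂ separation defaults to 45 ppm at
  120.15 MHz (≈5.41 kHz); no measured shift was available, and the value
  only needs to place the second peak well inside the bandwidth.
* **IR series** — the exact model curve plus Gaussian amplitude noise.
* **GRE images** — per-pixel amplitude = steady-state signal ×
  concentration on a boolean phantom mask (centered disc for the syringe
  phantom; two-lobe ellipses as a coarse lung projection), orthonormal FFT
  to k-space, independent complex Gaussian noise per average, complex
  averaging, inverse FFT, magnitude. This yields Rayleigh background with
  scale σ_k/√NSA and Rician signal regions, the regime in which the SNR
  conventions below are defined.

What the generators deliberately do not emulate: coil loading and B₁
inhomogeneity, gas density/polarization differences, respiratory motion and
ghosting, chemical-shift artifact displacement, and eddy-current phase
errors. Consequently the measured phantom/in vivo SNR magnitudes of the
source study (45.52, 628.44, …) are not reproduction targets — they depend
on hardware factors outside the model — and passing tests show the pipeline
recovers its own ground truth, not that a scanner would produce these
numbers. The default end-to-end k-space noise (σ_k = 3.07) is chosen so the
simulated breath-hold images land at study-scale SNR ≈ 10, i.e. realistic
Rician conditions.

## SNR measurement

SNR = (mean or max of a rectangular signal ROI) / (SD of a disjoint
background ROI of ≥25 pixels). The background SD is used raw — uncorrected
for the Rayleigh distribution — because that is how the reference values
were computed; `rayleigh_correction=True` divides by √(2−π/2) ≈ 0.655 when
the underlying Gaussian σ is wanted. `mode="peak"` takes the maximum over
the signal ROI (whole-image peaks would be artifact-sensitive). ROIs are
0-based half-open row/col rectangles; artifact exclusion is a manual
per-image flag, not automated detection. At in vivo SNR (~8–10) the Rician
signal bias is below 1% and cancels almost entirely in gas ratios.

## Statistics

Paired t test from the differences directly (p from the t CDF). Identical
samples return t = 0, p = 1 flagged degenerate instead of raising, so batch
pipelines survive constant fixtures; constant nonzero differences return
t = ±∞, p = 0 flagged.

Evidence grading uses the JZS Bayes factor for a one-sample test on the
paired differences: Cauchy(0, r) prior on the standardized effect,
r = √2/2 by default (the common software default), configurable. The
marginal likelihood integral over the g-prior (inverse-gamma(½, ½)) is
computed with adaptive quadrature to ≤1e−6 relative error (verified against
an independent dense transformed-trapezoid rule and cross-checked against
pingouin). Bayes factors are banded on the published Kass–Raftery scale —
cutpoints 3, 20, 150 on BF ("not worth more than a bare mention",
"positive", "strong", "very strong") — with reciprocal banding for BF < 1;
the bands are configurable for Jeffreys-style labels. The source study's
printed Bayes factors are not reproduction targets: the per-image SNR
samples behind them were never published.

## Problem sizes and determinism

Monte-Carlo checks use the study's own conditions: 100 seeds for
relaxometry recovery (amplitude SNR 100) and for replicate 5-animal
end-to-end studies, 50 seeds for noise-scaling laws; images are the study's
32×32 (breath-hold) and 64×64 (continuous) matrices. Every stochastic
routine takes a seed or NumPy Generator; a fixed seed reproduces outputs
bitwise, and pipeline artifacts are stamped with the seed and a config
hash.

## Known limitations

* The Ernst-angle protocols assume the nominal T₁; in vivo T₁ varies with
  local O₂ concentration, which the simulator does not model.
* Multi-peak Lorentzian fits assume line separations greater than one FWHM;
  heavily overlapped lines will trade area between components.
* The two-lobe lung mask is a geometric stand-in, not an anatomical
  segmentation; ROIs are explicit inputs, never auto-segmented.
* Reported-value tables carry both versions of internally inconsistent
  reference numbers (e.g. the full-recovery normalized SNR 0.39 vs the
  division 10.23/29 ≈ 0.35) and flag, never resolve, the discrepancy.
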