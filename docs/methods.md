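# Methods

This note records the models implemented in `tddcs`, the numerical and
design choices behind them, what the synthetic instrument does and does not
emulate, and the known limitations.

## Forward models

**Time-domain diffuse reflectance.** The semi-infinite medium is solved
with the extrapolated-boundary image-source construction: an isotropic
point source at depth z₀ = 1/µs′ and a negative image mirrored about the
extrapolated boundary z = −z_b, z_b = 2AD with D = 1/(3µs′). The boundary
coefficient A derives from the standard polynomial approximation of the
effective internal reflection coefficient R_eff(n); the speed of light in
the medium is c/n with a single configurable refractive index (default 1.4
for tissue, 1.33 for liquid phantoms — instrument papers rarely state n,
so both are exposed). The reflectance is evaluated through Fick's law at
the physical surface. Two exact identities are used as self-tests:
absorption factorizes as exp(−µa v t) channel by channel, and the time
integral equals the closed-form CW reflectance.

**Correlation diffusion.** The normalized field autocorrelation of a
semi-infinite medium under effective Brownian motion (mean-square
displacement 6 D_B τ) is the CW Green's function evaluated at the dynamic
attenuation K(τ)² = 3µaµs′ + 6 µs′² k₀² D_B τ, normalized at τ = 0; k₀ =
2πn/λ is the in-medium wavenumber. The blood flow index is α·D_B with α
fixed at 1 — α is not separable in a homogeneous fit, so BFI and D_B are
reported interchangeably.

**Two-layer medium.** For a finite top layer over a semi-infinite base
(shared n), the correlation diffusion equation is solved per spatial
frequency s in Hankel space, with each layer's dynamic absorption
µa_i + (1/3)µs′_i k₀²·6 D_B,i τ, and inverted by Gauss–Legendre quadrature
(upper cutoff 25µs′, node doubling until g1 changes < 1e-4 absolute;
non-convergence raises with diagnostics). All hyperbolic terms are
rewritten with non-positive exponents, so the solution is stable to
arbitrarily large s·L. The homogeneous-limit correction vanishes
identically when the layers match, and the thick-layer limit reduces to
the top layer's semi-infinite solution — both are asserted in tests.

**Chromophores.** The shipped extinction table (HbO₂/HHb at 685, 785 and
830 nm) holds natural-log coefficients in 1/(cm·µM) converted from the
standard compiled in-vitro spectra; the basis is an explicit,
user-replaceable object because published tabulations differ by a few
percent. Water/lipid backgrounds are off by default: the analysis chain
fits µa directly and applies Beer's law to µa alone.

## DTOF fitting

`DtofModel` minimizes the Poisson deviance between the measured histogram
and A·(IRF ⊛ R)(t − t₀) + bg over a data-driven fit range. Choices that
matter:

- **Poisson deviance, not Gaussian least squares** — the late-gate tail
  channels carry most of the µa information at counts where Gaussian
  weighting is badly mis-calibrated.
- **Amplitude profiled analytically** (A* = Σd/Σs, the Poisson MLE for a
  scale factor), leaving (µa, µs′, t₀) to the optimizer
  (`scipy.optimize.least_squares` on signed root-deviance residuals).
- **Fit range**: from the rising-edge channel at 80% of peak to the tail
  channel at 1% of peak, with the threshold crossings located on a
  5-channel-smoothed copy of the curve so the range does not wander with
  channel-level Poisson noise at low counts. Characterization papers
  rarely state their range; this default is configurable.
- **t₀ free** within ±100 ps: a nuisance for electronic timing drift.
  The width matters: with the IRF and DTOF sharing one TCSPC axis, real
  drift is tens of picoseconds (the scale seen in long IRF stability
  runs), and allowing t₀ hundreds of ps makes (t₀, µa, µs′) jointly
  unidentifiable at ~10⁴ counts — the likelihood ridge is then flat over
  hundreds of ps and the minimizer lands on the bound with badly biased
  parameters. ±100 ps keeps the nuisance physical and preserves the
  Poisson −1/2 noise scaling down to 10⁴ counts. Freeing t₀ still
  roughly doubles σ(µa) relative to a fixed-t₀ fit.
- **Background** estimated from a pre-peak window (first 10% of channels
  before the rising edge) and held fixed. The IRF kernel is
  background-subtracted, clipped at zero and area-normalized; DNL
  correction of DTOFs is available but off by default, since DNL
  structure falls outside the span of a typical DTOF.

At 10⁵ counts the fitted µa attains a CV within ~15% of the joint
Cramér–Rao bound of this four-parameter Poisson model, i.e. the estimator
is close to efficient; the CV-vs-counts slope is the Poisson −1/2 power law.

## Software correlator

Multi-tau estimator on binned counts: m = 16 lags per octave at the 200 ns
base bin, then bin-doubling per octave (default 20 octaves ≈ 200 ns–20 ms,
chosen to resolve phantom and tissue decays at both 1.5 and 2.5 cm).
Symmetric normalization divides each lag's product sum by the means of the
two window-restricted halves, suppressing finite-window bias; plain
normalization is switchable. Timestamps stay 64-bit integer picoseconds
end to end and binning is integer division, so results are exactly
reproducible and the first octave is bit-comparable to an O(N²)
pair-counting correlator (asserted to 1e-12 in tests). Windowed operation
tiles the stream with half-open windows; photons on a boundary belong to
the window containing their timestamp.

## g2 fitting

`G2Model` does least squares of 1 + β|g1(τ; D_B)|² on the measured curve,
with D_B optimized in log10 space (positivity, dynamic range). β is
initialized from the mean of the first three lags minus one; D_B from the
lag where g2−1 decays to β/e via a linearized single-exponential closed
form. The fit runs once over all lags, then cuts the range where the
fitted model's g2−1 drops below 1% of β and refits (one iteration).
Weights are uniform by default; a Koppel/Zhou-type multi-tau shot-noise
variance model is available both as optional weights and as the
"theoretical trend" curve in noise scans — it is never used to generate or
validate data. The model evaluates the photon occupancy at each lag's
*local* bin width (bins double per octave), without which the shot-noise
term at long lags is grossly overestimated; with the local width, its
error-propagated CV(D_B) reproduces the simulated noise scan within a few
percent.

## Synthetic instrument

**IRF**: Gaussian core (default 200 ps FWHM) convolved with a
double-exponential tail (defaults 150 ps at weight 0.20 and 700 ps at
0.03 — the SiPM-like falling edge), a flat signal-dependent background
parameterized by the afterpulsing ratio it produces (default 3%, typical
of SiPM TCSPC channels), and an optional secondary reflection peak.
Everything is Poisson sampled.

**DTOFs**: per-channel Poisson draws around the IRF-convolved diffusion
model, the amplitude set so the expected total equals the target count.
The generator and the fitter share the same convolution composition, so
noiseless round trips recover parameters to <0.1%.

**Perturbations**: a movable absorbing inclusion is modelled in first Born
approximation as a point defect of strength Δµa·V (default 0.17 cm⁻¹·cm³,
a conventional equivalent-strength scale for such phantoms), with
time-convolved products of image-source Green's functions; source and
detector endpoints both sit at one transport mean free path, which makes
the lateral scan exactly symmetric and the depth-integrated sensitivity
satisfy the total-pathlength identity ∫L(z,t)dz = v·t (asserted to 0.2%).
The perturbation enters as an exponentiated relative defect, keeping
counts positive. Bilayer absorption changes use the time-resolved mean
partial pathlength per layer (microscopic Beer–Lambert): N(t) →
N(t)·exp(−Δµa·L_layer(t)). This neglects the pathlength variance within a
time channel, which saturates the superficial late-gate contrast at large
Δµa — adequate for the ordering laws studied, not for absolute contrast
calibration. Amplitudes stay calibrated on the unperturbed reference
(constant injected power), and peak-referenced gates are resolved once on
the reference curve so all measurements share absolute gate windows.

**Speckle streams**: a stationary complex Gaussian field with the target
autocorrelation is synthesized per segment by spectral coloring (the
discrete PSD is the FFT of the sampled g1), at a time step of
τ(g1 = 0.95)/10. A coherence factor β = 1/M is realized by summing M
independent speckle intensities (β = 0.5 → M = 2; the realized β is
recorded). Photons are drawn as an inhomogeneous Poisson process: a
Poisson total per segment, placed by inverse-CDF sampling of the intensity
and uniformly within field samples, on integer picoseconds. Segments
(≤ 2¹⁹ samples, ~0.1 s) are independent; lags analyzed downstream must be
well below the segment length, which holds by two orders of magnitude for
every study here. Fields are complex64: the synthesis noise floor is far
below photon shot noise. A medium with no resolvable decay (D_B = 0)
degenerates to constant intensity — the photon stream is then exactly
homogeneous Poisson, as the normalized g2 of a static speckle is 1.

What the generator does **not** emulate: detector afterpulsing correlations
and dead time in the DCS channels, pile-up in the TCSPC channels,
cross-talk between detectors, ambient drifts, and motion artifacts.
Passing tests therefore demonstrate correctness of the estimators under
ideal shot-noise + speckle statistics, not robustness to those hardware
effects.

**Hemodynamic scenarios**: the stepped-occlusion generator follows the
standard cuff protocol (2 min baseline, 1 min light, 1 min venous, 1 min
arterial occlusion, 5 min recovery at 5 Hz) with piecewise-linear
chromophore ramps smoothed by a 5 s exponential: venous occlusion raises
tHb 25% at constant StO₂ with a mild D_B decrease to 0.85×; arterial
occlusion freezes tHb while swapping 12 µM from HbO₂ to HHb and collapses
D_B to 0.15×; release produces gamma-shaped hyperemic overshoots. Baseline
muscle values (HbO₂ 42 µM, HHb 18 µM → StO₂ 70%, tHb 60 µM, D_B 1e-8
cm²/s) are typical resting forearm figures. These are scenario parameters,
not measured values. The pulsatile generator modulates D_B with a cardiac
fundamental plus harmonics (amplitude a/i on harmonic i), one independent
speckle realization per 30 ms window.

## Pipelines

The occlusion pipeline preserves the filtering order of the analysis it
models: the 5-sample running **median** acts on g2 curves *before* fitting
(outlier windows vanish without biasing neighbors), and the 5-sample
moving **average** acts on all output traces *after* the fits. A test
demonstrates the orderings are not interchangeable on outlier-laden data.
The assumed optics for the DCS fit are derived from the TD NIRS chain:
median fitted chromophores pushed through Beer's law at 785 nm. Output
samples are stamped at window centers; non-converged fits propagate as
flagged NaN gaps, never interpolated.

The Welch PSD uses Hamming windows (default 20 s, 50% overlap), one-sided
density normalization; total power matches the signal variance within the
~5% window bias.

## Protocol statistics

Contrast uses natural logarithms (base-10 switchable); contrast is
computed from repetition-summed counts while its noise term σ[log N_k]
comes from per-repetition logs, exactly as the gated-contrast and CNR
definitions juxtapose them. Depth selectivity is reported as the
deep-over-superficial contrast ratio C_DOWN/C_UP — the orientation in
which late gates and larger source-detector separations are more
selective. All spreads are sample (n−1) standard deviations. Noise-scan
thresholds interpolate on log-log axes (where the scans are linear);
stability warm-up is the first time a series enters and never leaves a
±1% band around the mean of its final 10%.

## Study sizes

The packaged studies run at sizes chosen for a single CPU core: the TD
NIRS noise scan uses 8 count levels × 10 repetitions (more levels than the
minimum six, to reduce the leverage of any single 10-repetition CV
estimate, which itself carries ~24% sampling error); the DCS noise study
4 count rates × 100 one-second windows × 4 channels, with the same
speckle-field realizations thinned at every rate (common random numbers:
per-rate CVs are unbiased and the rate-to-rate comparison is smoothed;
fields and photon draws use independent substreams per window and
channel). The test suite runs reduced versions (8 repetitions, 30 windows)
with correspondingly wider statistical bands.

## Known limitations

- The TD forward model is homogeneous; layered TD NIRS fitting is out of
  scope (the two-layer solution exists only on the DCS side).
- The Born point-inclusion model understates contrast very near the
  surface (the diffusion Green's function vanishes toward the
  extrapolated boundary), where a finite-size inclusion would not.
- Absolute noise thresholds (counts at 3% CV, rate at 5% CV) depend on
  estimator settings — fit range, free t₀, correlator lag grid — all fixed
  to the defaults above; hardware-specific backgrounds would shift them.
- The quasi-analytic noise model (Koppel/Zhou) assumes a single-exponential
  g1; it is used only for weighting and trend comparison.
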