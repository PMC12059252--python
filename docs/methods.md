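# Methods

## Signal model and calibration

The package models the recorded NMR signal as

    signal = A · f(RG) · sin α · P · C ,

with A a hardware coefficient, f(RG) the receiver gain function (identity
for a linear receiver), α the excitation flip angle, P the nuclear spin
polarization (fraction) and C the spin concentration (M; molecular
concentration × spins per molecule). The model has no intercept — zero
gain records zero signal — so all slope fits go through the origin.

A calibration sweep acquires one spectrum per RG setting at fixed
reference conditions (α_ref, P_ref, C_ref) and quantifies three things per
point:

* **signal integral** — trapezoidal integral of the real (absorption)
  part over a peak window, in a.u.·Hz so it is invariant under zero
  filling;
* **noise RMS** — root-mean-square of the real part of a signal-free
  window after removing a linear baseline; the automatic mode picks the
  minimum-variance contiguous window (default 10 % of the points)
  disjoint from all declared peak windows;
* **FID maximum** — the largest magnitude of the complex time-domain
  signal, the quantity the ADC ceiling actually limits.

SNR is defined as integral ÷ noise RMS (a peak-amplitude convention is
available as an option in `snr_of`). Two calibrated channels — integral
and FID maximum — are carried separately throughout: their scales are not
derivable from one another (integrals depend on lineshape and integration
aperture; the FID maximum does not), and conflating them would misplace
the overflow boundary.

Reference SNR at arbitrary gain is piecewise-linear interpolation between
measured points, exact at the knots, with one deliberate exception: a
segment across which SNR drops by more than 10 % (the level-plan switch
signature, see below) is never interpolated — queries inside it snap to
the nearer measured knot, and the planner's default gain grid includes the
measured knots so plans land on calibrated settings. No extrapolation
outside the measured range, ever.

The linearity diagnostic is

    deviation(RG) = (signal(RG)/RG) · (RG_max / signal(RG_max)) − 1 ,

identically zero for a linear receiver and exactly zero at RG_max by
construction.

Per-scan normalization: when a sweep mixes averaging counts, stored
signal integrals and FID maxima are divided by `n_averages` (the
convention benchtop consoles apply to saved data). Noise is stored as
given; with a constant scan count across a sweep — the usual case — the
normalization is a pure rescaling that cancels from every ratio the
planner uses. dB-valued gains convert with the amplitude convention
RG = 10^(dB/20); stored curves always carry linear RG.

## Thermal polarization

For thermally polarized references P follows the spin-1/2 two-level form
P = tanh(h·f_L / 2k_B·T) with f_L = |γ/2π|·B₀. The registry ships
|γ/2π| for ¹H, ²H, ¹³C, ¹⁵N and ¹⁹F (CODATA/IAEA magnitudes; the sign of
γ never enters the ratios used). The same formula is applied to the
spin-1 deuteron: in the high-temperature linear regime, which holds to
better than 10⁻⁶ relative up to 25 T at ≥ 250 K, polarization *ratios*
are identical between the two-level and Brillouin forms, and reference
polarizations are in any case carried as explicit stored values rather
than silently recomputed (measurement temperature defaults to 298 K when
unstated).

## Planning

Given a calibration curve, a sample (C, P) and a receiver (gain range,
RRT, safety factor), the planner maximizes

    SNR(RG, α) = SNR_ref(RG) · sin α/sin α_ref · P/P_ref · C/C_ref

subject to predicted-FID-max(RG, α) ≤ S_m = safety_factor · RRT and
0 < α ≤ α_m, on a grid: α from 0.1° to α_m in 0.1° steps; RG on the
receiver's discrete allowed list when provided, else 400 log-spaced points
plus the measured knots. Infeasible grids raise an error reporting the
minimal-violation cell. Ties (within 10⁻¹² relative) break toward lower
RG — identical sensitivity at lower clipping risk — then lower α. The
default overflow condition is the exact one (S_m = RRT); `safety_factor =
0.5` reproduces the conservative half-ceiling convention. sin α is exact
trigonometry, no small-angle shortcut. A Karush–Kuhn–Tucker analytic
solution would be possible for smooth curves but the grid is exact on
discrete hardware gain lists, trivially fast at this size, and validated
against an exhaustive brute-force scan in the tests.

Closed forms for linear receivers: the clipping product
k = S_m · sin α_ref · P_ref / (slope_fid · C · P) is the largest
sin α · RG that avoids overflow (inversely proportional to P·C), and
arcsin(min(1, k/RG)) is the flip-angle limit at a given gain. An SNR
improvement by a factor r shortens signal averaging by r², since averaged
SNR grows with the square root of the scan count.

## Spectral processing choices

* Plain FFT scaled by the dwell time (spectral values in a.u./Hz);
  frequency axis in Hz offset from the carrier (rotating frame). No
  apodization anywhere — windowing would bias both signal and noise
  quantification. Zero filling is optional and integral-normalized.
* Rectangle-rule sampling of a one-sided decay adds a flat pedestal of
  s(0)·dwell/2 to the spectrum. `integrate_peak` removes it as a
  zero-order offset equal to half the full-axis mean of the real part
  (an exact DFT identity). The correction is linear in the data, so noise
  cannot bias it — an earlier median-based offset was measurably biased
  on skewed Lorentzian-tail backgrounds.
* Baseline handling beyond that is limited to the linear detrend inside
  the noise window.
* Clipping is evaluated per quadrature channel (real and imaginary
  digitized separately); a sample at or above `near_fraction` (default
  0.999) of the ceiling counts as clipped, and the ceiling itself counts
  (the allowed region is signal ≤ S_m). RRT estimation looks for runs of
  ≥ 4 consecutive samples within 0.1 % of a channel's maximum magnitude
  and returns the median plateau level; unclipped records contribute
  nothing and purely unclipped inputs are an error.

## The receiver simulator

Synthetic FIDs are exponentially decaying complex signals with an
off-resonance offset (default 120 Hz, T₂* = 50 ms, 2048 points at
4096 Hz sweep), amplified by f(RG), plus circular complex Gaussian noise
of per-channel sigma

    σ(RG) = sqrt( (σ_in · f(RG))² + (σ_out · pen(RG))² ) ,

then hard-limited per channel at ±RRT. σ_in is noise referred to the
receiver input (amplified with the signal), σ_out a post-gain floor, and
pen(RG) jumps from 1 to a switch penalty above the level-plan switch
gain. This one phenomenological family reproduces the three observed
SNR(RG) shapes: input-dominated saturation, dip-and-recover, and
output-dominated monotone growth.

Three presets ship as the study conditions:

* **dip** (X-nucleus-like, 9.4 T class): σ_out/σ_in and the switch
  penalty are solved in closed form so that SNR gains exactly 4.8× from
  RG 0.25 to 18 and drops exactly 40 % from RG 18 to 20.2 — the reported
  behaviour of such channels (σ_out/σ_in ≈ 1.176, penalty ≈ 23.0).
* **saturating** (¹H-like): σ_out/σ_in = 5, SNR plateaus above RG ≈ 30.
* **monotone** (high-field cryo-class): σ_out/σ_in = 60, SNR still
  rising, decelerating, at RG 101.

These are synthetic stand-ins chosen to match reported ratios and
qualitative shapes; they are not measured hardware curves, and passing
tests against them demonstrates the *pipeline* (quantification,
calibration, planning), not any particular instrument. Features of real
data the simulator does not emulate: multi-line spectra, B₀ drift and
lineshape distortion, receiver intermodulation below the ceiling, RG
miscalibration (nominal ≠ actual gain), and temperature-dependent noise
figure.

Hyperpolarized series: polarization before shot n is
p₀ · exp(−t_n/T₁) · Π cos α_m over the preceding shots; repetition times
can carry seeded uniform jitter (default 7–10 s, emulating console
compilation delays). `normalize_series` multiplies each integral by the
calibrated signal ratio signal_ref(RG_ref)/signal_ref(RG_n) (reference =
the largest gain in the series), exactly the factor-based normalization
used to merge alternating-gain shots, then fits a·exp(−t/τ) by weighted
least squares — shots normalized with a large factor carry
proportionally larger noise, so relative sigmas factor·noise_ref(RG)
enter the fit; the τ confidence interval is the t-distribution 95 %
interval from the scaled covariance. The cos α polarization-consumption
correction is opt-in (`correct_flip`), because the factor-only
normalization is the procedure used on real series; with it, the fit
estimates T₁ itself instead of the effective (flip-shortened) decay.

Default hyperpolarized study conditions: 46 shots, α = 5°, RG
alternating 0.25/18, p₀ = 0.329, C = 100 mM, T₁ = 55 s (a typical
in-vitro [1-¹³C]pyruvate value at high field), first-shot SNR ≈ 300 at
RG 18 / ≈ 60 at RG 0.25.

## Numerical and test-design notes

* All stochastic code takes a seed (or `numpy.random.Generator`) and is
  bit-reproducible; CLI outputs are JSON with sorted keys, so identical
  configurations give byte-identical files.
* Problem sizes in the test suite and acceptance script (2048–8192-point
  FIDs, 3–32 replicates per sweep point, 100-replicate slope studies,
  50-replicate T₁ coverage, 1000 randomized planning scenarios) were
  sized by statistical power analysis of each estimator before the tests
  were run, keeping the whole suite in a few seconds.
* The SNR round-trip check generates peaks whose *peak-height* SNR spans
  5–500. At the bottom of that range any integral- or amplitude-based
  estimate carries an irreducible sampling error of order 1/SNR, so the
  check compares the integral-convention estimate against its analytic
  expectation with acquisition length (40 T₂*) and aperture (±2 FWHM)
  chosen so the estimator's sampling deviation stays within ±10 % in
  ≥ 95 % of realizations.
* On a sub-1 % SNR plateau (RG 10–18 on the dip preset), finite averaging
  cannot resolve *which* plateau gain is best; end-to-end tests therefore
  assert the plan lands in the plateau, and the exact analytic arg-max
  (RG 18) is asserted only under heavy averaging (32 replicates).
* Interpolation of an 8-knot thinned curve reconstructs the smooth
  segments of the dip preset within 10 % (piecewise-linear error on the
  concave saturation curve), and never bridges the flagged switch.

## Known limitations

* The level-plan dip is modelled as a single switch with a constant
  penalty; real consoles may switch several times across the gain range.
* The overflow prediction assumes the FID maximum scales like the signal
  model; near-ceiling compression (nonlinearity *below* RRT, reported on
  some hardware) is not modelled — hence the optional 0.5·RRT safety
  factor.
* The quantifier handles one dominant resonance per spectrum; multiplet
  fitting, peak picking and solvent suppression are out of scope.
* Acquisition control, polarizer operation and vendor raw-data formats
  are out of scope; interchange is CSV/JSON only.
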